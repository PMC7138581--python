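import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from fcnet.config import AnalysisConfig
from fcnet.errors import DegenerateStatisticError, InsufficientDataError
from fcnet.inference import (
    compare_groups,
    demographics_table,
    fdr_correct,
    permutation_test_difference,
    spearman_correlation,
    two_sample_t,
)
from fcnet.types import METRIC_NAMES


def test_t_identical_groups():
    t, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert t == 0.0 and p == pytest.approx(1.0)


def test_t_textbook_value():
    # pooled sd 1, se = sqrt(2/3), t = -3/se = -3.6742, df = 4
    t, p = two_sample_t([1, 2, 3], [4, 5, 6])
    assert t == pytest.approx(-3.6742, abs=1e-3)
    assert p == pytest.approx(0.02131, abs=1e-4)


def test_t_swap_symmetry():
    t1, p1 = two_sample_t([1, 2, 3], [4, 5, 6])
    t2, p2 = two_sample_t([4, 5, 6], [1, 2, 3])
    assert t2 == pytest.approx(-t1)
    assert p2 == pytest.approx(p1)


def test_t_zero_variance():
    with pytest.raises(DegenerateStatisticError):
        two_sample_t([1.0, 1.0], [1.0, 1.0])


def test_t_welch_flag_runs():
    t, p = two_sample_t([1, 2, 3, 9], [4, 5, 6], welch=True)
    assert np.isfinite(t) and 0 <= p <= 1


def test_fdr_step_up_by_hand():
    flags = fdr_correct([0.001, 0.02, 0.8], q=0.05)
    np.testing.assert_array_equal(flags, [True, True, False])


def test_fdr_all_ones():
    assert not fdr_correct(np.ones(10), q=0.05).any()


def test_fdr_all_zeros():
    assert fdr_correct(np.zeros(10), q=0.05).all()


def test_fdr_matches_statsmodels():
    rng = np.random.default_rng(0)
    for _ in range(50):
        p = rng.uniform(0, 1, size=int(rng.integers(3, 40)))
        ours = fdr_correct(p, q=0.05)
        ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
        np.testing.assert_array_equal(ours, ref)


def test_fdr_flags_are_downward_closed():
    rng = np.random.default_rng(1)
    p = rng.uniform(0, 1, 30)
    flags = fdr_correct(p, q=0.1)
    if flags.any() and (~flags).any():
        assert p[flags].max() <= p[~flags].min()


def test_permutation_identical_multisets():
    _, p = permutation_test_difference([1, 2, 3], [1, 2, 3], 100, seed=0)
    assert p == 1.0


def test_permutation_minimum_p():
    rng = np.random.default_rng(2)
    a = rng.normal(10, 1, 20)
    b = rng.normal(0, 1, 20)
    _, p = permutation_test_difference(a, b, 100, seed=1)
    assert p >= 1 / 101
    assert p == pytest.approx(1 / 101)


def test_permutation_separated_groups_match_enumeration():
    # exact enumeration for (10,11,12) vs (0,1,2): 2 of the 20 splits give
    # |delta| >= 10, so the true permutation p is 0.1 and the estimate
    # (1 + Bin(100, 0.1)) / 101 concentrates there
    ps = []
    for seed in range(100):
        _, p = permutation_test_difference([10, 11, 12], [0, 1, 2], 100, seed=seed)
        ps.append(p)
    assert np.mean(ps) == pytest.approx(11 / 101, abs=0.02)


def test_permutation_deterministic():
    a = [1.0, 2.0, 5.0]
    b = [0.5, 2.5, 3.0]
    r1 = permutation_test_difference(a, b, 100, seed=3)
    r2 = permutation_test_difference(a, b, 100, seed=3)
    assert r1 == r2


def test_spearman_monotone_invariance():
    x = np.array([0.1, 0.5, 1.2, 2.0, 3.3])
    rho, _ = spearman_correlation(x, np.exp(x))
    assert rho == pytest.approx(1.0)
    rho_neg, _ = spearman_correlation(x, -x)
    assert rho_neg == pytest.approx(-1.0)


def test_spearman_hand_rank_formula():
    # ranks of y = (3,1,2,5,4); d = (-2,1,1,-1,1); sum d^2 = 8
    # rho = 1 - 6*8 / (5*24) = 0.6
    x = [1, 2, 3, 4, 5]
    y = [3, 1, 2, 5, 4]
    rho, _ = spearman_correlation(x, y)
    d = np.array(x) - np.array([3, 1, 2, 5, 4])
    expected = 1 - 6 * (d ** 2).sum() / (5 * (25 - 1))
    assert expected == pytest.approx(0.6)
    assert rho == pytest.approx(0.6, abs=1e-12)


def test_spearman_pairwise_deletion():
    x = [1.0, 2.0, np.nan, 4.0, 5.0]
    y = [2.0, 3.0, 9.0, 5.0, 6.0]
    rho, _ = spearman_correlation(x, y)
    assert rho == pytest.approx(1.0)


def test_spearman_insufficient_pairs():
    with pytest.raises(InsufficientDataError):
        spearman_correlation([1.0, np.nan, 3.0], [np.nan, 2.0, 4.0])


def _manifest(n_per_group=10):
    rows = []
    rng = np.random.default_rng(0)
    for g, prefix in (("patient", "P"), ("control", "C")):
        for i in range(n_per_group):
            rows.append({
                "subject_id": f"{prefix}{i:02d}", "group": g,
                "age": float(40 + rng.integers(0, 20)),
                "sex": "M" if i % 2 else "F",
                "education": float(10 + rng.integers(0, 8)),
                "duration": float(i + 1) if g == "patient" else np.nan,
                "acth": float(50 + 5 * i) if g == "patient" else np.nan,
            })
    return pd.DataFrame(rows)


def test_demographics_balanced_sex():
    df = _manifest()
    table = demographics_table(df)
    sex_row = table[table["variable"] == "sex"].iloc[0]
    assert sex_row["statistic"] == pytest.approx(0.0)
    assert sex_row["p"] == pytest.approx(1.0)


def test_demographics_rank_sum_extreme():
    df = pd.DataFrame({
        "subject_id": [f"S{i}" for i in range(20)],
        "group": ["patient"] * 10 + ["control"] * 10,
        "age": list(range(1, 11)) + list(range(11, 21)),
        "sex": ["M", "F"] * 10,
        "education": [12.0] * 10 + [13.0] * 10,
    })
    table = demographics_table(df)
    age_row = table[table["variable"] == "age"].iloc[0]
    assert age_row["statistic"] == 0.0
    assert age_row["p"] < 0.001


def test_demographics_order_invariance():
    df = _manifest()
    shuffled = df.sample(frac=1.0, random_state=4).reset_index(drop=True)
    t1 = demographics_table(df)
    t2 = demographics_table(shuffled)
    pd.testing.assert_frame_equal(t1, t2)


def _tidy_inputs(n_per_group=6, n_levels=3, shift=0.0, seed=0):
    rng = np.random.default_rng(seed)
    manifest = _manifest(n_per_group)
    levels = np.round(0.1 + 0.05 * np.arange(n_levels), 10)
    rows = []
    strengths = []
    for _, subj in manifest.iterrows():
        delta = shift if subj["group"] == "patient" else 0.0
        for metric in METRIC_NAMES:
            for s in levels:
                rows.append({
                    "subject_id": subj["subject_id"], "sparsity": s,
                    "metric": metric, "value": rng.normal(1.0 + delta, 0.1),
                })
        strengths.append({
            "subject_id": subj["subject_id"],
            "rich_club": rng.normal(5 - delta, 0.5),
            "feeder": rng.normal(20 - delta, 1.0),
            "local": rng.normal(40 - delta, 2.0),
        })
    return pd.DataFrame(rows), pd.DataFrame(strengths), manifest


def test_compare_groups_shapes():
    profiles, strengths, manifest = _tidy_inputs()
    cfg = AnalysisConfig(seed=1, n_permutations=50)
    comparison = compare_groups(profiles, strengths, manifest, cfg)
    assert len(comparison.metric_table) == len(METRIC_NAMES) * 3
    assert set(comparison.metric_table.columns) == {
        "metric", "sparsity", "t", "p", "fdr_significant",
    }
    assert len(comparison.strength_table) == 3
    assert (comparison.strength_table["p_perm"] >= 1 / 51).all()
    # (7 metrics + 3 strengths) x 2 clinical variables
    assert len(comparison.spearman_table) == 20


def test_compare_groups_subject_order_invariance():
    profiles, strengths, manifest = _tidy_inputs()
    cfg = AnalysisConfig(seed=1, n_permutations=50)
    c1 = compare_groups(profiles, strengths, manifest, cfg)
    c2 = compare_groups(
        profiles.sample(frac=1.0, random_state=1).reset_index(drop=True),
        strengths.sample(frac=1.0, random_state=2).reset_index(drop=True),
        manifest.sample(frac=1.0, random_state=3).reset_index(drop=True),
        cfg,
    )
    pd.testing.assert_frame_equal(c1.metric_table, c2.metric_table)
    pd.testing.assert_frame_equal(c1.strength_table, c2.strength_table)


def test_compare_groups_null_rarely_flags():
    # identically distributed groups: few FDR flags over 20 replicates
    flagged = total = 0
    cfg = AnalysisConfig(seed=1, n_permutations=20, fdr_q=0.05)
    for rep in range(20):
        profiles, strengths, manifest = _tidy_inputs(seed=rep)
        comparison = compare_groups(profiles, strengths, manifest, cfg)
        flagged += int(comparison.metric_table["fdr_significant"].sum())
        total += len(comparison.metric_table)
    assert flagged / total < 0.10


def test_compare_groups_detects_shift():
    profiles, strengths, manifest = _tidy_inputs(n_per_group=10, shift=1.0, seed=3)
    cfg = AnalysisConfig(seed=1, n_permutations=100, fdr_q=0.05)
    comparison = compare_groups(profiles, strengths, manifest, cfg)
    assert comparison.metric_table["fdr_significant"].all()
    assert (comparison.strength_table["p_perm"] < 0.05).all()
    assert (comparison.strength_table["delta_obs"] < 0).all()
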