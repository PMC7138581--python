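"""Group inference: demographics tests, per-sparsity metric comparisons
with Benjamini-Hochberg FDR, permutation tests on edge-class strengths,
and Spearman correlations against clinical covariates.

Conventions (documented assumptions): the two-sample t-test is the
classical equal-variance form (Welch behind a flag); the chi-square test
for sex omits the Yates continuity correction; permutation p-values use
the +1 convention and therefore never fall below 1/(P+1); Spearman
correlations are computed within the patient group only, since the
clinical covariates exist only there.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as _stats

from ._rng import substream
from .config import AnalysisConfig
from .errors import DegenerateStatisticError, InsufficientDataError
from .richclub import EDGE_CLASSES
from .types import METRIC_NAMES

__all__ = [
    "two_sample_t",
    "fdr_correct",
    "permutation_test_difference",
    "spearman_correlation",
    "demographics_table",
    "compare_groups",
    "GroupComparison",
]


@dataclass
class GroupComparison:
    """All between-group statistics for one analysis run."""

    metric_table: pd.DataFrame      # metric, sparsity, t, p, fdr_significant
    strength_table: pd.DataFrame    # edge_class, delta_obs, p_perm
    demographics: pd.DataFrame      # variable, test, statistic, p
    spearman_table: pd.DataFrame    # parameter, clinical, rho, p, n


def two_sample_t(group_a, group_b, welch: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t-test (equal-variance by default)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("need at least 2 values per group")
    if not welch:
        na, nb = a.size, b.size
        pooled = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        if pooled == 0:
            raise DegenerateStatisticError("zero pooled variance")
    t, p = _stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def fdr_correct(pvalues, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up at level q; returns boolean flags.

    Flags are true for every p <= the largest sorted p(k) satisfying
    p(k) <= k*q/m.
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    below = ranked <= (np.arange(1, m + 1) * q / m)
    if not below.any():
        return np.zeros(m, dtype=bool)
    cutoff = ranked[np.flatnonzero(below)[-1]]
    return p <= cutoff


def permutation_test_difference(
    group_a, group_b, n_permutations: int, seed: int,
) -> tuple[float, float]:
    """Group-label permutation test on the difference in means.

    Returns (delta_obs, p) with delta_obs = mean(A) - mean(B) and
    p = (1 + #{|delta_perm| >= |delta_obs|}) / (P + 1).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    delta_obs = float(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    n_a, n_tot = a.size, pooled.size
    rng = substream(seed, "permutation")
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n_tot)
        delta = pooled[perm[:n_a]].mean() - pooled[perm[n_a:]].mean()
        if abs(delta) >= abs(delta_obs) - 1e-15:
            count += 1
    p = (1 + count) / (n_permutations + 1)
    return delta_obs, float(p)


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation with pairwise deletion of missing values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    if keep.sum() < 3:
        raise InsufficientDataError(
            f"need >= 3 complete pairs for Spearman, got {int(keep.sum())}"
        )
    res = _stats.spearmanr(x[keep], y[keep])
    return float(res.statistic), float(res.pvalue)


def demographics_table(manifest: pd.DataFrame, continuity: bool = False) -> pd.DataFrame:
    """Sex (chi-square), age and education (Mann-Whitney U) group tests."""
    patients = manifest[manifest["group"] == "patient"]
    controls = manifest[manifest["group"] == "control"]
    if patients.empty or controls.empty:
        raise InsufficientDataError("need both groups for demographics")
    rows = []
    if "sex" in manifest.columns and manifest["sex"].notna().all():
        table = pd.crosstab(manifest["group"], manifest["sex"])
        if table.shape == (2, 2):
            chi2, p, _, _ = _stats.chi2_contingency(table.to_numpy(), correction=continuity)
            rows.append({"variable": "sex", "test": "chi_square",
                         "statistic": float(chi2), "p": float(p)})
    for col in ("age", "education"):
        if col not in manifest.columns:
            continue
        a = patients[col].dropna().to_numpy(dtype=float)
        b = controls[col].dropna().to_numpy(dtype=float)
        if a.size == 0 or b.size == 0:
            continue  # skip with missing covariate in a whole group
        u, p = _stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False,
        )
        rows.append({"variable": col, "test": "mann_whitney_u",
                     "statistic": float(u), "p": float(p)})
    return pd.DataFrame(rows, columns=["variable", "test", "statistic", "p"])


CLINICAL_TARGETS = ("duration", "acth")


def compare_groups(
    profiles: pd.DataFrame,
    strengths: pd.DataFrame,
    manifest: pd.DataFrame,
    config: AnalysisConfig,
) -> GroupComparison:
    """Full between-group comparison.

    ``profiles`` is tidy (subject_id, sparsity, metric, value);
    ``strengths`` is wide (subject_id, rich_club, feeder, local);
    groups come from ``manifest``.  Per-sparsity t-tests are FDR
    corrected within each metric family (or pooled across metrics when
    ``config.fdr_pool_metrics``); class strengths get permutation tests;
    Spearman correlations use patient-group grid means.
    """
    groups = manifest.set_index("subject_id")["group"]
    prof = profiles.merge(groups.rename("group"), left_on="subject_id", right_index=True)

    metric_rows = []
    for metric in METRIC_NAMES:
        sub = prof[prof["metric"] == metric]
        for s, block in sub.groupby("sparsity", sort=True):
            a = block.loc[block["group"] == "patient", "value"].to_numpy()
            b = block.loc[block["group"] == "control", "value"].to_numpy()
            t, p = two_sample_t(a, b, welch=config.use_welch)
            metric_rows.append({"metric": metric, "sparsity": s, "t": t, "p": p})
    metric_table = pd.DataFrame(metric_rows)
    if config.fdr_pool_metrics:
        metric_table["fdr_significant"] = fdr_correct(
            metric_table["p"].to_numpy(), config.fdr_q,
        )
    else:
        flags = np.zeros(len(metric_table), dtype=bool)
        for metric in METRIC_NAMES:
            idx = metric_table.index[metric_table["metric"] == metric]
            flags[idx] = fdr_correct(
                metric_table.loc[idx, "p"].to_numpy(), config.fdr_q,
            )
        metric_table["fdr_significant"] = flags

    # permutation RNG keys on sorted subject IDs so subject order is irrelevant
    strengths = strengths.sort_values("subject_id").reset_index(drop=True)
    sid_key = ",".join(strengths["subject_id"].astype(str))
    strength_rows = []
    merged = strengths.merge(groups.rename("group"), left_on="subject_id", right_index=True)
    for cls in EDGE_CLASSES:
        a = merged.loc[merged["group"] == "patient", cls].to_numpy(dtype=float)
        b = merged.loc[merged["group"] == "control", cls].to_numpy(dtype=float)
        delta, p = permutation_test_difference(
            a, b, config.n_permutations,
            seed=_strength_seed(config.seed, cls, sid_key),
        )
        strength_rows.append({"edge_class": cls, "delta_obs": delta, "p_perm": p})
    strength_table = pd.DataFrame(strength_rows)

    demo = demographics_table(manifest, continuity=config.chi2_continuity)

    # patient-group grid means of each metric, plus class strengths
    patient_ids = groups[groups == "patient"].index
    patient_prof = prof[prof["group"] == "patient"]
    summaries: dict[str, pd.Series] = {}
    for metric in METRIC_NAMES:
        sub = patient_prof[patient_prof["metric"] == metric]
        summaries[metric] = sub.groupby("subject_id")["value"].mean()
    for cls in EDGE_CLASSES:
        summaries[cls] = merged[merged["group"] == "patient"].set_index("subject_id")[cls]

    clin = manifest.set_index("subject_id").loc[:, [c for c in CLINICAL_TARGETS if c in manifest.columns]]
    spearman_rows = []
    for name, series in summaries.items():
        for clinical in CLINICAL_TARGETS:
            if clinical in clin.columns:
                x = clin.loc[patient_ids, clinical].to_numpy(dtype=float)
                y = series.reindex(patient_ids).to_numpy(dtype=float)
                try:
                    rho, p = spearman_correlation(x, y)
                    n_pairs = int((np.isfinite(x) & np.isfinite(y)).sum())
                except InsufficientDataError:
                    rho, p, n_pairs = np.nan, np.nan, 0
            else:
                rho, p, n_pairs = np.nan, np.nan, 0
            spearman_rows.append({
                "parameter": name, "clinical": clinical,
                "rho": rho, "p": p, "n": n_pairs,
            })
    spearman_table = pd.DataFrame(spearman_rows)

    return GroupComparison(
        metric_table=metric_table,
        strength_table=strength_table,
        demographics=demo,
        spearman_table=spearman_table,
    )


def _strength_seed(seed: int, cls: str, sid_key: str) -> int:
    from ._rng import substream_seed

    return substream_seed(seed, "strength-permutation", cls, sid_key)
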