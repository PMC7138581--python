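import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fcnet.config import AnalysisConfig
from fcnet.construct import (
    correlation_matrix,
    edge_count_for_sparsity,
    preprocess_timeseries,
    sparsity_sweep,
    threshold_by_sparsity,
)
from fcnet.errors import (
    DegenerateSignalError,
    DimensionError,
    InfeasibleSparsityError,
    ThresholdError,
)
from fcnet.types import SparsityGrid, TimeSeriesPanel, default_region_labels

from conftest import conn_from_upper

CFG = AnalysisConfig()


def _panel(values, tr=2.0):
    values = np.asarray(values, dtype=float)
    return TimeSeriesPanel(
        subject_id="s", region_labels=default_region_labels(values.shape[0]),
        values=values, tr_seconds=tr,
    )


def test_discard_leaves_200_volumes():
    rng = np.random.default_rng(0)
    panel = _panel(rng.standard_normal((5, 210)))
    out = preprocess_timeseries(panel, CFG)
    assert out.n_volumes == 200


def test_in_band_sinusoid_passes_through():
    t = np.arange(210) * 2.0
    wave = np.sin(2 * np.pi * 0.04 * t)
    panel = _panel(np.vstack([wave, np.cos(2 * np.pi * 0.04 * t)]))
    out = preprocess_timeseries(panel, CFG)
    kept = wave[10:]
    r = np.corrcoef(out.values[0], kept)[0, 1]
    assert r > 0.99


def test_out_of_band_sinusoid_removed():
    t = np.arange(210) * 2.0
    wave = np.sin(2 * np.pi * 0.2 * t)
    panel = _panel(np.vstack([wave, wave[::-1]]))
    out = preprocess_timeseries(panel, CFG)
    assert np.sqrt((out.values[0] ** 2).mean()) < 0.05 * np.sqrt((wave ** 2).mean())


def test_linear_ramp_annihilated():
    ramp = np.linspace(0.0, 5.0, 210)
    panel = _panel(np.vstack([ramp, 2.0 - 3.0 * ramp]))
    out = preprocess_timeseries(panel, CFG)
    assert np.abs(out.values).max() < 1e-8


def test_output_mean_is_zero():
    rng = np.random.default_rng(1)
    panel = _panel(rng.standard_normal((4, 210)) + 100.0)
    out = preprocess_timeseries(panel, CFG)
    assert np.abs(out.values.mean(axis=1)).max() < 1e-8


def test_too_few_volumes_errors():
    panel = _panel(np.random.default_rng(2).standard_normal((3, 20)))
    with pytest.raises(DimensionError):
        preprocess_timeseries(panel, CFG)  # 20 - 10 < 12.5 needed for the band


def test_correlation_identical_rows():
    base = np.array([1.0, 3.0, 2.0, 5.0])
    conn = correlation_matrix(_panel(np.vstack([base, base, -base])))
    assert conn.r[0, 1] == pytest.approx(1.0)
    assert conn.r[0, 2] == pytest.approx(-1.0)
    assert np.all(np.diag(conn.r) == 0)


def test_correlation_hand_value():
    # Pearson((1,2,3,4), (1,3,2,4)): deviations (-1.5,-.5,.5,1.5) and
    # (-1.5,.5,-.5,1.5) give covariance 4/3 and variances 5/3 -> r = 0.8
    conn = correlation_matrix(_panel([[1, 2, 3, 4], [1, 3, 2, 4]]))
    assert conn.r[0, 1] == pytest.approx(0.8, abs=1e-12)


def test_correlation_zero_variance_names_region():
    values = np.vstack([np.ones(5), np.arange(5.0)])
    with pytest.raises(DegenerateSignalError, match="R001"):
        correlation_matrix(_panel(values))


def test_threshold_keeps_top_positive_edges():
    # upper triangle in (i,j) lex order: (0,1) (0,2) (0,3) (1,2) (1,3) (2,3)
    conn = conn_from_upper(4, [0.9, 0.8, 0.7, 0.3, 0.2, 0.1])
    graph = threshold_by_sparsity(conn, 0.5)
    assert graph.n_edges == 3
    assert graph.adjacency[0, 1] and graph.adjacency[0, 2] and graph.adjacency[0, 3]
    assert not graph.adjacency[1, 2]


def test_threshold_edge_count_definitional():
    rng = np.random.default_rng(3)
    n = 20
    conn = conn_from_upper(n, rng.uniform(0.01, 0.99, n * (n - 1) // 2))
    for s in (0.05, 0.13, 0.4, 0.77):
        graph = threshold_by_sparsity(conn, s)
        assert graph.n_edges == edge_count_for_sparsity(n, s)
        achieved = graph.n_edges / (n * (n - 1) / 2)
        assert abs(achieved - s) <= 0.5 / (n * (n - 1) / 2) + 1e-12


def test_threshold_all_negative_infeasible():
    conn = conn_from_upper(4, [-0.1, -0.2, -0.3, -0.4, -0.5, -0.6])
    with pytest.raises(InfeasibleSparsityError) as err:
        threshold_by_sparsity(conn, 0.5)
    assert err.value.max_sparsity == 0.0


def test_threshold_zero_edges_errors():
    conn = conn_from_upper(4, [0.9, 0.8, 0.7, 0.3, 0.2, 0.1])
    with pytest.raises(ThresholdError):
        threshold_by_sparsity(conn, 0.05)  # round(0.3) = 0 edges


def test_threshold_tie_break_lexicographic():
    conn = conn_from_upper(4, [0.5, 0.5, 0.5, 0.5, 0.5, 0.5])
    graph = threshold_by_sparsity(conn, 0.5)
    # first three pairs in lex order win the tie
    assert graph.adjacency[0, 1] and graph.adjacency[0, 2] and graph.adjacency[0, 3]
    assert graph.n_edges == 3


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_threshold_rank_invariance(seed):
    # any strictly increasing transform of r keeps the same edge set
    rng = np.random.default_rng(seed)
    n = 10
    upper = rng.uniform(-1, 1, n * (n - 1) // 2)
    conn = conn_from_upper(n, upper)
    mono = conn_from_upper(n, np.tanh(2.0 * upper))  # increasing, sign-preserving
    g1 = threshold_by_sparsity(conn, 0.3)
    g2 = threshold_by_sparsity(mono, 0.3)
    np.testing.assert_array_equal(g1.adjacency, g2.adjacency)


def test_sweep_default_grid_on_90_nodes():
    rng = np.random.default_rng(4)
    n = 90
    conn = conn_from_upper(n, rng.uniform(0.01, 0.99, n * (n - 1) // 2))
    graphs = sparsity_sweep(conn, CFG.sparsity_grid())
    assert len(graphs) == 36
    counts = [g.n_edges for g in graphs]
    assert all(b >= a for a, b in zip(counts, counts[1:]))
    # nestedness of adjacent levels
    for a, b in zip(graphs, graphs[1:]):
        assert np.all(b.adjacency >= a.adjacency)


def test_sparsity_grid_type_rejects_non_increasing():
    with pytest.raises(ValueError):
        SparsityGrid((0.1, 0.1))
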