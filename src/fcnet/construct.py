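"""Network construction: temporal cleanup, Pearson connectivity, sparsity
thresholding into families of binary graphs.

Thresholding conventions (documented assumptions):

* only positive correlations become edges; negative r is never an edge;
* the edge count at sparsity ``s`` is round-half-up of ``s * N(N-1)/2``;
* ties at the cutoff value are broken by lexicographic (i, j) node order.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as _signal

from .config import AnalysisConfig
from .errors import (
    DegenerateSignalError,
    DimensionError,
    InfeasibleSparsityError,
    ThresholdError,
)
from .types import BinaryGraph, ConnectivityMatrix, SparsityGrid, TimeSeriesPanel

__all__ = [
    "preprocess_timeseries",
    "correlation_matrix",
    "threshold_by_sparsity",
    "sparsity_sweep",
]


def preprocess_timeseries(panel: TimeSeriesPanel, config: AnalysisConfig) -> TimeSeriesPanel:
    """Discard leading volumes, detrend, and band-pass each region.

    The first ``config.discard_volumes`` columns are dropped, a linear
    trend is removed per region by least squares, and frequencies are
    retained only strictly inside (band_low_hz, band_high_hz) via an
    ideal rectangular filter on the real DFT.  The filtered signal has
    zero mean by construction (the DC bin is removed).
    """
    t_kept = panel.n_volumes - config.discard_volumes
    t_min = 2.0 / (config.band_high_hz * config.tr_seconds)
    if t_kept < t_min:
        raise DimensionError(
            f"subject {panel.subject_id}: {t_kept} volumes after discarding "
            f"{config.discard_volumes} is below the {t_min:.1f} needed for the "
            f"({config.band_low_hz}, {config.band_high_hz}) Hz band"
        )
    values = panel.values[:, config.discard_volumes:]
    values = _signal.detrend(values, axis=1, type="linear")

    spectra = np.fft.rfft(values, axis=1)
    freqs = np.fft.rfftfreq(values.shape[1], d=config.tr_seconds)
    keep = (freqs > config.band_low_hz) & (freqs < config.band_high_hz)
    spectra[:, ~keep] = 0.0
    filtered = np.fft.irfft(spectra, n=values.shape[1], axis=1)

    return TimeSeriesPanel(
        subject_id=panel.subject_id,
        region_labels=list(panel.region_labels),
        values=filtered,
        tr_seconds=panel.tr_seconds,
    )


def correlation_matrix(panel: TimeSeriesPanel) -> ConnectivityMatrix:
    """Pearson correlation between every pair of regions; diagonal set to 0."""
    stds = panel.values.std(axis=1)
    dead = np.flatnonzero(stds == 0)
    if dead.size:
        names = [panel.region_labels[i] for i in dead]
        raise DegenerateSignalError(
            f"subject {panel.subject_id}: zero-variance region(s) {names}"
        )
    r = np.corrcoef(panel.values)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(
        subject_id=panel.subject_id,
        region_labels=list(panel.region_labels),
        r=r,
    )


def edge_count_for_sparsity(n_nodes: int, s: float) -> int:
    """Round-half-up of s * N(N-1)/2."""
    n_pairs = n_nodes * (n_nodes - 1) // 2
    return int(np.floor(s * n_pairs + 0.5))


def threshold_by_sparsity(conn: ConnectivityMatrix, s: float) -> BinaryGraph:
    """Keep the E strongest positive correlations as edges, E = round(s*N(N-1)/2)."""
    if not (0 < s < 1):
        raise ThresholdError(f"sparsity must be in (0, 1), got {s}")
    n = conn.n_regions
    n_pairs = n * (n - 1) // 2
    n_edges = edge_count_for_sparsity(n, s)
    if n_edges == 0:
        raise ThresholdError(
            f"sparsity {s} yields zero edges on {n} nodes"
        )
    iu, ju = np.triu_indices(n, k=1)
    weights = conn.r[iu, ju]
    n_positive = int((weights > 0).sum())
    if n_positive < n_edges:
        raise InfeasibleSparsityError(
            f"sparsity {s} needs {n_edges} edges but only {n_positive} positive "
            f"correlations exist (max attainable sparsity {n_positive / n_pairs:.6g})",
            max_sparsity=n_positive / n_pairs,
        )
    # primary key: descending r; ties by (i, j) lexicographic
    order = np.lexsort((ju, iu, -weights))
    keep = order[:n_edges]
    adjacency = np.zeros((n, n), dtype=np.uint8)
    adjacency[iu[keep], ju[keep]] = 1
    adjacency[ju[keep], iu[keep]] = 1
    return BinaryGraph(
        region_labels=list(conn.region_labels), adjacency=adjacency, sparsity=float(s),
    )


def sparsity_sweep(conn: ConnectivityMatrix, grid: SparsityGrid) -> list[BinaryGraph]:
    """One binary graph per grid level; edge sets are nested across levels."""
    return [threshold_by_sparsity(conn, s) for s in grid]
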