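"""Degree-preserving null networks and small-world normalization.

The null model is Maslov-Sneppen double-edge-swap rewiring: pick two
edges (a,b), (c,d) with four distinct endpoints, propose (a,d), (c,b),
and accept only if neither proposed edge exists.  The degree sequence is
preserved exactly; self-loops and multi-edges can never arise.  The swap
loop is JIT-compiled because the pipeline rewires tens of thousands of
graphs per run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from ._rng import substream_seed
from .errors import UndefinedNormalizationError
from .metrics import characteristic_path_length, clustering_coefficients
from .types import BinaryGraph

__all__ = [
    "rewire_degree_preserving",
    "null_reference",
    "small_world_parameters",
    "NullEnsemble",
]


@dataclass
class NullEnsemble:
    """Summary of M degree-preserving rewired references for one graph."""

    sparsity: float
    n_nulls: int
    cp_rand: float
    lp_rand: float
    cp_values: np.ndarray  # per-null raw Cp
    lp_values: np.ndarray  # per-null raw Lp


@njit(cache=True)
def _rewire_kernel(adj, edges, n_attempts, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    n_edges = edges.shape[0]
    for _ in range(n_attempts):
        e1 = np.random.randint(0, n_edges)
        e2 = np.random.randint(0, n_edges)
        if e1 == e2:
            continue
        a, b = edges[e1, 0], edges[e1, 1]
        c, d = edges[e2, 0], edges[e2, 1]
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = 0
        adj[b, a] = 0
        adj[c, d] = 0
        adj[d, c] = 0
        adj[a, d] = 1
        adj[d, a] = 1
        adj[c, b] = 1
        adj[b, c] = 1
        edges[e1, 1] = d
        edges[e2, 1] = b


def _rewire_adjacency(adj: np.ndarray, n_swaps_per_edge: int, seed32: int) -> np.ndarray:
    out = adj.copy()
    iu, ju = np.nonzero(np.triu(out, k=1))
    edges = np.column_stack((iu, ju)).astype(np.int64)
    if edges.shape[0] >= 2:
        n_attempts = int(n_swaps_per_edge) * edges.shape[0]
        _rewire_kernel(out, edges, n_attempts, np.uint32(seed32))
    return out


def rewire_degree_preserving(graph: BinaryGraph, n_swaps_per_edge: int, seed: int) -> BinaryGraph:
    """Randomize topology with n_swaps_per_edge * E attempted double-edge swaps."""
    rewired = _rewire_adjacency(
        graph.adjacency, n_swaps_per_edge, substream_seed(seed, "rewire"),
    )
    return BinaryGraph(
        region_labels=list(graph.region_labels),
        adjacency=rewired,
        sparsity=graph.sparsity,
    )


def null_reference(
    graph: BinaryGraph, n_nulls: int, n_swaps_per_edge: int, seed: int,
) -> NullEnsemble:
    """Cp and Lp means over M independent rewired graphs (substream per index).

    Disconnected nulls are retained and use the finite-pair path-length
    convention; resampling them would bias the ensemble toward
    connectedness.
    """
    cp_values = np.empty(n_nulls)
    lp_values = np.empty(n_nulls)
    for m in range(n_nulls):
        null_adj = _rewire_adjacency(
            graph.adjacency, n_swaps_per_edge, substream_seed(seed, "null", m),
        )
        _, cp_values[m] = clustering_coefficients(null_adj)
        lp_values[m], _ = characteristic_path_length(null_adj)
    return NullEnsemble(
        sparsity=graph.sparsity,
        n_nulls=n_nulls,
        cp_rand=float(cp_values.mean()),
        lp_rand=float(lp_values.mean()),
        cp_values=cp_values,
        lp_values=lp_values,
    )


def small_world_parameters(graph: BinaryGraph, ensemble: NullEnsemble) -> tuple[float, float, float]:
    """gamma = Cp/Cp_rand, lambda = Lp/Lp_rand, sigma = gamma/lambda."""
    if ensemble.cp_rand == 0 or ensemble.lp_rand == 0:
        raise UndefinedNormalizationError(
            "null-ensemble mean Cp or Lp is zero; normalization undefined"
        )
    _, cp = clustering_coefficients(graph)
    lp, _ = characteristic_path_length(graph)
    gamma = cp / ensemble.cp_rand
    lam = lp / ensemble.lp_rand
    return gamma, lam, gamma / lam
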