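"""Unweighted graph statistics.

All metrics operate on binary undirected graphs.  Conventions for
degenerate cases (documented assumptions, since exact formulas are not
universally standardized):

* clustering coefficient C_i = 0 for nodes of degree < 2, and the mean
  Cp averages over *all* nodes;
* characteristic path length averages hop distances over reachable
  (finite) pairs only; the connectedness flag records whether any pair
  was unreachable;
* global efficiency counts unreachable pairs as zero contribution.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .errors import UndefinedMetricError
from .types import BinaryGraph

__all__ = [
    "shortest_path_matrix",
    "global_efficiency",
    "clustering_coefficients",
    "local_efficiency",
    "characteristic_path_length",
    "degree_centrality",
]


def _as_adjacency(graph) -> np.ndarray:
    if isinstance(graph, BinaryGraph):
        return graph.adjacency
    return np.asarray(graph, dtype=np.uint8)


def _distances(adj: np.ndarray) -> np.ndarray:
    if adj.shape[0] == 0:
        return np.zeros((0, 0))
    dist = _csgraph_shortest_path(
        csr_matrix(adj), method="D", directed=False, unweighted=True,
    )
    return dist


def shortest_path_matrix(graph) -> np.ndarray:
    """All-pairs minimum hop counts (BFS); unreachable pairs are inf."""
    return _distances(_as_adjacency(graph))


def _global_efficiency_from_dist(dist: np.ndarray) -> float:
    n = dist.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def global_efficiency(graph) -> float:
    """Mean inverse shortest-path length over ordered node pairs (1/inf = 0)."""
    return _global_efficiency_from_dist(_distances(_as_adjacency(graph)))


def clustering_coefficients(graph) -> tuple[np.ndarray, float]:
    """Nodal clustering vector and its mean Cp.

    C_i = 2 e_i / (k_i (k_i - 1)) with e_i the number of edges among the
    neighbors of i; C_i = 0 when k_i < 2.
    """
    adj = _as_adjacency(graph).astype(float)
    k = adj.sum(axis=1)
    triangles = ((adj @ adj) * adj).sum(axis=1)  # (A^3)_ii = 2 e_i per node
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, triangles / denom, 0.0)
    return c, float(c.mean()) if c.size else 0.0


def local_efficiency(graph) -> float:
    """Mean global efficiency of each node's neighbor-induced subgraph."""
    adj = _as_adjacency(graph)
    n = adj.shape[0]
    if n == 0:
        return 0.0
    total = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        if nbrs.size < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        total += _global_efficiency_from_dist(_distances(sub))
    return total / n


def characteristic_path_length(graph) -> tuple[float, bool]:
    """Mean hop distance over finite unordered pairs, plus connectedness flag."""
    dist = _distances(_as_adjacency(graph))
    n = dist.shape[0]
    iu = np.triu_indices(n, k=1)
    pair_dists = dist[iu]
    finite = np.isfinite(pair_dists)
    if not finite.any():
        raise UndefinedMetricError("no finite node pair: path length undefined")
    lp = float(pair_dists[finite].mean())
    return lp, bool(finite.all())


def degree_centrality(graph) -> np.ndarray:
    """Nodal degree vector (row sums of the adjacency matrix)."""
    return _as_adjacency(graph).sum(axis=1).astype(np.int64)
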