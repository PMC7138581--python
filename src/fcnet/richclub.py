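"""Hub identification and rich-club / feeder / local edge analysis.

Hubs are regions whose degree centrality — averaged over the sparsity
grid of the *group-mean* connectivity matrix — lies at least one
population standard deviation above the across-region mean.  Edges are
then classified by their endpoints: both hubs (rich_club), exactly one
hub (feeder), neither (local).  Class strengths sum the Pearson weights
of suprathreshold edges, averaged over grid levels.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._rng import substream_seed
from .construct import sparsity_sweep, threshold_by_sparsity
from .errors import LabelError
from .metrics import degree_centrality
from .nullmodels import _rewire_adjacency
from .types import BinaryGraph, ConnectivityMatrix, RichClubPartition, SparsityGrid

__all__ = [
    "identify_hubs",
    "classify_edges",
    "connection_strengths",
    "normalized_rich_club_coefficient",
    "group_mean_connectivity",
]

EDGE_CLASSES = ("rich_club", "feeder", "local")


def group_mean_connectivity(conns: list[ConnectivityMatrix], group: str = "group") -> ConnectivityMatrix:
    """Elementwise mean of raw Pearson matrices over a group's subjects."""
    if not conns:
        raise ValueError("need at least one connectivity matrix")
    labels = conns[0].region_labels
    for conn in conns[1:]:
        if conn.region_labels != labels:
            raise LabelError("connectivity matrices have inconsistent region labels")
    mean_r = np.mean([conn.r for conn in conns], axis=0)
    return ConnectivityMatrix(subject_id=group, region_labels=list(labels), r=mean_r)


def identify_hubs(
    conns: list[ConnectivityMatrix], grid: SparsityGrid, group: str = "group",
) -> RichClubPartition:
    """Hub set of one group: mean + 1 SD rule on grid-averaged degree centrality.

    The SD is the population standard deviation across regions.  When SD
    is zero (regular graphs at every level) the rule degenerates; we then
    require centrality strictly above the mean, so no region qualifies.
    """
    mean_conn = group_mean_connectivity(conns, group)
    degrees = np.array([
        degree_centrality(graph) for graph in sparsity_sweep(mean_conn, grid)
    ], dtype=float)
    centrality = degrees.mean(axis=0)
    mu = centrality.mean()
    sd = centrality.std()  # population SD
    threshold = mu + sd
    if sd == 0:
        hub_mask = centrality > mu
    else:
        hub_mask = centrality >= threshold
    labels = mean_conn.region_labels
    return RichClubPartition(
        group=group,
        hub_regions={labels[i] for i in np.flatnonzero(hub_mask)},
        hub_rule_threshold=float(threshold),
        mean_degree_centrality=pd.Series(centrality, index=labels),
    )


def _hub_mask(labels: list, hubs: set) -> np.ndarray:
    unknown = set(hubs) - set(labels)
    if unknown:
        raise LabelError(f"hub regions not in graph: {sorted(unknown)}")
    mask = np.zeros(len(labels), dtype=bool)
    for i, lab in enumerate(labels):
        if lab in hubs:
            mask[i] = True
    return mask


def classify_edges(graph: BinaryGraph, hubs: set) -> dict:
    """Map each edge (label_i, label_j), i < j, to its class."""
    mask = _hub_mask(graph.region_labels, hubs)
    iu, ju = np.nonzero(np.triu(graph.adjacency, k=1))
    classes = {}
    for i, j in zip(iu, ju):
        n_hub_ends = int(mask[i]) + int(mask[j])
        cls = EDGE_CLASSES[2 - n_hub_ends]
        classes[(graph.region_labels[i], graph.region_labels[j])] = cls
    return classes


def connection_strengths(
    conn: ConnectivityMatrix,
    grid: SparsityGrid,
    hubs: set,
    stat: str = "sum",
) -> dict:
    """Per-class edge-weight strengths, averaged across grid levels.

    At each level the strength of a class is the sum (or mean, when
    ``stat == 'mean'``) of the Pearson r weights over that class's
    suprathreshold edges; the reported value is the mean across levels.
    """
    mask = _hub_mask(conn.region_labels, hubs)
    per_level = {cls: [] for cls in EDGE_CLASSES}
    for s in grid:
        graph = threshold_by_sparsity(conn, s)
        iu, ju = np.nonzero(np.triu(graph.adjacency, k=1))
        n_hub_ends = mask[iu].astype(int) + mask[ju].astype(int)
        weights = conn.r[iu, ju]
        for n_ends, cls in ((2, "rich_club"), (1, "feeder"), (0, "local")):
            sel = weights[n_hub_ends == n_ends]
            if stat == "mean":
                per_level[cls].append(float(sel.mean()) if sel.size else 0.0)
            else:
                per_level[cls].append(float(sel.sum()))
    return {cls: float(np.mean(vals)) for cls, vals in per_level.items()}


def normalized_rich_club_coefficient(
    graph: BinaryGraph,
    k_levels,
    n_nulls: int,
    seed: int,
    n_swaps_per_edge: int = 10,
) -> pd.DataFrame:
    """phi(k), phi_rand(k) and phi_norm(k) over the given degree levels.

    phi(k) is the edge density among nodes of degree > k; it is undefined
    (NaN) where fewer than 2 such nodes exist.  phi_norm divides by the
    mean phi over degree-preserving rewired nulls.
    """
    def _phi(adj: np.ndarray, k: int) -> float:
        deg = adj.sum(axis=1)
        members = np.flatnonzero(deg > k)
        n_k = members.size
        if n_k < 2:
            return np.nan
        sub = adj[np.ix_(members, members)]
        return float(sub.sum() / (n_k * (n_k - 1)))

    adj = graph.adjacency.astype(np.int64)
    k_levels = list(k_levels)
    phi = np.array([_phi(adj, k) for k in k_levels])
    phi_rand = np.zeros((n_nulls, len(k_levels)))
    for m in range(n_nulls):
        null_adj = _rewire_adjacency(
            graph.adjacency, n_swaps_per_edge, substream_seed(seed, "phi-null", m),
        ).astype(np.int64)
        phi_rand[m] = [_phi(null_adj, k) for k in k_levels]
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)  # all-NaN slices
        mean_rand = np.nanmean(phi_rand, axis=0) if n_nulls else np.full(len(k_levels), np.nan)
        phi_norm = phi / mean_rand
    return pd.DataFrame({
        "k": k_levels, "phi": phi, "phi_rand": mean_rand, "phi_norm": phi_norm,
    })
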