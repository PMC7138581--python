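import numpy as np
import pytest

from fcnet.types import BinaryGraph, ConnectivityMatrix, default_region_labels


def graph_from_edges(n, edges, sparsity=0.1):
    adj = np.zeros((n, n), dtype=np.uint8)
    for i, j in edges:
        adj[i, j] = 1
        adj[j, i] = 1
    return BinaryGraph(
        region_labels=default_region_labels(n), adjacency=adj, sparsity=sparsity,
    )


def conn_from_upper(n, upper, subject_id="S"):
    """Connectivity matrix from upper-triangle weights in (i, j) lex order."""
    r = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    r[iu, ju] = upper
    r[ju, iu] = upper
    return ConnectivityMatrix(
        subject_id=subject_id, region_labels=default_region_labels(n), r=r,
    )


def random_graph(rng, n_max=12):
    n = int(rng.integers(4, n_max + 1))
    p = float(rng.uniform(0.1, 0.8))
    adj = (rng.random((n, n)) < p).astype(np.uint8)
    adj = np.triu(adj, k=1)
    adj = adj + adj.T
    return BinaryGraph(
        region_labels=default_region_labels(n), adjacency=adj, sparsity=0.1,
    )


@pytest.fixture
def path3():
    return graph_from_edges(3, [(0, 1), (1, 2)])


@pytest.fixture
def k4():
    return graph_from_edges(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])


@pytest.fixture
def k5():
    return graph_from_edges(5, [(i, j) for i in range(5) for j in range(i + 1, 5)])


@pytest.fixture
def star5():
    return graph_from_edges(5, [(0, j) for j in range(1, 5)])


@pytest.fixture
def triangle():
    return graph_from_edges(3, [(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def two_disjoint_edges():
    return graph_from_edges(4, [(0, 1), (2, 3)])


@pytest.fixture
def triangle_pendant():
    return graph_from_edges(4, [(0, 1), (1, 2), (0, 2), (0, 3)])


@pytest.fixture
def empty4():
    return graph_from_edges(4, [])
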