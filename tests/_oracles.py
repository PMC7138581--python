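"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's code paths: distances come from
Floyd-Warshall (the package uses BFS), clustering from explicit
neighbor-pair enumeration, efficiencies from direct pair sums.
"""

import numpy as np


def fw_distances(adj):
    """All-pairs hop distances by Floyd-Warshall."""
    n = len(adj)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and adj[i][j]:
                dist[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    return dist


def oracle_global_efficiency(adj):
    n = len(adj)
    if n < 2:
        return 0.0
    dist = fw_distances(adj)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(dist[i, j]):
                total += 1.0 / dist[i, j]
    return total / (n * (n - 1))


def oracle_clustering(adj):
    """Nodal clustering by explicit neighbor-pair enumeration."""
    n = len(adj)
    c = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i][j]]
        k = len(nbrs)
        if k < 2:
            continue
        links = 0
        for a in range(k):
            for b in range(a + 1, k):
                if adj[nbrs[a]][nbrs[b]]:
                    links += 1
        c[i] = 2.0 * links / (k * (k - 1))
    return c, float(c.mean()) if n else 0.0


def oracle_local_efficiency(adj):
    n = len(adj)
    if n == 0:
        return 0.0
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i][j]]
        if len(nbrs) < 2:
            continue
        sub = np.asarray(adj)[np.ix_(nbrs, nbrs)]
        total += oracle_global_efficiency(sub)
    return total / n


def oracle_path_length(adj):
    """(mean finite pair distance, connected flag); None if no finite pair."""
    n = len(adj)
    dist = fw_distances(adj)
    finite, all_finite = [], True
    for i in range(n):
        for j in range(i + 1, n):
            if np.isfinite(dist[i, j]):
                finite.append(dist[i, j])
            else:
                all_finite = False
    if not finite:
        return None, False
    return float(np.mean(finite)), all_finite


def oracle_degrees(adj):
    return np.asarray(adj).sum(axis=1)
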