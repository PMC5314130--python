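"""Independent brute-force oracles for graph metrics.

Deliberately naive (O(N^3) and worse): triangle enumeration for
clustering, Floyd-Warshall for distances, exhaustive shortest-path
enumeration for betweenness, two-pass covariance for Pearson r.  Used
only to check the fast implementations on small graphs.
"""

from itertools import combinations

import numpy as np


def clustering_brute(adj):
    adj = np.asarray(adj, dtype=bool)
    n = adj.shape[0]
    per_node = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        triangles = sum(1 for u, v in combinations(nbrs, 2) if adj[u, v])
        per_node[i] = 2.0 * triangles / (k * (k - 1))
    return per_node, per_node.mean()


def floyd_warshall_paths(adj):
    """Distance matrix by Floyd-Warshall; inf where unreachable."""
    adj = np.asarray(adj, dtype=bool)
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    dist[adj] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    return dist


def path_length_brute(adj):
    dist = floyd_warshall_paths(adj)
    n = dist.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist) & off
    return dist[finite].mean(), int((off & ~finite).sum())


def _all_shortest_paths(adj, dist, s, t):
    """Enumerate every shortest s-t path as a node tuple."""
    if not np.isfinite(dist[s, t]):
        return []
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(tuple(path))
            return
        for v in np.flatnonzero(adj[u]):
            if dist[s, v] == dist[s, u] + 1 and dist[v, t] == dist[u, t] - 1:
                extend(path + [v])

    extend([s])
    return paths


def betweenness_brute(adj):
    """Betweenness by explicitly enumerating all shortest paths."""
    adj = np.asarray(adj, dtype=bool)
    n = adj.shape[0]
    dist = floyd_warshall_paths(adj)
    b = np.zeros(n)
    for s, t in combinations(range(n), 2):
        paths = _all_shortest_paths(adj, dist, s, t)
        if not paths:
            continue
        for path in paths:
            for node in path[1:-1]:
                b[node] += 1.0 / len(paths)
    return b


def pearson_two_pass(x, y):
    """Naive two-pass Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mx, my = x.mean(), y.mean()
    cov = ((x - mx) * (y - my)).sum()
    return cov / np.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())


def random_graph(rng, n_min=4, n_max=12):
    """A random connected-or-not test graph with at least one edge."""
    while True:
        n = int(rng.integers(n_min, n_max + 1))
        p = float(rng.uniform(0.15, 0.9))
        upper = rng.random((n, n)) < p
        adj = np.triu(upper, 1)
        adj = (adj | adj.T).astype(np.uint8)
        if adj.sum() > 0:
            return adj
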