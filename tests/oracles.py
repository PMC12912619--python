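"""Independent brute-force oracles for graph metrics.

Deliberately naive: Floyd–Warshall O(n^3) distances, betweenness by
exhaustive enumeration of every shortest path, efficiencies recomputed
from the Floyd–Warshall matrix.  Only usable on small graphs; the
implementations under test never call into this module.
"""

import itertools

import numpy as np


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def all_shortest_paths(adj: np.ndarray, s: int, t: int,
                       dist: np.ndarray) -> list[tuple[int, ...]]:
    """Every geodesic from s to t, by depth-first expansion."""
    if not np.isfinite(dist[s, t]):
        return []
    if s == t:
        return [(s,)]
    paths = []
    for v in np.flatnonzero(adj[s]):
        if dist[v, t] == dist[s, t] - 1:
            for tail in all_shortest_paths(adj, v, t, dist):
                paths.append((s,) + tail)
    return paths


def betweenness_bruteforce(adj: np.ndarray) -> np.ndarray:
    """Raw betweenness over unordered pairs by full path enumeration."""
    n = adj.shape[0]
    dist = floyd_warshall(adj)
    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = all_shortest_paths(adj, s, t, dist)
        if not paths:
            continue
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(v in p for p in paths)
            bc[v] += through / len(paths)
    return bc


def clustering_bruteforce(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    cc = np.zeros(n)
    for v in range(n):
        nb = np.flatnonzero(adj[v])
        k = len(nb)
        if k < 2:
            continue
        links = sum(adj[a, b] for a, b in itertools.combinations(nb, 2))
        cc[v] = 2 * links / (k * (k - 1))
    return cc


def global_efficiency_bruteforce(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        return 0.0
    d = floyd_warshall(adj)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def nodal_efficiency_bruteforce(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = floyd_warshall(adj)
    out = np.zeros(n)
    for v in range(n):
        for u in range(n):
            if u != v and np.isfinite(d[v, u]):
                out[v] += 1.0 / d[v, u]
        out[v] /= max(n - 1, 1)
    return out


def local_efficiency_bruteforce(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for v in range(n):
        nb = np.flatnonzero(adj[v])
        if len(nb) < 2:
            continue
        out[v] = global_efficiency_bruteforce(adj[np.ix_(nb, nb)])
    return out


def path_length_bruteforce(adj: np.ndarray) -> float:
    d = floyd_warshall(adj)
    n = adj.shape[0]
    vals = [d[i, j] for i in range(n) for j in range(n)
            if i != j and np.isfinite(d[i, j])]
    return float(np.mean(vals)) if vals else float("nan")
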