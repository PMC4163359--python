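"""Independent brute-force reference implementations for the centrality
measures: Floyd-Warshall distances, explicit shortest-path enumeration for
betweenness, dense eigendecomposition for eigenvector centrality, and a
direct triple loop for Burt's constraint.  Deliberately naive and kept
separate from the package's algorithms."""

from __future__ import annotations

import numpy as np

TOL = 1e-9


def length_matrix(adj: np.ndarray, weighted: bool) -> np.ndarray:
    lengths = np.full(adj.shape, np.inf)
    mask = adj > 0
    lengths[mask] = 1.0 / adj[mask] if weighted else 1.0
    return lengths


def bf_distance_matrix(lengths: np.ndarray) -> np.ndarray:
    """Floyd-Warshall (a different algorithm family than Dijkstra)."""
    dist = lengths.copy()
    np.fill_diagonal(dist, 0.0)
    n = dist.shape[0]
    for k in range(n):
        dist = np.minimum(dist, dist[:, k][:, None] + dist[k][None, :])
    return dist


def _enumerate_shortest_paths(lengths, dist, s, t):
    """All shortest s-t paths as node lists, by pruned DFS (A*-style:
    abandon any prefix that can no longer reach t at the shortest length)."""
    target = dist[s, t]
    if not np.isfinite(target):
        return []
    n = lengths.shape[0]
    paths = []

    def rec(node, acc, path):
        if node == t:
            if abs(acc - target) <= TOL * max(1.0, target):
                paths.append(list(path))
            return
        for nb in range(n):
            if np.isfinite(lengths[node, nb]) and nb not in path:
                new = acc + lengths[node, nb]
                if new + dist[nb, t] <= target + TOL * max(1.0, target):
                    path.append(nb)
                    rec(nb, new, path)
                    path.pop()

    rec(s, 0.0, [s])
    return paths


def bf_betweenness(adj: np.ndarray, weighted: bool) -> np.ndarray:
    lengths = length_matrix(adj, weighted)
    dist = bf_distance_matrix(lengths)
    n = adj.shape[0]
    values = np.zeros(n)
    for h in range(n):
        for j in range(h + 1, n):
            paths = _enumerate_shortest_paths(lengths, dist, h, j)
            if not paths:
                continue
            for path in paths:
                for i in path[1:-1]:
                    values[i] += 1.0 / len(paths)
    return values


def bf_closeness(adj: np.ndarray, weighted: bool) -> np.ndarray:
    dist = bf_distance_matrix(length_matrix(adj, weighted))
    n = adj.shape[0]
    values = np.zeros(n)
    for i in range(n):
        d = np.delete(dist[i], i)
        finite = d[np.isfinite(d)]
        if finite.size:
            values[i] = finite.size / finite.sum()
    return values


def bf_eigenvector(adj: np.ndarray, gap_tol: float = 1e-8):
    """Leading eigenvector via dense eigendecomposition, max-normalized.

    Returns None when the leading eigenvalue is (near-)degenerate, where the
    normalized eigenvector is not unique.
    """
    if not adj.any():
        return np.zeros(adj.shape[0])
    w, v = np.linalg.eigh(adj)
    if adj.shape[0] > 1 and w[-1] - w[-2] < gap_tol:
        return None
    vec = v[:, -1]
    if vec.sum() < 0:
        vec = -vec
    vec = np.clip(vec, 0.0, None)  # Perron vector; clip -0.0 noise
    return vec / vec.max()


def bf_burt(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    values = np.zeros(n)
    strength = adj.sum(axis=1)
    for i in range(n):
        if strength[i] == 0:
            continue
        total = 0.0
        for j in range(n):
            if adj[i, j] <= 0 or j == i:
                continue
            p_ij = adj[i, j] / strength[i]
            indirect = 0.0
            for q in range(n):
                if q in (i, j) or adj[i, q] <= 0 or strength[q] == 0:
                    continue
                indirect += (adj[i, q] / strength[i]) * (adj[q, j] / strength[q])
            total += (p_ij + indirect) ** 2
        values[i] = total
    return values


def random_graph(rng: np.random.Generator, n: int, p: float, weighted: bool) -> np.ndarray:
    """Symmetric ER adjacency, optionally with U(0.2, 1) weights."""
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, k=1).astype(float)
    if weighted:
        adj *= rng.uniform(0.2, 1.0, size=(n, n))
    adj = adj + adj.T
    return adj
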