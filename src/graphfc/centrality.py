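"""Node centrality measures on subject connectivity graphs.

Implements the five measures used as classifier features: degree (strength
on weighted graphs), closeness, betweenness, eigenvector centrality, and
Burt's constraint.  Degree, closeness, and betweenness are computed on both
the weighted graph and the three binarized graphs; eigenvector centrality
and Burt's constraint are defined on the weighted graph only, giving the
full battery of 5 + 3 x 3 = 14 feature vectors per subject.

Conventions (the field leaves several free; all are fixed here and
documented in docs/methods.md):

* Weighted shortest paths use edge length ``1/weight`` — correlations are
  similarities, path algorithms need costs.
* Closeness of node i is ``|R(i)| / sum_{j in R(i)} d(i, j)`` over the set
  R(i) of nodes reachable from i (excluding i): the reciprocal mean distance
  to reachable nodes.  Isolated nodes get 0.
* Betweenness is the unnormalized Freeman/Brandes sum of fractional
  shortest-path counts ``rho_hj(i) / rho_hj`` over pairs h < j, endpoints
  excluded.  Distances come from Dijkstra (scipy's csgraph); path counting
  and dependency accumulation run in topological (distance) order via
  triangular solves, which is Brandes' recursion in matrix form.
* Eigenvector centrality is the leading eigenvector of the adjacency matrix,
  by power iteration (uniform start, sup-norm tolerance 1e-10, at most 1000
  iterations) on the diagonally shifted matrix ``A + 0.1 max_i s_i I`` —
  the shift leaves eigenvectors untouched but guarantees the Perron vector
  strictly dominates even on bipartite components, where unshifted power
  iteration oscillates.  Output rescaled so the maximum entry is 1.
* Burt's constraint of i is ``sum_{j in N(i)} (p_ij + sum_{q} p_iq p_qj)^2``
  with ``p_ij = a_ij / sum_k a_ik`` the proportional investment; isolated
  nodes get 0 with a degeneracy flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular
from scipy.sparse import csr_array
from scipy.sparse.csgraph import shortest_path

from .connectivity import BinaryGraph, WeightedGraph

__all__ = [
    "WEIGHTED_MEASURES",
    "UNWEIGHTED_MEASURES",
    "CentralityVector",
    "degree",
    "closeness",
    "betweenness",
    "eigenvector_centrality",
    "burt_constraint",
    "centrality_profile",
    "profile_frame",
]

WEIGHTED_MEASURES = ("degree", "closeness", "betweenness", "eigenvector", "burt")
UNWEIGHTED_MEASURES = ("degree", "closeness", "betweenness")

_PATH_TOL = 1e-9


@dataclass(frozen=True)
class CentralityVector:
    """One centrality measure evaluated at every node of one graph."""

    values: np.ndarray
    measure: str
    graph_kind: str  # "weighted" | "unweighted"
    cutoff: float | None = None
    degenerate: np.ndarray | None = None  # per-node flags (Burt isolates)


def _adjacency(graph):
    if isinstance(graph, WeightedGraph):
        return np.asarray(graph.adjacency, dtype=float), True, None
    if isinstance(graph, BinaryGraph):
        return np.asarray(graph.adjacency, dtype=float), False, graph.cutoff
    raise TypeError(f"expected WeightedGraph or BinaryGraph, got {type(graph).__name__}")


def _kind(weighted: bool) -> str:
    return "weighted" if weighted else "unweighted"


def _length_matrix(adj: np.ndarray, weighted: bool) -> np.ndarray:
    lengths = np.full(adj.shape, np.inf)
    mask = adj > 0
    lengths[mask] = 1.0 / adj[mask] if weighted else 1.0
    return lengths


def _distance_matrix(adj: np.ndarray, weighted: bool) -> np.ndarray:
    n = adj.shape[0]
    mask = adj > 0
    if not mask.any():
        dist = np.full((n, n), np.inf)
        np.fill_diagonal(dist, 0.0)
        return dist
    rows, cols = np.nonzero(mask)
    data = 1.0 / adj[rows, cols] if weighted else np.ones(rows.size)
    sparse = csr_array((data, (rows, cols)), shape=adj.shape)
    return shortest_path(sparse, method="D", directed=False)


def degree(graph) -> CentralityVector:
    """Edge count (unweighted) or strength = weight sum (weighted)."""
    adj, weighted, cutoff = _adjacency(graph)
    return CentralityVector(adj.sum(axis=1).astype(float), "degree", _kind(weighted), cutoff)


def closeness(graph) -> CentralityVector:
    adj, weighted, cutoff = _adjacency(graph)
    dist = _distance_matrix(adj, weighted)
    finite = np.isfinite(dist)
    np.fill_diagonal(finite, False)
    n_reach = finite.sum(axis=1)
    total = np.where(finite, dist, 0.0).sum(axis=1)
    values = np.zeros(adj.shape[0])
    ok = n_reach > 0
    values[ok] = n_reach[ok] / total[ok]
    return CentralityVector(values, "closeness", _kind(weighted), cutoff)


def betweenness(graph) -> CentralityVector:
    """Brandes-style betweenness: for each source, shortest-path counts and
    dependencies are propagated through the (distance-ordered) predecessor
    DAG with unit-triangular solves."""
    adj, weighted, cutoff = _adjacency(graph)
    n = adj.shape[0]
    values = np.zeros(n)
    if n > 2 and adj.any():
        lengths = _length_matrix(adj, weighted)
        dist = _distance_matrix(adj, weighted)
        for s in range(n):
            d = dist[s]
            order = np.flatnonzero(np.isfinite(d))
            order = order[np.argsort(d[order], kind="stable")]
            k = order.size
            if k < 3:
                continue
            dd = d[order]
            sub_len = lengths[np.ix_(order, order)]
            # pred[u, v]: edge (u, v) lies on a shortest path from s to v
            pred = np.abs(dd[:, None] + sub_len - dd[None, :]) <= _PATH_TOL * np.maximum(1.0, dd[None, :])
            pred &= np.isfinite(sub_len)
            pred &= dd[:, None] < dd[None, :]  # strictly upper triangular in `order`
            e0 = np.zeros(k)
            e0[0] = 1.0
            sigma = solve_triangular(np.eye(k) - pred.T, e0, lower=True, unit_diagonal=True)
            ratio = pred * (sigma[:, None] / sigma[None, :])
            delta = solve_triangular(
                np.eye(k) - ratio, ratio.sum(axis=1), lower=False, unit_diagonal=True
            )
            values[order[1:]] += delta[1:]
        values /= 2.0  # undirected: each pair visited from both endpoints
        values[np.abs(values) < 1e-12] = 0.0
    return CentralityVector(values, "betweenness", _kind(weighted), cutoff)


def eigenvector_centrality(graph: WeightedGraph, tol: float = 1e-10, max_iter: int = 1000) -> CentralityVector:
    """Leading eigenvector of the weighted adjacency, max-normalized to 1."""
    if not isinstance(graph, WeightedGraph):
        raise TypeError("eigenvector centrality is defined on weighted graphs only")
    adj = np.asarray(graph.adjacency, dtype=float)
    n = adj.shape[0]
    if n == 0 or not adj.any():
        return CentralityVector(np.zeros(n), "eigenvector", "weighted")
    shift = 0.1 * adj.sum(axis=1).max()
    x = np.full(n, 1.0 / n)
    residual = np.inf
    for _ in range(max_iter):
        y = adj @ x + shift * x
        y /= y.max()
        residual = float(np.max(np.abs(y - x)))
        x = y
        if residual < tol:
            break
    else:
        raise RuntimeError(
            f"power iteration did not converge within {max_iter} iterations "
            f"(last sup-norm residual {residual:.3e})"
        )
    return CentralityVector(x / x.max(), "eigenvector", "weighted")


def burt_constraint(graph: WeightedGraph) -> CentralityVector:
    """Burt's constraint from investment proportions p_ij = a_ij / strength_i."""
    if not isinstance(graph, WeightedGraph):
        raise TypeError("Burt's constraint is defined on weighted graphs only")
    adj = np.asarray(graph.adjacency, dtype=float)
    strength = adj.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(strength[:, None] > 0, adj / strength[:, None], 0.0)
    indirect = p @ p  # (q = i and q = j terms vanish: zero diagonal)
    contrib = (p + indirect) ** 2
    values = np.where(strength > 0, (contrib * (adj > 0)).sum(axis=1), 0.0)
    return CentralityVector(values, "burt", "weighted", degenerate=strength == 0)


_DISPATCH = {
    "degree": degree,
    "closeness": closeness,
    "betweenness": betweenness,
    "eigenvector": eigenvector_centrality,
    "burt": burt_constraint,
}


def centrality_profile(weighted_graph=None, binary_graphs=(), measures=None) -> list[CentralityVector]:
    """The full per-subject measure battery.

    With the default measure set and one weighted plus three binary graphs
    this yields 14 vectors: 5 weighted measures and 3 unweighted measures
    at each cut-off.  ``measures`` restricts the battery by name; unknown
    names are rejected.
    """
    if measures is None:
        measures = WEIGHTED_MEASURES
    measures = tuple(measures)
    unknown = set(measures) - set(WEIGHTED_MEASURES)
    if unknown:
        raise ValueError(f"unknown centrality measure(s): {sorted(unknown)}")
    out: list[CentralityVector] = []
    if weighted_graph is not None:
        for m in measures:
            out.append(_DISPATCH[m](weighted_graph))
    for bg in binary_graphs:
        for m in measures:
            if m in UNWEIGHTED_MEASURES:
                out.append(_DISPATCH[m](bg))
    return out


def profile_frame(profile: list[CentralityVector], subject_id: str):
    """Tidy per-subject centrality table: one row per (measure, graph, ROI)."""
    import pandas as pd

    rows = []
    for vec in profile:
        for roi, value in enumerate(vec.values):
            rows.append(
                {"subject_id": subject_id, "measure": vec.measure,
                 "graph_kind": vec.graph_kind, "cutoff": vec.cutoff,
                 "roi_index": roi, "value": float(value)}
            )
    return pd.DataFrame(rows)
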