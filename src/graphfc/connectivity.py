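"""Subject-level connectivity: Pearson correlation graphs over ROIs.

Each subject's (timepoints x ROIs) series becomes a symmetric ROI x ROI
Pearson correlation matrix, read in two ways: as the adjacency of an
undirected *weighted* graph (negative correlations clipped to zero, see
below) and as three *binary* graphs obtained by thresholding the raw
correlations at the cut-offs 0.1, 0.15 and 0.25.

Conventions fixed project-wide:

* Negative correlations are excluded from the weighted graph (clipped to 0).
  Eigenvector centrality and Burt's constraint require nonnegative weights
  for their Perron-Frobenius / investment-proportion interpretations, and
  positive cut-offs imply positive-correlation edges.  The number of clipped
  entries is recorded on the graph so the convention is auditable.
* Binarization uses a strict ``r > cutoff`` test, which makes the three edge
  sets nested: every edge at 0.25 is present at 0.15, and so on.
* No Fisher z-transform and no absolute-value transform before thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "CUTOFFS",
    "ConnectivityMatrix",
    "WeightedGraph",
    "BinaryGraph",
    "correlation_matrix",
    "to_weighted_graph",
    "binarize",
    "edge_list",
    "write_edge_list",
    "write_matrix",
    "read_matrix",
]

#: The three binarization cut-offs applied to every subject.
CUTOFFS = (0.1, 0.15, 0.25)


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric ROI x ROI Pearson correlation matrix with unit diagonal."""

    values: np.ndarray
    roi_ids: tuple | None = None

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class WeightedGraph:
    """Undirected nonnegative-weight graph; ``n_clipped`` counts the
    unordered ROI pairs whose negative correlation was clipped to zero."""

    adjacency: np.ndarray
    n_clipped: int = 0

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


@dataclass(frozen=True)
class BinaryGraph:
    """Undirected 0/1 graph from thresholding correlations at ``cutoff``."""

    adjacency: np.ndarray
    cutoff: float

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


def correlation_matrix(timeseries, roi_ids=None) -> ConnectivityMatrix:
    """Pearson correlation between every pair of ROI time series.

    Requires at least 3 timepoints and no constant column; a constant column
    is rejected naming the offending ROI index.  The result is symmetrized
    and its diagonal set to exactly 1.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError("timeseries must be a 2-d (timepoints x ROIs) matrix")
    if ts.shape[0] < 3:
        raise ValueError("need at least 3 timepoints to estimate correlations")
    constant = np.flatnonzero(np.ptp(ts, axis=0) == 0)
    if constant.size:
        raise ValueError(
            f"ROI {int(constant[0])} has a constant time series; "
            "Pearson correlation is undefined"
        )
    r = np.corrcoef(ts, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(r, tuple(roi_ids) if roi_ids is not None else None)


def to_weighted_graph(cm: ConnectivityMatrix) -> WeightedGraph:
    """Correlation matrix as weighted adjacency: zero diagonal, negatives
    clipped to 0, positive entries preserved exactly."""
    values = np.asarray(cm.values, dtype=float)
    adj = values.copy()
    np.fill_diagonal(adj, 0.0)
    iu = np.triu_indices_from(adj, k=1)
    n_clipped = int(np.count_nonzero(adj[iu] < 0))
    adj[adj < 0] = 0.0
    return WeightedGraph(adj, n_clipped)


def binarize(cm: ConnectivityMatrix, cutoff: float) -> BinaryGraph:
    """0/1 adjacency with an edge wherever ``r_ij > cutoff`` (strict), i != j."""
    cutoff = float(cutoff)
    if not 0.0 < cutoff < 1.0:
        raise ValueError(f"cutoff must lie in (0, 1), got {cutoff}")
    adj = (np.asarray(cm.values, dtype=float) > cutoff).astype(np.int8)
    np.fill_diagonal(adj, 0)
    return BinaryGraph(adj, cutoff)


def edge_list(graph: BinaryGraph) -> np.ndarray:
    """Undirected edges as an (m, 2) array of 0-based ROI indices, i < j."""
    i, j = np.nonzero(np.triu(graph.adjacency, k=1))
    return np.column_stack([i, j])


def write_edge_list(graph: BinaryGraph, path) -> Path:
    path = Path(path)
    np.savetxt(path, edge_list(graph), fmt="%d")
    return path


def write_matrix(matrix: np.ndarray, path) -> Path:
    """Plain whitespace-delimited numeric matrix, one row per line."""
    path = Path(path)
    np.savetxt(path, np.asarray(matrix, dtype=float), fmt="%.10g")
    return path


def read_matrix(path) -> np.ndarray:
    return np.loadtxt(path, ndmin=2)
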