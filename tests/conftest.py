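import numpy as np
import pytest

from graphfc import BinaryGraph, CohortSpec, SiteSpec, WeightedGraph


def weighted_from_edges(n, edges):
    """WeightedGraph from (i, j, w) triples."""
    adj = np.zeros((n, n))
    for i, j, w in edges:
        adj[i, j] = adj[j, i] = w
    return WeightedGraph(adj)


def binary_from_edges(n, edges, cutoff=0.1):
    adj = np.zeros((n, n), dtype=np.int8)
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1
    return BinaryGraph(adj, cutoff)


@pytest.fixture
def star5():
    """Star K_{1,4} with unit weights, center node 0."""
    return weighted_from_edges(5, [(0, k, 1.0) for k in range(1, 5)])


@pytest.fixture
def tiny_cohort_spec():
    """Two sites, 100 ROIs, strong planted effect: fast end-to-end fixture."""
    return CohortSpec(
        n_rois=100,
        n_timepoints=120,
        sites=(
            SiteSpec("siteA", {"control": 6, "inattentive": 4, "combined": 4}, 0.4, 120),
            SiteSpec("siteB", {"control": 6, "inattentive": 4, "combined": 4}, 0.6, 100),
        ),
        n_modules=4,
        within_module_corr=0.35,
        between_module_corr=0.05,
        effect_nodes=tuple(range(0, 100, 10)),
        effect_size=0.3,
        seed=7,
    )
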