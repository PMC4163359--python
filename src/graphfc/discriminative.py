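"""Discriminative-node maps from linear-SVM hyperplane coefficients.

The decision function of a linear SVM is a hyperplane whose per-feature
coefficients quantify how much each ROI contributes to separating the two
groups.  After training on *all* subjects (not the leave-one-out folds),
ROIs are ranked by the absolute value of their coefficient — in the
standardized feature space, so that feature scale does not masquerade as
importance — and the top 5% (ceil(0.05 n), i.e. 20 of 400) form the
discriminative map.  Maps are conventionally emitted only for
classifications whose balanced score clears a reporting gate (0.70 by
default); the gate is metadata at the reporting layer, not part of the
ranking itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .classify import FeatureTable, _train_scaler

__all__ = [
    "DiscriminativeMap",
    "fit_full_and_extract_weights",
    "top_fraction",
    "export_map",
]


@dataclass(frozen=True)
class DiscriminativeMap:
    """Hyperplane weights with the |weight|-ranked node ordering and the
    selected top-fraction node set."""

    weights: np.ndarray
    ranking: np.ndarray  # permutation of 0..n-1, |weight| descending
    selected: np.ndarray  # first ceil(fraction * n) entries of ranking
    fraction: float
    task: str | None = None
    scope: str | None = None
    measure: str | None = None
    graph_kind: str | None = None
    cutoff: float | None = None
    score: float | None = None
    passed_gate: bool | None = None


def fit_full_and_extract_weights(table: FeatureTable, regularization: float = 1.0):
    """Train on all subjects; return (weights, degenerate_flag).

    Standardization and C match the cross-validated classifier.  A table
    that cannot produce a separating direction (constant labels, or
    identical rows so the fit collapses to the intercept) yields all-zero
    weights with the degeneracy flag set.
    """
    labels = np.asarray(table.labels)
    if np.unique(labels).size < 2:
        return np.zeros(table.matrix.shape[1]), True
    mu, sd = _train_scaler(table.matrix)
    clf = SVC(kernel="linear", C=regularization)
    clf.fit((table.matrix - mu) / sd, labels)
    weights = np.asarray(clf.coef_).ravel()
    degenerate = not np.any(np.abs(weights) > 0)
    return weights, degenerate


def top_fraction(weights, fraction: float = 0.05, *, score: float | None = None,
                 score_gate: float = 0.70, **meta) -> DiscriminativeMap:
    """Rank nodes by |weight| (ties broken by ascending index) and select
    the top ``ceil(fraction * n)``.

    All-zero weight vectors are rejected — there is nothing to rank.  When a
    classification ``score`` is supplied, ``passed_gate`` records whether it
    clears ``score_gate`` (the reporting convention for emitting maps).
    """
    weights = np.asarray(weights, dtype=float)
    if weights.ndim != 1 or weights.size == 0:
        raise ValueError("weights must be a non-empty 1-d vector")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if not np.any(np.abs(weights) > 0):
        raise ValueError("all-zero weight vector: nothing to rank")
    n = weights.size
    ranking = np.lexsort((np.arange(n), -np.abs(weights)))
    k = math.ceil(fraction * n)
    passed = None if score is None else bool(score >= score_gate)
    return DiscriminativeMap(
        weights=weights, ranking=ranking, selected=ranking[:k].copy(),
        fraction=fraction, score=score, passed_gate=passed, **meta,
    )


def export_map(dmap: DiscriminativeMap, path, atlas_labels=None,
               parcellation=None, out_image=None) -> Path:
    """Write the selected-node table as CSV (rank, roi_index, weight,
    abs_weight[, atlas_label]).

    If a ``parcellation`` (integer-labelled NIfTI volume, label l for ROI
    l-1) is supplied together with ``out_image``, additionally writes a
    volume in which each selected ROI carries its rank and everything else
    is 0.  Atlas/ROI-count mismatches are rejected.
    """
    n = dmap.weights.size
    if atlas_labels is not None and len(atlas_labels) != n:
        raise ValueError(
            f"atlas has {len(atlas_labels)} labels but the map covers {n} ROIs"
        )
    rows = []
    for rank, roi in enumerate(dmap.selected, start=1):
        row = {"rank": rank, "roi_index": int(roi),
               "weight": float(dmap.weights[roi]),
               "abs_weight": float(abs(dmap.weights[roi]))}
        if atlas_labels is not None:
            row["atlas_label"] = atlas_labels[roi]
        rows.append(row)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)
    if parcellation is not None:
        if out_image is None:
            raise ValueError("out_image is required when a parcellation is given")
        import nibabel as nib  # optional neuroimaging dependency

        img = nib.load(str(parcellation))
        data = np.asarray(img.dataobj).astype(np.int32)
        if int(data.max()) != n:
            raise ValueError(
                f"parcellation has {int(data.max())} labels but the map covers {n} ROIs"
            )
        out = np.zeros_like(data)
        for rank, roi in enumerate(dmap.selected, start=1):
            out[data == int(roi) + 1] = rank
        nib.save(nib.Nifti1Image(out, img.affine, img.header), str(out_image))
    return path
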