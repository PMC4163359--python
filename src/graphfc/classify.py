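"""Leave-one-subject-out linear-SVM classification of centrality features.

One :class:`FeatureTable` holds the subjects x ROIs matrix of a single
centrality measure under a single graph configuration, for one of two tasks:

* ``control_vs_adhd`` — typically developing controls against all ADHD
  patients (positive class ``adhd``);
* ``inattentive_vs_combined`` — ADHD subtypes (positive class ``combined``).

Accuracy is estimated by leave-one-subject-out cross-validation of a linear
maximum-margin classifier (SVM, fixed C, never tuned on test folds).
Features are standardized per fold using training-fold statistics only; the
held-out row is transformed with those statistics, so no information leaks
from the held-out subject into the scaler.  Results are summarized as
sensitivity (positive-class recall), specificity (negative-class recall) and
the balanced score ``(sensitivity + specificity) / 2``, which is robust to
the strong class imbalance typical of these cohorts.  Percentages are
reported rounded half away from zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

__all__ = [
    "TASKS",
    "InfeasibleTaskError",
    "FeatureTable",
    "ClassificationResult",
    "build_feature_table",
    "loocv_classify",
    "confusion_stats",
    "balanced_score",
    "percent",
    "results_to_frame",
]

#: task -> (groups mapped to the positive label, groups mapped to the
#: negative label, positive label, negative label)
TASKS = {
    "control_vs_adhd": (("inattentive", "combined"), ("control",), "adhd", "control"),
    "inattentive_vs_combined": (("combined",), ("inattentive",), "combined", "inattentive"),
}


class InfeasibleTaskError(ValueError):
    """A requested (task, scope) cell has an empty class and cannot be trained."""


@dataclass(frozen=True)
class FeatureTable:
    """Subjects x ROIs features for one measure/graph configuration."""

    matrix: np.ndarray
    labels: np.ndarray
    sites: np.ndarray
    positive_class: str
    negative_class: str
    task: str | None = None
    scope: str | None = None
    measure: str | None = None
    graph_kind: str | None = None
    cutoff: float | None = None

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class ClassificationResult:
    """Per-fold predictions plus the sensitivity/specificity/score triple."""

    predictions: tuple
    sensitivity: float
    specificity: float
    score: float
    task: str | None = None
    scope: str | None = None
    measure: str | None = None
    graph_kind: str | None = None
    cutoff: float | None = None
    n_pos: int = 0
    n_neg: int = 0

    def __post_init__(self):
        if abs(self.score - (self.sensitivity + self.specificity) / 2.0) > 1e-12:
            raise ValueError("score must equal (sensitivity + specificity) / 2")


def build_feature_table(cohort, features, *, measure, graph_kind, cutoff=None,
                        task, scope="all") -> FeatureTable:
    """Assemble the classifier input for one grid cell.

    ``cohort`` is a sequence of subject records (``subject_id``, ``site``,
    ``group`` attributes); ``features`` maps subject_id to a dict keyed by
    ``(measure, graph_kind, cutoff)`` holding that subject's centrality
    vector.  Subjects are selected by task and scope in cohort order; a
    class that is empty within the scope is rejected (as happens for the
    subtype task at sites with no combined subjects).
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {sorted(TASKS)}")
    pos_groups, neg_groups, pos_label, neg_label = TASKS[task]
    key = (measure, graph_kind, None if graph_kind == "weighted" else cutoff)
    rows, labels, sites = [], [], []
    for rec in cohort:
        if scope != "all" and rec.site != scope:
            continue
        if rec.group in pos_groups:
            label = pos_label
        elif rec.group in neg_groups:
            label = neg_label
        else:
            continue
        rows.append(np.asarray(features[rec.subject_id][key], dtype=float))
        labels.append(label)
        sites.append(rec.site)
    labels = np.asarray(labels)
    for cls in (pos_label, neg_label):
        if not np.any(labels == cls):
            raise InfeasibleTaskError(
                f"task {task!r} in scope {scope!r}: class {cls!r} has no subjects"
            )
    return FeatureTable(
        matrix=np.vstack(rows), labels=labels, sites=np.asarray(sites),
        positive_class=pos_label, negative_class=neg_label,
        task=task, scope=scope, measure=measure, graph_kind=graph_kind,
        cutoff=None if graph_kind == "weighted" else cutoff,
    )


def _train_scaler(x_train: np.ndarray):
    """Mean/sd of the training fold only; zero-variance features get sd 1."""
    mu = x_train.mean(axis=0)
    sd = x_train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return mu, sd


def _loocv_fold(matrix: np.ndarray, labels: np.ndarray, held_out: int, C: float):
    """Prediction for one held-out subject; returns (label, (mu, sd) or None).

    A single-class training fold degenerates to predicting that class, which
    keeps the LOOCV total equal to n under extreme class imbalance.
    """
    mask = np.ones(len(labels), dtype=bool)
    mask[held_out] = False
    x_train, y_train = matrix[mask], labels[mask]
    classes = np.unique(y_train)
    if classes.size == 1:
        return classes[0], None
    mu, sd = _train_scaler(x_train)
    clf = SVC(kernel="linear", C=C)
    clf.fit((x_train - mu) / sd, y_train)
    pred = clf.predict(((matrix[held_out] - mu) / sd)[None, :])[0]
    return pred, (mu, sd)


def loocv_classify(table: FeatureTable, regularization: float = 1.0) -> ClassificationResult:
    """Leave-one-subject-out cross-validation of the linear max-margin model."""
    preds = [
        _loocv_fold(table.matrix, table.labels, i, regularization)[0]
        for i in range(table.n_subjects)
    ]
    preds = np.asarray(preds)
    sens, spec = confusion_stats(preds, table.labels, table.positive_class)
    return ClassificationResult(
        predictions=tuple(preds), sensitivity=sens, specificity=spec,
        score=balanced_score(sens, spec),
        task=table.task, scope=table.scope, measure=table.measure,
        graph_kind=table.graph_kind, cutoff=table.cutoff,
        n_pos=int(np.sum(table.labels == table.positive_class)),
        n_neg=int(np.sum(table.labels == table.negative_class)),
    )


def confusion_stats(predicted, actual, positive_class) -> tuple[float, float]:
    """(sensitivity, specificity) = (TP/(TP+FN), TN/(TN+FP))."""
    predicted = np.asarray(predicted)
    actual = np.asarray(actual)
    if predicted.shape != actual.shape:
        raise ValueError("predicted and actual label vectors differ in length")
    pos = actual == positive_class
    if not pos.any() or pos.all():
        raise ValueError(
            f"both classes must appear in the actual labels (positive={positive_class!r})"
        )
    sensitivity = float(np.mean(predicted[pos] == positive_class))
    specificity = float(np.mean(predicted[~pos] != positive_class))
    return sensitivity, specificity


def balanced_score(sensitivity: float, specificity: float) -> float:
    """The headline metric: (sensitivity + specificity) / 2."""
    for name, value in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {value}")
    return (sensitivity + specificity) / 2.0


def percent(fraction: float) -> int:
    """Fraction as an integer percent, rounded half away from zero
    (so 0.765 reports as 77, not banker's 76)."""
    scaled = fraction * 100.0
    return int(math.floor(scaled + 0.5)) if scaled >= 0 else int(math.ceil(scaled - 0.5))


def results_to_frame(results) -> pd.DataFrame:
    """Long-format results table (the machine-readable analogue of the
    per-site score tables): one row per ClassificationResult."""
    rows = [
        {"task": r.task, "scope": r.scope, "measure": r.measure,
         "graph_kind": r.graph_kind, "cutoff": r.cutoff,
         "spec": r.specificity, "sens": r.sensitivity, "score": r.score,
         "n_pos": r.n_pos, "n_neg": r.n_neg}
        for r in results
    ]
    return pd.DataFrame(rows)
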