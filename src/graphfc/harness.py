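"""End-to-end experiment grid: tasks x measures x graphs x scopes.

One :class:`ExperimentConfig` drives the full analysis: a cohort (synthetic
spec or on-disk manifest) is turned into per-subject connectivity graphs and
the 14-vector centrality battery, then every (task, measure, graph kind,
cut-off, scope) cell is classified by leave-one-subject-out linear SVM —
site by site and pooled across sites — and the grid is written as a
long-format CSV.  Infeasible cells (a class empty within a site, as happens
for the subtype task at sites with almost no combined subjects) are
recorded as explicit skips rather than dropped, so grids stay auditable.

All randomness lives in the cohort seed: identical configs produce
byte-identical result files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .centrality import UNWEIGHTED_MEASURES, WEIGHTED_MEASURES, centrality_profile
from .classify import (
    InfeasibleTaskError,
    build_feature_table,
    loocv_classify,
)
from .connectivity import CUTOFFS, binarize, correlation_matrix, to_weighted_graph
from .discriminative import export_map, fit_full_and_extract_weights, top_fraction
from .synthetic import CohortSpec, cohort_spec_from_dict, cohort_spec_to_dict, read_cohort, simulate_cohort

__all__ = [
    "ExperimentConfig",
    "ResultsGrid",
    "measure_configs",
    "subject_features",
    "run_experiment",
    "mean_vs_pooled",
    "make_maps",
    "config_from_yaml",
]

logger = logging.getLogger("graphfc")

_GRID_COLUMNS = ["task", "scope", "measure", "graph_kind", "cutoff",
                 "spec", "sens", "score", "n_pos", "n_neg", "status", "reason"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one grid run."""

    cohort: CohortSpec | str | Path
    cutoffs: tuple = CUTOFFS
    measures: tuple | None = None  # None -> full five-measure battery
    tasks: tuple = ("control_vs_adhd", "inattentive_vs_combined")
    scopes: tuple | None = None  # None -> every site plus "all"
    regularization: float = 1.0
    map_score_gate: float = 0.70
    top_fraction: float = 0.05
    out_dir: str | Path = "graphfc-results"

    def validate(self) -> None:
        for c in self.cutoffs:
            if not 0.0 < c < 1.0:
                raise ValueError(f"cutoff {c} outside (0, 1)")
        if not 0.0 < self.top_fraction <= 1.0:
            raise ValueError("top_fraction must lie in (0, 1]")


@dataclass
class ResultsGrid:
    """A grid run's long-format results plus the caches needed for maps."""

    frame: pd.DataFrame
    cohort: list
    features: dict
    config: ExperimentConfig


def measure_configs(config: ExperimentConfig) -> list[tuple]:
    """(measure, graph_kind, cutoff) cells: 5 weighted + 3 x cutoffs = 14."""
    wanted = config.measures
    cells = []
    for m in WEIGHTED_MEASURES:
        if wanted is None or m in wanted:
            cells.append((m, "weighted", None))
    for c in config.cutoffs:
        for m in UNWEIGHTED_MEASURES:
            if wanted is None or m in wanted:
                cells.append((m, "unweighted", c))
    return cells


def subject_features(record, cutoffs=CUTOFFS, measures=None) -> dict:
    """Connectivity + centrality for one subject, keyed by
    (measure, graph_kind, cutoff)."""
    cm = correlation_matrix(record.timeseries)
    weighted = to_weighted_graph(cm)
    binaries = [binarize(cm, c) for c in cutoffs]
    out = {}
    for vec in centrality_profile(weighted, binaries, measures):
        out[(vec.measure, vec.graph_kind, vec.cutoff)] = vec.values
    return out


def _resolve_cohort(source):
    if isinstance(source, CohortSpec):
        return simulate_cohort(source)
    return read_cohort(source)


def _config_hash(config: ExperimentConfig) -> str:
    payload = {
        "cohort": cohort_spec_to_dict(config.cohort)
        if isinstance(config.cohort, CohortSpec) else str(config.cohort),
        "cutoffs": list(config.cutoffs),
        "measures": None if config.measures is None else list(config.measures),
        "tasks": list(config.tasks),
        "scopes": None if config.scopes is None else list(config.scopes),
        "regularization": config.regularization,
        "map_score_gate": config.map_score_gate,
        "top_fraction": config.top_fraction,
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def run_experiment(config: ExperimentConfig) -> ResultsGrid:
    """Execute the full grid; writes ``results.csv`` and ``run.log``."""
    config.validate()
    t0 = time.perf_counter()
    cohort = _resolve_cohort(config.cohort)
    features = {
        rec.subject_id: subject_features(rec, config.cutoffs, config.measures)
        for rec in cohort
    }
    t_features = time.perf_counter() - t0
    sites = sorted({rec.site for rec in cohort})
    scopes = tuple(config.scopes) if config.scopes is not None else tuple(sites) + ("all",)
    rows = []
    for task in config.tasks:
        for measure, kind, cutoff in measure_configs(config):
            for scope in scopes:
                cell = {"task": task, "scope": scope, "measure": measure,
                        "graph_kind": kind, "cutoff": cutoff}
                try:
                    table = build_feature_table(
                        cohort, features, measure=measure, graph_kind=kind,
                        cutoff=cutoff, task=task, scope=scope,
                    )
                    res = loocv_classify(table, config.regularization)
                    cell.update(spec=res.specificity, sens=res.sensitivity,
                                score=res.score, n_pos=res.n_pos, n_neg=res.n_neg,
                                status="ok", reason="")
                except InfeasibleTaskError as exc:
                    logger.info("skipping %s: %s", cell, exc)
                    cell.update(spec=np.nan, sens=np.nan, score=np.nan,
                                n_pos=0, n_neg=0, status="skipped", reason=str(exc))
                rows.append(cell)
    frame = pd.DataFrame(rows, columns=_GRID_COLUMNS)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame.to_csv(out_dir / "results.csv", index=False)
    elapsed = time.perf_counter() - t0
    (out_dir / "run.log").write_text(
        f"graphfc {__version__}\n"
        f"numpy {np.__version__}, pandas {pd.__version__}\n"
        f"config_hash {_config_hash(config)}\n"
        f"n_subjects {len(cohort)}\n"
        f"grid_cells {len(rows)}\n"
        f"feature_seconds {t_features:.2f}\n"
        f"total_seconds {elapsed:.2f}\n"
    )
    return ResultsGrid(frame=frame, cohort=cohort, features=features, config=config)


def mean_vs_pooled(grid) -> pd.DataFrame:
    """Per measure-configuration: unweighted mean of site scores next to the
    pooled ("all" scope) score and their difference."""
    frame = grid.frame if isinstance(grid, ResultsGrid) else grid
    ok = frame[frame["status"] == "ok"]
    rows = []
    keys = ["task", "measure", "graph_kind", "cutoff"]
    for cell, sub in ok.groupby(keys, dropna=False, sort=False):
        pooled = sub[sub["scope"] == "all"]
        site_scores = sub.loc[sub["scope"] != "all", "score"]
        if pooled.empty or site_scores.empty:
            continue
        mean_site = float(site_scores.mean())
        pooled_score = float(pooled["score"].iloc[0])
        rows.append(dict(zip(keys, cell)) | {
            "mean_site_score": mean_site,
            "pooled_score": pooled_score,
            "difference": mean_site - pooled_score,
        })
    return pd.DataFrame(rows)


def make_maps(grid: ResultsGrid, out_dir=None) -> list:
    """Discriminative maps for every grid cell whose score clears the gate.

    Each map retrains the classifier on all subjects of that cell, ranks
    ROIs by |hyperplane weight| and exports the top fraction as CSV.
    """
    config = grid.config
    out_dir = Path(out_dir) if out_dir is not None else Path(config.out_dir) / "maps"
    ok = grid.frame[(grid.frame["status"] == "ok")
                    & (grid.frame["score"] >= config.map_score_gate)]
    if ok.empty:
        logger.info("no classification reached the map score gate %.2f; no maps emitted",
                    config.map_score_gate)
        return []
    maps = []
    for row in ok.itertuples(index=False):
        cutoff = None if pd.isna(row.cutoff) else float(row.cutoff)
        table = build_feature_table(
            grid.cohort, grid.features, measure=row.measure,
            graph_kind=row.graph_kind, cutoff=cutoff,
            task=row.task, scope=row.scope,
        )
        weights, degenerate = fit_full_and_extract_weights(table, config.regularization)
        if degenerate:
            logger.info("degenerate weights for %s/%s/%s at %s; map skipped",
                        row.task, row.measure, row.graph_kind, row.scope)
            continue
        dmap = top_fraction(
            weights, config.top_fraction, score=float(row.score),
            score_gate=config.map_score_gate, task=row.task, scope=row.scope,
            measure=row.measure, graph_kind=row.graph_kind, cutoff=cutoff,
        )
        name = f"{row.task}__{row.scope}__{row.measure}_{row.graph_kind}"
        if cutoff is not None:
            name += f"_{cutoff:g}"
        export_map(dmap, out_dir / f"{name}.csv")
        maps.append(dmap)
    return maps


def config_from_yaml(path) -> ExperimentConfig:
    """Read an ExperimentConfig (with nested cohort spec or manifest path)."""
    import yaml

    path = Path(path)
    data = yaml.safe_load(path.read_text())
    cohort_block = data.get("cohort")
    if cohort_block is None:
        raise ValueError("config must contain a 'cohort' block")
    if isinstance(cohort_block, dict) and "manifest" in cohort_block:
        manifest = Path(cohort_block["manifest"])
        if not manifest.is_absolute():
            manifest = path.parent / manifest
        cohort = manifest
    elif isinstance(cohort_block, dict):
        cohort = cohort_spec_from_dict(cohort_block.get("spec", cohort_block))
    else:
        cohort = Path(cohort_block)
    kwargs = {"cohort": cohort}
    for key in ("regularization", "map_score_gate", "top_fraction", "out_dir"):
        if key in data:
            kwargs[key] = data[key]
    for key in ("cutoffs", "measures", "tasks", "scopes"):
        if key in data and data[key] is not None:
            kwargs[key] = tuple(data[key])
    config = ExperimentConfig(**kwargs)
    config.validate()
    return config
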