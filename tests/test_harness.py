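import numpy as np
import pandas as pd
import pytest

from graphfc import (
    CohortSpec,
    ExperimentConfig,
    SiteSpec,
    make_maps,
    mean_vs_pooled,
    run_experiment,
    simulate_cohort,
    write_cohort,
)
from graphfc.harness import config_from_yaml, measure_configs


@pytest.fixture(scope="module")
def small_spec():
    """30 ROIs, 2 sites, all three groups, strong effect; fast grid runs."""
    return CohortSpec(
        n_rois=30, n_timepoints=80,
        sites=(SiteSpec("siteA", {"control": 5, "inattentive": 3, "combined": 3}, 0.3, 80),
               SiteSpec("siteB", {"control": 5, "inattentive": 3, "combined": 0}, 0.5, 60)),
        n_modules=3, within_module_corr=0.35, between_module_corr=0.05,
        effect_nodes=(0, 6, 12), effect_size=0.3, seed=21,
    )


@pytest.fixture(scope="module")
def small_grid(small_spec, tmp_path_factory):
    config = ExperimentConfig(cohort=small_spec,
                              out_dir=tmp_path_factory.mktemp("grid"))
    return run_experiment(config)


class TestGrid:
    def test_measure_battery_has_fourteen_configs(self, small_spec):
        cells = measure_configs(ExperimentConfig(cohort=small_spec))
        assert len(cells) == 14
        assert sum(kind == "weighted" for _, kind, _ in cells) == 5

    def test_grid_completeness(self, small_grid):
        # 2 tasks x 14 measure-configs x (2 sites + all) = 84 cells,
        # each present exactly once as a result or an explicit skip
        frame = small_grid.frame
        assert len(frame) == 84
        assert set(frame["status"]) == {"ok", "skipped"}
        keys = frame[["task", "scope", "measure", "graph_kind", "cutoff"]]
        assert not keys.duplicated().any()

    def test_infeasible_cell_recorded_with_reason(self, small_grid):
        # siteB has no combined subjects: the subtype task must be skipped
        skipped = small_grid.frame.query(
            "task == 'inattentive_vs_combined' and scope == 'siteB'")
        assert (skipped["status"] == "skipped").all()
        assert skipped["reason"].str.contains("combined").all()
        ok = small_grid.frame.query("status == 'ok'")
        assert len(ok) == 84 - 14

    def test_scores_equal_mean_of_sens_spec(self, small_grid):
        ok = small_grid.frame.query("status == 'ok'")
        np.testing.assert_allclose(ok["score"], (ok["sens"] + ok["spec"]) / 2)

    def test_rerun_is_byte_identical(self, small_spec, tmp_path):
        out_a, out_b = tmp_path / "a", tmp_path / "b"
        run_experiment(ExperimentConfig(cohort=small_spec, out_dir=out_a))
        run_experiment(ExperimentConfig(cohort=small_spec, out_dir=out_b))
        assert (out_a / "results.csv").read_bytes() == (out_b / "results.csv").read_bytes()

    def test_manifest_cohort_matches_in_memory(self, small_spec, tmp_path):
        records = simulate_cohort(small_spec)
        manifest = write_cohort(records, tmp_path / "cohort")
        grid_mem = run_experiment(
            ExperimentConfig(cohort=small_spec, out_dir=tmp_path / "mem"))
        grid_disk = run_experiment(
            ExperimentConfig(cohort=manifest, out_dir=tmp_path / "disk"))
        ok_mem = grid_mem.frame.query("status == 'ok'")["score"].to_numpy()
        ok_disk = grid_disk.frame.query("status == 'ok'")["score"].to_numpy()
        np.testing.assert_allclose(ok_mem, ok_disk, atol=0.15)


class TestMeanVsPooled:
    def test_arithmetic(self):
        frame = pd.DataFrame([
            {"task": "t", "scope": "siteA", "measure": "degree", "graph_kind": "weighted",
             "cutoff": None, "score": 0.6, "status": "ok"},
            {"task": "t", "scope": "siteB", "measure": "degree", "graph_kind": "weighted",
             "cutoff": None, "score": 0.7, "status": "ok"},
            {"task": "t", "scope": "all", "measure": "degree", "graph_kind": "weighted",
             "cutoff": None, "score": 0.66, "status": "ok"},
        ])
        out = mean_vs_pooled(frame)
        assert len(out) == 1
        assert out["mean_site_score"].iloc[0] == pytest.approx(0.65)
        assert out["difference"].iloc[0] == pytest.approx(-0.01)

    def test_single_site_mean_is_that_site(self):
        frame = pd.DataFrame([
            {"task": "t", "scope": "siteA", "measure": "m", "graph_kind": "weighted",
             "cutoff": None, "score": 0.58, "status": "ok"},
            {"task": "t", "scope": "all", "measure": "m", "graph_kind": "weighted",
             "cutoff": None, "score": 0.6, "status": "ok"},
        ])
        out = mean_vs_pooled(frame)
        assert out["mean_site_score"].iloc[0] == pytest.approx(0.58)

    def test_missing_pooled_record_skipped(self):
        frame = pd.DataFrame([
            {"task": "t", "scope": "siteA", "measure": "m", "graph_kind": "weighted",
             "cutoff": None, "score": 0.58, "status": "ok"},
        ])
        assert mean_vs_pooled(frame).empty

    def test_every_measure_present_on_real_grid(self, small_grid):
        out = mean_vs_pooled(small_grid)
        # control task: all 14 configs have pooled + site rows; subtype task
        # keeps siteA and pooled, so all 28 appear
        assert len(out) == 28


class TestMaps:
    def test_gate_disabled_yields_map_per_feasible_cell(self, small_grid, tmp_path):
        from dataclasses import replace

        grid = small_grid
        grid_open = type(grid)(
            frame=grid.frame, cohort=grid.cohort, features=grid.features,
            config=replace(grid.config, map_score_gate=0.0),
        )
        maps = make_maps(grid_open, tmp_path / "maps")
        assert len(maps) == len(grid.frame.query("status == 'ok'"))
        assert all(len(m.selected) == 2 for m in maps)  # ceil(0.05 * 30)
        assert len(list((tmp_path / "maps").glob("*.csv"))) == len(maps)

    def test_impossible_gate_yields_no_maps(self, small_grid, tmp_path, caplog):
        from dataclasses import replace
        import logging

        grid = small_grid
        grid_closed = type(grid)(
            frame=grid.frame, cohort=grid.cohort, features=grid.features,
            config=replace(grid.config, map_score_gate=1.01),
        )
        with caplog.at_level(logging.INFO, logger="graphfc"):
            maps = make_maps(grid_closed, tmp_path / "maps")
        assert maps == []
        assert "no maps emitted" in caplog.text


class TestConfigYaml:
    def test_round_trip_with_inline_spec(self, tmp_path):
        yaml_text = """
cohort:
  spec:
    n_rois: 12
    n_timepoints: 30
    n_modules: 2
    within_module_corr: 0.3
    between_module_corr: 0.0
    effect_nodes: [0, 1]
    effect_size: 0.2
    seed: 9
    sites:
      - {site_id: a, n_per_group: {control: 3, combined: 3}, noise_sd: 0.2, n_timepoints: 30}
tasks: [control_vs_adhd]
cutoffs: [0.1, 0.15, 0.25]
map_score_gate: 0.5
"""
        path = tmp_path / "exp.yaml"
        path.write_text(yaml_text)
        config = config_from_yaml(path)
        assert isinstance(config.cohort, CohortSpec)
        assert config.cohort.n_rois == 12
        assert config.tasks == ("control_vs_adhd",)
        assert config.map_score_gate == 0.5

    def test_invalid_cutoff_rejected(self, small_spec):
        with pytest.raises(ValueError, match="cutoff"):
            ExperimentConfig(cohort=small_spec, cutoffs=(0.1, 1.5)).validate()


def test_effect_size_raises_scores_over_null(tmp_path):
    """Average pooled weighted-degree score grows with planted effect size."""
    from graphfc.classify import build_feature_table, loocv_classify
    from graphfc.harness import subject_features

    def mean_score(effect, seeds):
        scores = []
        for seed in seeds:
            spec = CohortSpec(
                n_rois=40, n_timepoints=150,
                sites=(SiteSpec("a", {"control": 10, "combined": 10}, 0.4, 150),),
                n_modules=2, within_module_corr=0.3, between_module_corr=0.05,
                effect_nodes=tuple(range(0, 40, 8)), effect_size=effect, seed=seed,
            )
            cohort = simulate_cohort(spec)
            features = {r.subject_id: subject_features(r, measures=("degree",))
                        for r in cohort}
            table = build_feature_table(
                cohort, features, measure="degree", graph_kind="weighted",
                task="control_vs_adhd", scope="all")
            scores.append(loocv_classify(table).score)
        return float(np.mean(scores))

    seeds = range(200, 205)
    assert mean_score(0.4, seeds) > mean_score(0.0, seeds) + 0.1
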