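"""End-to-end pipeline orchestration, artifacts, determinism, CLI surface."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from thermoleaf import LeafSceneSpec, generate_cohort
from thermoleaf.cli import main as cli_main
from thermoleaf.workflow import (
    RunConfig,
    extract_feature_table,
    run_pipeline,
    simulate_to_dir,
)

def _small_config(tmp_path, seed=0, **kw):
    return RunConfig(
        output_dir=tmp_path / "run",
        cv_folds=4,
        search_iterations=2,
        seed=seed,
        **kw,
    )


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(12, dd_offset=3.0, seed=11)


class TestRunPipeline:
    def test_artifacts_and_accuracy(self, tmp_path, cohort):
        config = _small_config(tmp_path)
        samples = [(s.frame, None) for s in cohort]
        result = run_pipeline(config, samples=samples)
        out = result.output_dir
        for name in (
            "feature_table.csv",
            "screen_results.csv",
            "report_rf.txt",
            "report_mlp.txt",
            "confusion_rf.csv",
            "confusion_mlp.csv",
            "comparison.json",
            "config.json",
        ):
            assert (out / name).exists(), name
        assert result.report_rf.accuracy > 0.5
        assert result.report_mlp.n_validation == len(result.feature_table) - int(
            0.75 * len(result.feature_table)
        )
        comp = json.loads((out / "comparison.json").read_text())
        assert "delta_correct_mlp_minus_rf" in comp

    def test_rerun_same_seed_bit_identical(self, tmp_path, cohort):
        samples = [(s.frame, None) for s in cohort]
        r1 = run_pipeline(_small_config(tmp_path / "a"), samples=samples)
        r2 = run_pipeline(_small_config(tmp_path / "b"), samples=samples)
        pd.testing.assert_frame_equal(r1.feature_table, r2.feature_table)
        np.testing.assert_array_equal(r1.report_rf.confusion, r2.report_rf.confusion)
        np.testing.assert_array_equal(r1.report_mlp.confusion, r2.report_mlp.confusion)
        assert (
            (tmp_path / "a" / "run" / "feature_table.csv").read_text()
            == (tmp_path / "b" / "run" / "feature_table.csv").read_text()
        )

    def test_missing_manifest_fails_fast(self, tmp_path):
        config = RunConfig(manifest=tmp_path / "nope.csv", output_dir=tmp_path / "o")
        with pytest.raises(FileNotFoundError):
            run_pipeline(config)
        assert not (tmp_path / "o").exists()  # no partial outputs

    def test_segmentation_and_features_are_label_blind(self, cohort):
        """Mutating every treatment label leaves masks and thermal features
        identical: labels enter only at screening/classification."""
        samples = [(s.frame, None) for s in cohort[:6]]
        table1, _ = extract_feature_table(samples)
        for frame, _ in samples:
            frame.metadata["treatment"] = (
                "DD" if frame.metadata["treatment"] == "WW" else "WW"
            )
        table2, _ = extract_feature_table(samples)
        feature_cols = [c for c in table1.columns if c not in ("treatment",)]
        pd.testing.assert_frame_equal(table1[feature_cols], table2[feature_cols])


class TestSimulateToDir:
    def test_writes_csvs_manifest_and_masks(self, tmp_path):
        out = simulate_to_dir(tmp_path / "sim", n_per_class=3, seed=0)
        manifest = pd.read_csv(out / "manifest.csv")
        assert len(manifest) == 6
        assert set(manifest["treatment"]) == {"WW", "DD"}
        for sid in manifest["sample_id"]:
            assert (out / f"{sid}.csv").exists()
            assert (out / f"{sid}_truth.png").exists()

    def test_simulate_then_run_smoke(self, tmp_path):
        """The on-disk round trip: simulate a cohort, then run the full
        pipeline from the manifest."""
        sim = simulate_to_dir(tmp_path / "sim", n_per_class=10, dd_offset=3.0, seed=1)
        config = _small_config(tmp_path, manifest=sim / "manifest.csv")
        result = run_pipeline(config)
        assert result.report_rf.n_validation > 0
        assert result.report_rf.accuracy > 0.5


class TestConfigFile:
    def test_yaml_round_trip(self, tmp_path):
        cfg_file = tmp_path / "run.yaml"
        cfg_file.write_text(
            "seed: 5\nalpha: 0.01\ncv_folds: 4\n"
            "segmentation:\n  struct_radius: 2\n  min_area: 30\n"
        )
        from thermoleaf.workflow import load_run_config

        config = load_run_config(cfg_file, output_dir=tmp_path / "o")
        assert config.seed == 5
        assert config.alpha == 0.01
        assert config.segmentation.struct_radius == 2
        assert config.segmentation.min_area == 30
        assert config.output_dir == tmp_path / "o"  # override wins

    def test_json_config(self, tmp_path):
        cfg_file = tmp_path / "run.json"
        cfg_file.write_text('{"seed": 9, "train_fraction": 0.8}')
        from thermoleaf.workflow import load_run_config

        config = load_run_config(cfg_file)
        assert config.seed == 9
        assert config.train_fraction == 0.8


class TestCli:
    def test_simulate_and_parse(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(
            cli_main,
            ["simulate", str(tmp_path / "sim"), "--n-per-class", "2", "--seed", "3"],
        )
        assert res.exit_code == 0, res.output
        res = runner.invoke(cli_main, ["parse", str(tmp_path / "sim" / "ww_0000.csv")])
        assert res.exit_code == 0
        assert "120x160 grid" in res.output

    def test_segment_subcommand(self, tmp_path):
        runner = CliRunner()
        runner.invoke(
            cli_main,
            ["simulate", str(tmp_path / "sim"), "--n-per-class", "1", "--seed", "4"],
        )
        res = runner.invoke(
            cli_main,
            [
                "segment",
                str(tmp_path / "sim" / "dd_0000.csv"),
                "--out",
                str(tmp_path / "mask.png"),
            ],
        )
        assert res.exit_code == 0, res.output
        assert (tmp_path / "mask.png").exists()
        assert (tmp_path / "mask.csv").exists()

    def test_parse_reports_data_error(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("1,2\n3,oops\n")
        res = CliRunner().invoke(cli_main, ["parse", str(bad)])
        assert res.exit_code == 2
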