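import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from ringtrial.cli import main as cli_main
from ringtrial.io import CONTROL, PTSD, MeasurementTable, read_measurements
from ringtrial.model import PipelineError, RingTrialEvaluation
from ringtrial.report import published_accuracy, render_summary, run_pipeline
from ringtrial.synthetic import demo_config, generate, synthetic_harmonization_map, truth_coa
from tests.conftest import make_rows


@pytest.fixture(scope="module")
def demo_results():
    cfg = demo_config(7)
    table, truth = generate(cfg)
    model = RingTrialEvaluation(
        table, harmonization_map=synthetic_harmonization_map(cfg), coa=truth_coa(truth)
    )
    return model.fit()


class TestModelFit:
    def test_all_stages_populate(self, demo_results):
        res = demo_results
        assert len(res.retained) > 0
        assert not res.intra_cv.empty and not res.inter_cv.empty
        assert not res.class_summary_intra.empty and not res.class_summary_inter.empty
        assert res.accuracy and res.linearity
        assert res.coverage is not None and len(res.coverage["counts"]) == 31
        assert not res.coverage_drift.empty
        assert res.consistent_classes is not None

    def test_summary_mentions_key_stages(self, demo_results):
        text = demo_results.summary()
        for needle in ("intra-assay", "inter-assay", "accuracy", "linearity", "coverage"):
            assert needle in text

    def test_class_summary_carries_pooled_and_per_group_ranges(self, demo_results):
        cs = demo_results.class_summary_intra
        assert {"min_cv", "max_cv", "pooled_min_cv", "pooled_max_cv"} <= set(cs.columns)
        assert (cs["pooled_min_cv"] <= cs["min_cv"] + 1e-12).all()
        assert (cs["pooled_max_cv"] >= cs["max_cv"] - 1e-12).all()

    def test_relative_platform_absent_from_accuracy(self, demo_results):
        assert "LCMS-D" not in set(demo_results.accuracy_frame["platform"])

    def test_single_shipment_skips_inter_stage(self):
        cfg = demo_config(3)
        table, truth = generate(cfg)
        ship1 = MeasurementTable(table.df[table.df["shipment"] == 1].reset_index(drop=True))
        model = RingTrialEvaluation(ship1, coa=truth_coa(truth))
        with pytest.warns(UserWarning, match="single shipment"):
            res = model.fit()
        assert res.inter_cv is None and res.class_summary_inter is None
        assert not res.intra_cv.empty

    def test_stage_failure_names_the_stage(self, duplicate_table):
        model = RingTrialEvaluation(duplicate_table, groups=(PTSD, "MISSING_GROUP"))
        with pytest.raises(PipelineError, match="80% rule"):
            model.fit()

    def test_from_dataframe_constructor(self):
        df = pd.DataFrame(make_rows() + make_rows(group=CONTROL, parent="C01"))
        model = RingTrialEvaluation.from_dataframe(df)
        assert isinstance(model.table, MeasurementTable)


class TestPipelineOutputs:
    def test_demo_config_produces_all_report_files(self, tmp_path):
        out = run_pipeline({"simulate": True, "seed": 5}, outdir=tmp_path / "out")
        for name in (
            "metabolite_cvs_intra.csv",
            "metabolite_cvs_inter.csv",
            "class_summary_intra.csv",
            "class_summary_inter.csv",
            "accuracy.csv",
            "linearity.csv",
            "exclusions.csv",
            "coverage.json",
            "run_manifest.json",
            "report.md",
        ):
            assert (out / name).exists() and (out / name).stat().st_size > 0

    def test_end_to_end_determinism(self, tmp_path):
        cfg = {"simulate": True, "seed": 9}
        out1 = run_pipeline(cfg, outdir=tmp_path / "a")
        out2 = run_pipeline(cfg, outdir=tmp_path / "b")
        for name in ("class_summary_intra.csv", "accuracy.csv", "linearity.csv", "coverage.json", "report.md"):
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes()

    def test_no_imputed_values_in_reports(self, tmp_path):
        """Missing cells stay empty in every exported table — no substitution."""
        out = run_pipeline({"simulate": True, "seed": 5}, outdir=tmp_path / "out")
        inputs = read_measurements(out / "inputs" / "measurements.csv")
        n_missing = int(inputs.df["missing"].sum())
        assert n_missing > 0  # the design does produce censored/MCAR cells
        raw = (out / "inputs" / "measurements.csv").read_text()
        # a missing measurement serializes as an empty value field, never 0
        assert raw.count(",,") >= n_missing
        cvs = pd.read_csv(out / "metabolite_cvs_intra.csv")
        assert not (cvs["cv_pct"] == 0).all()

    def test_manifest_records_conventions_and_config_hash(self, tmp_path):
        out = run_pipeline({"simulate": True, "seed": 5}, outdir=tmp_path / "out")
        manifest = json.loads((out / "run_manifest.json").read_text())
        assert "config_sha256" in manifest
        assert "uncentered" in manifest["conventions"]["r_squared"]
        assert "√2" in manifest["conventions"]["cv"]

    def test_render_requires_output_files(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="class_summary_intra"):
            render_summary(tmp_path)

    def test_report_lists_all_venn_regions(self, tmp_path):
        out = run_pipeline({"simulate": True, "seed": 5}, outdir=tmp_path / "out")
        text = (out / "report.md").read_text()
        assert text.count("| ") > 31  # 31 region rows plus tables
        cov = json.loads((out / "coverage.json").read_text())
        assert len(cov["overlap"]["counts"]) == 2**5 - 1

    def test_rendering_is_deterministic(self, tmp_path):
        out = run_pipeline({"simulate": True, "seed": 5}, outdir=tmp_path / "out")
        first = (out / "report.md").read_text()
        second = render_summary(out)
        assert first == second


class TestCLI:
    def test_simulate_then_evaluate_then_report(self, tmp_path):
        runner = CliRunner()
        sim = runner.invoke(cli_main, ["simulate", "--out", str(tmp_path / "sim"), "--seed", "2"])
        assert sim.exit_code == 0, sim.output
        config = tmp_path / "cfg.yaml"
        config.write_text(
            f"""
measurements: {tmp_path / 'sim' / 'measurements.csv'}
harmonization_map: {tmp_path / 'sim' / 'harmonization_map.tsv'}
coa: {tmp_path / 'sim' / 'coa.csv'}
output_dir: {tmp_path / 'out'}
"""
        )
        ev = runner.invoke(cli_main, ["evaluate", "--config", str(config)])
        assert ev.exit_code == 0, ev.output
        rep = runner.invoke(cli_main, ["report", "--out", str(tmp_path / "out")])
        assert rep.exit_code == 0, rep.output
        assert (tmp_path / "out" / "report.md").exists()

    def test_accuracy_demo_prints_reference_worked_example(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(cli_main, ["accuracy-demo", "--out", str(tmp_path / "acc.csv")])
        assert res.exit_code == 0, res.output
        df = pd.read_csv(tmp_path / "acc.csv")
        night = df[df["platform"] == "Nightingale"].set_index("analyte")
        assert round(night.loc["Alanine", "percent_diff"], 2) == 4.08
        assert round(night.loc["Cholesterol", "percent_diff"], 2) == -7.58


class TestPlotting:
    def test_profile_plot_draws_one_series_per_platform(self, demo_results):
        import matplotlib

        matplotlib.use("Agg")
        from ringtrial.plotting import plot_platform_profile

        ax = plot_platform_profile(demo_results.profile, title="demo")
        platforms = demo_results.profile.loc[demo_results.profile["assessable"], "platform"].nunique()
        assert len(ax.get_legend().get_texts()) == platforms
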