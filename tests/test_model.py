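"""Model/results workflow, sensitivity, reporting, and CLI."""

import json

import numpy as np
import pandas as pd
import pytest
from typer.testing import CliRunner

from agrivision import (
    FarmPanel,
    GeneratorConfig,
    SensitivityResult,
    VisionBenchmark,
    equal_weights_rerun,
    generate_farm_panel,
    rank_stability,
)
from agrivision.cli import app
from agrivision.report import RunConfig, render_report, run_assess


class TestFitWorkflow:
    def test_cardinality_and_schema(self, default_results):
        scores = default_results.scores
        assert scores["farm_id"].nunique() == 20
        assert set(scores["vision_id"]) == {"AS", "SBV", "LmZ"}
        assert len(scores) == 60

    def test_end_to_end_determinism(self):
        r1 = VisionBenchmark.from_synthetic(seed=17).fit()
        r2 = VisionBenchmark.from_synthetic(seed=17).fit()
        assert r1.to_json() == r2.to_json()

    def test_fit_equals_sweep_at_baseline_threshold(self, default_results):
        """The single-point sweep at 5% reproduces the baseline fit."""
        sens = default_results.sensitivity(grid=[0.05])
        assert sens.medians_at(0.05) == default_results.median_agreement()

    def test_landscape_codes_shared_by_all_farms(self, default_results):
        frame = default_results.observed.frame
        for ind in ("total_agri_area", "avg_field_size", "semi_natural"):
            assert frame[ind].nunique() == 1

    def test_summary_orders_visions_by_median(self, default_results):
        text = default_results.summary()
        med = default_results.median_agreement()
        order = sorted(med, key=lambda v: -med[v])
        positions = [text.index(f"\n  {v} ") for v in order]
        assert positions == sorted(positions)

    def test_category_breakdown_has_five_categories(self, default_results):
        cat = default_results.category_median_agreement()
        assert cat.shape == (3, 5)
        # landscape development codes are identical across farms, so the
        # category medians are single-valued per vision
        assert cat["landscape_dev"].notna().all()

    def test_empty_panel_reports_no_farms(self):
        empty = FarmPanel(pd.DataFrame(
            columns=["farm_id", "indicator_id", "period", "value"]))
        results = VisionBenchmark(empty).fit()
        assert "no farms" in results.summary()
        report = results.to_report(with_comparison=False)
        assert report["n_farms"] == 0
        assert "No farms" in render_report(report)


class TestSensitivity:
    def test_monotone_no_change_cell_count(self):
        """The number of 0-codes never decreases along the threshold grid."""
        from agrivision import build_observed_change_matrix

        model = VisionBenchmark.from_synthetic(seed=2)
        counts = [
            build_observed_change_matrix(
                model.panel, model.landscape_values, t, model.one_time_codes
            ).n_no_change()
            for t in np.arange(0.0, 0.101, 0.01)
        ]
        assert counts == sorted(counts)

    def test_uniform_weight_vision_unaffected_by_equalizing(self):
        """Equal-weight deltas vanish when all positive weights are
        already uniform (weight-scale invariance corollary)."""
        model = VisionBenchmark.from_synthetic(seed=3)
        uniform = {v: s.reweighted(1) for v, s in model.visions.items()}
        deltas = equal_weights_rerun(
            model.panel, model.landscape_values, uniform,
            one_time_codes=model.one_time_codes,
        )
        assert all(d == pytest.approx(0.0) for d in deltas.values())

    def test_constant_medians_are_rank_stable(self):
        rows = []
        for t in (0.0, 0.05, 0.10):
            for w in ("baseline", "equal"):
                for v, m in (("AS", 80.0), ("SBV", 60.0), ("LmZ", 40.0)):
                    rows.append({"threshold": t, "weights": w, "vision_id": v,
                                 "median_agreement": m})
        sens = SensitivityResult(
            threshold_grid=(0.0, 0.05, 0.10),
            medians=pd.DataFrame(rows),
            baseline_threshold=0.05,
            equal_weight_delta={"AS": 0.0, "SBV": 0.0, "LmZ": 0.0},
        )
        stable, order = rank_stability(sens)
        assert stable
        assert order == (("AS",), ("SBV",), ("LmZ",))

    def test_swapped_medians_are_unstable(self):
        rows = []
        for t, (a, b) in ((0.0, (80, 60)), (0.05, (60, 80))):
            for v, m in (("AS", a), ("SBV", b)):
                rows.append({"threshold": t, "weights": "baseline", "vision_id": v,
                             "median_agreement": float(m)})
        sens = SensitivityResult(
            threshold_grid=(0.0, 0.05),
            medians=pd.DataFrame(rows),
            baseline_threshold=0.05,
            equal_weight_delta={},
        )
        assert rank_stability(sens)[0] is False

    def test_ties_annotated_in_ordering(self):
        rows = [
            {"threshold": 0.05, "weights": "baseline", "vision_id": v,
             "median_agreement": m}
            for v, m in (("AS", 70.0), ("SBV", 70.0), ("LmZ", 50.0))
        ]
        sens = SensitivityResult(
            threshold_grid=(0.05,),
            medians=pd.DataFrame(rows),
            baseline_threshold=0.05,
            equal_weight_delta={},
        )
        stable, order = rank_stability(sens)
        assert stable
        assert order == (("AS", "SBV"), ("LmZ",))

    def test_grid_validation(self):
        model = VisionBenchmark.from_synthetic(seed=1)
        results = model.fit()
        with pytest.raises(ValueError, match="nonempty"):
            results.sensitivity(grid=[])


class TestReportAndCli:
    def test_run_config_validates_paths(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            RunConfig(panel_csv=str(tmp_path / "missing.csv"))

    def test_run_assess_round_trip(self, tmp_path, default_panel):
        panel_csv = tmp_path / "panel.csv"
        default_panel.to_csv(panel_csv)
        config = RunConfig(panel_csv=str(panel_csv), out_dir=str(tmp_path / "out"))
        report = run_assess(config)
        assert report["n_farms"] == 20
        written = json.loads((tmp_path / "out" / "agreement_report.json").read_text())
        assert written["median_agreement"] == report["median_agreement"]
        text = render_report(report)
        assert "Median agreement" in text and "AS" in text

    def test_render_report_dashes_undefined_categories(self):
        report = {
            "n_farms": 1,
            "threshold": 0.05,
            "median_agreement": {"AS": 70.0},
            "category_median_agreement": {"AS": {"social": None, "economic": 50.0}},
            "best_vision_shares": {"AS": 1.0},
        }
        text = render_report(report)
        assert "—" in text

    def test_cli_simulate_then_assess(self, tmp_path):
        runner = CliRunner()
        prefix = tmp_path / "syn"
        res = runner.invoke(app, ["simulate", "--seed", "3", "--out-prefix", str(prefix)])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "syn_panel.csv").exists()
        assert (tmp_path / "syn_config.yaml").exists()
        res2 = runner.invoke(
            app,
            ["assess", str(tmp_path / "syn_panel.csv"),
             "--landscape-values", str(tmp_path / "syn_landscape_values.csv"),
             "--out-dir", str(tmp_path / "out")],
        )
        assert res2.exit_code == 0, res2.output
        assert "Median agreement" in res2.output
        assert (tmp_path / "out" / "agreement_report.json").exists()

    def test_cli_rejects_invalid_panel(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("farm_id,indicator_id,period,value\nA,mystery,t0,1\n")
        runner = CliRunner()
        res = runner.invoke(app, ["assess", str(bad)])
        assert res.exit_code == 2
        assert "mystery" in res.output

    def test_cli_landscape_metrics(self, tmp_path):
        runner = CliRunner()
        prefix = tmp_path / "syn"
        runner.invoke(app, ["simulate", "--seed", "2", "--out-prefix", str(prefix)])
        res = runner.invoke(
            app,
            ["landscape", str(tmp_path / "syn_landcover.csv"),
             "--trees", str(tmp_path / "syn_trees.csv"),
             "--out-dir", str(tmp_path / "land")],
        )
        assert res.exit_code == 0, res.output
        assert (tmp_path / "land" / "transition_matrix.csv").exists()
        assert "total_agri_area" in res.output
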