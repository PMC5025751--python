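"""Trace/report I/O, pipeline determinism and the CLI surface."""

import json

import numpy as np
import pytest
from typer.testing import CliRunner

from myoxwalk.cli import app
from myoxwalk.io import read_report, read_trace, write_report, write_trace
from myoxwalk.pipeline import (
    AnalysisConfig,
    Report,
    SimulationConfig,
    demo_config,
    run_pipeline,
)
from myoxwalk.simulate import FL_SINGLE, TraceParams, simulate_trace

runner = CliRunner()


class TestTraceIO:
    def test_round_trip_preserves_values(self, tmp_path):
        tr = simulate_trace(TraceParams(seed=0), FL_SINGLE)
        p = tmp_path / "trace.tsv"
        write_trace(tr, p)
        back = read_trace(p)
        assert back.times_s == pytest.approx(tr.times_s, abs=1e-9)
        assert back.positions_nm == pytest.approx(tr.positions_nm, abs=1e-9)

    def test_comment_lines_skipped(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("# header comment\ntime_s\tposition_nm\n0.0\t1.0\n0.1\t2.0\n")
        tr = read_trace(p)
        assert len(tr.times_s) == 2

    def test_missing_column_is_a_schema_error(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("time_s\tx\n0.0\t1.0\n")
        with pytest.raises(ValueError, match="position_nm"):
            read_trace(p)

    def test_malformed_rows_reported_with_line_numbers(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("time_s\tposition_nm\n0.0\t1.0\n0.1\tbroken\n0.2\t2.0\n")
        with pytest.raises(ValueError, match=r"\[3\]"):
            read_trace(p)

    def test_extra_columns_ignored(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("time_s,position_nm,frame\n0.0,1.0,0\n0.1,2.0,1\n")
        tr = read_trace(p)
        assert tr.positions_nm == pytest.approx([1.0, 2.0])


@pytest.fixture(scope="module")
def small_config():
    return AnalysisConfig(
        name="small",
        seed=42,
        simulation=SimulationConfig(
            mixture="fl_single", n_traces=4, steps_per_trace=15,
            n_runs=60, run_lambda_um=0.6, run_x0_um=0.2,
        ),
    )


@pytest.fixture(scope="module")
def report(small_config):
    return run_pipeline(small_config)


class TestPipeline:
    def test_report_round_trips_through_json(self, report, tmp_path):
        p = tmp_path / "report.json"
        write_report(report, p)
        assert Report.from_dict(read_report(p)).to_dict() == report.to_dict()

    def test_report_regenerates_bit_identically(self, small_config, report):
        again = run_pipeline(small_config)
        assert json.dumps(again.to_dict(), sort_keys=True) == json.dumps(
            report.to_dict(), sort_keys=True
        )

    def test_report_carries_provenance(self, small_config, report):
        assert report.provenance["seed"] == 42
        assert report.provenance["config_hash"] == small_config.digest()

    def test_zero_traces_yield_empty_report_with_warning(self):
        cfg = AnalysisConfig(
            simulation=SimulationConfig(n_traces=0, n_runs=0)
        )
        rep = run_pipeline(cfg)
        assert rep.k_selected is None
        assert rep.mixture_components == []
        assert any("no traces" in w for w in rep.warnings)

    def test_unknown_config_keys_rejected(self):
        with pytest.raises(Exception):
            AnalysisConfig.model_validate({"seed": 1, "bogus": True})

    def test_demo_recovers_two_populations_with_forward_peak_near_36(self):
        """End-to-end single-filament demo: modal K = 2, main peak ~36 nm."""
        ks, mains, lams = [], [], []
        for seed in range(5):
            rep = run_pipeline(demo_config("fl_single", seed=seed))
            ks.append(rep.k_selected)
            forward = [c for c in rep.mixture_components if c["mean_nm"] > 0]
            mains.append(max(forward, key=lambda c: c["weight"])["mean_nm"])
            lams.append(rep.run_length["lambda_um"])
        values, counts = np.unique(ks, return_counts=True)
        assert values[np.argmax(counts)] == 2
        assert np.median(mains) == pytest.approx(36.0, abs=4.0)
        assert np.median(lams) == pytest.approx(0.60, rel=0.25)

    def test_demo_on_bundles_resolves_four_populations(self):
        """End-to-end fascin-bundle demo: modal K = 4."""
        ks = [
            run_pipeline(demo_config("hmm_bundle", seed=seed)).k_selected
            for seed in range(5)
        ]
        values, counts = np.unique(ks, return_counts=True)
        assert values[np.argmax(counts)] == 4


class TestCLI:
    def test_targets_subcommand_lists_hot_spots(self, tmp_path):
        out = tmp_path / "zones.json"
        result = runner.invoke(
            app, ["targets", "--tol", "60", "--band-min", "33",
                  "--band-max", "57", "--json-out", str(out)]
        )
        assert result.exit_code == 0, result.output
        zones = json.loads(out.read_text())
        assert [z["axial_nm"] for z in zones] == pytest.approx([35.75, 41.25, 46.75])

    def test_reach_subcommand_reports_envelope(self):
        result = runner.invoke(app, ["reach", "--preset", "relaxed"])
        assert result.exit_code == 0
        env = json.loads(result.output)
        assert env["flattened_span_nm"] == pytest.approx(66.1)

    def test_validation_errors_exit_with_code_2(self):
        result = runner.invoke(app, ["reach", "--preset", "bogus"])
        assert result.exit_code == 2

    def test_simulate_then_analyze_round_trip(self, tmp_path):
        traces = tmp_path / "traces"
        r1 = runner.invoke(
            app, ["simulate", "--out", str(traces), "--n-traces", "4",
                  "--n-steps", "15", "--seed", "5"]
        )
        assert r1.exit_code == 0, r1.output
        assert len(list(traces.glob("*.tsv"))) == 4
        report = tmp_path / "report.json"
        r2 = runner.invoke(
            app, ["analyze", "--traces", str(traces), "--kmax", "3",
                  "--seed", "5", "--report", str(report)]
        )
        assert r2.exit_code == 0, r2.output
        payload = json.loads(report.read_text())
        assert payload["n_traces"] == 4
        assert payload["k_selected"] in (1, 2, 3)
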