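import datetime as dt
import json
from pathlib import Path

import numpy as np
import pytest
from click.testing import CliRunner

from feverwatch import io
from feverwatch.cli import main as cli_main
from feverwatch.epistats import summarize_day, weekly_aggregate
from feverwatch.synthgen import ARISeries, ScenarioConfig, generate_day
from feverwatch.tti import PersonDetection

from .conftest import make_stream

DATE = dt.date(2022, 4, 22)


class TestRecordingRoundTrip:
    def test_small_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        stream = make_stream(26.0 + rng.uniform(0, 10, 900))
        path = tmp_path / io.recording_filename(DATE)
        io.write_recording(stream, path)
        back = io.read_recording(path)
        assert len(back) == len(stream)
        assert back.sample_rate_hz == 9.0
        assert back.date == DATE
        np.testing.assert_allclose(back.t_r1_max, stream.t_r1_max, atol=0.005)
        np.testing.assert_allclose(back.t_r2_mean, stream.t_r2_mean, atol=0.005)

    def test_full_day_round_trip(self, tmp_path):
        cfg = ScenarioConfig()
        stream, _ = generate_day(cfg, DATE, seed=1)
        path = tmp_path / io.recording_filename(DATE)
        io.write_recording(stream, path)
        back = io.read_recording(path)
        assert len(back) == 777_600
        np.testing.assert_allclose(back.t_r1_max, stream.t_r1_max, atol=0.005)

    def test_header_only_warns_empty(self, tmp_path):
        path = tmp_path / "2022-04-22.csv"
        path.write_text(io.RECORDING_HEADER + "\n")
        with pytest.warns(UserWarning):
            stream = io.read_recording(path)
        assert len(stream) == 0

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "2022-04-22.csv"
        path.write_text(io.RECORDING_HEADER + "\n0.000,26.00,20.00\n0.111,26.00\n")
        with pytest.raises(io.RecordingParseError, match="line 3"):
            io.read_recording(path)

    def test_non_monotonic_time_rejected(self, tmp_path):
        path = tmp_path / "2022-04-22.csv"
        rows = ["0.000,26.00,20.00", "0.222,26.00,20.00", "0.111,26.00,20.00"]
        path.write_text(io.RECORDING_HEADER + "\n" + "\n".join(rows) + "\n")
        with pytest.raises(io.RecordingParseError, match="increasing"):
            io.read_recording(path)

    def test_inconsistent_interval_rejected(self, tmp_path):
        path = tmp_path / "2022-04-22.csv"
        rows = [f"{t:.3f},26.00,20.00" for t in (0.0, 0.111, 0.222, 0.9)]
        path.write_text(io.RECORDING_HEADER + "\n" + "\n".join(rows) + "\n")
        with pytest.raises(io.RecordingParseError, match="interval"):
            io.read_recording(path)

    def test_wrong_header_rejected(self, tmp_path):
        path = tmp_path / "2022-04-22.csv"
        path.write_text("a,b,c\n1,2,3\n")
        with pytest.raises(io.RecordingParseError, match="header"):
            io.read_recording(path)


class TestDetectionsFile:
    def test_round_trip_with_fti_blank_duration(self, tmp_path):
        dets = [
            PersonDetection("TTI", 34200.0, 36.5, duration_s=2.0, date=DATE),
            PersonDetection("FTI", 34201.0, 36.2, duration_s=None, date=DATE),
        ]
        path = tmp_path / "detections.csv"
        io.write_detections(dets, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "date,method,detect_time_s,temp_c,duration_s"
        assert lines[2].endswith(",")  # FTI duration empty
        back = io.read_detections(path)
        assert [d.method for d in back] == ["TTI", "FTI"]
        assert back[1].duration_s is None
        assert back[0].temp_c == pytest.approx(36.5)
        assert back[0].date == DATE


class TestARIFile:
    def test_round_trip(self, tmp_path):
        ari = ARISeries((0, 1, 2), (120.5, 340.25, 0.0))
        path = tmp_path / "ari.csv"
        io.write_ari(ari, path)
        back = io.read_ari(path)
        assert back.week_index == ari.week_index
        np.testing.assert_allclose(back.incidence_per_100k, ari.incidence_per_100k)

    def test_negative_incidence_rejected(self):
        with pytest.raises(ValueError):
            ARISeries((0,), (-1.0,))


class TestScenarioConfigFile:
    def test_round_trip(self, tmp_path):
        cfg = ScenarioConfig(p_front=0.6, sample_rate=3.0, seed=9)
        path = tmp_path / "scenario.toml"
        io.dump_scenario_config(cfg, path)
        assert io.load_scenario_config(path) == cfg

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "scenario.toml"
        path.write_text("p_front = 0.5\nbananas = 3\n")
        with pytest.raises(ValueError, match="bananas"):
            io.load_scenario_config(path)


class TestSummariesFile:
    def test_weekly_round_trip(self, tmp_path):
        dets = [
            PersonDetection("TTI", 36000.0 + k, 35.0 + 0.05 * k, 2.0, DATE + dt.timedelta(days=k % 7))
            for k in range(40)
        ]
        by_date = {}
        for d in dets:
            by_date.setdefault(d.date, []).append(d)
        dailies = [summarize_day(v, k) for k, v in sorted(by_date.items())]
        weekly = weekly_aggregate(dailies, dets)
        path = tmp_path / "weekly.csv"
        io.write_summaries(weekly, path)
        back = io.read_weekly_summaries(path)
        assert len(back) == len(weekly)
        assert back[0].n_persons == weekly[0].n_persons
        assert back[0].mean_temp_c == pytest.approx(weekly[0].mean_temp_c, abs=1e-5)

    def test_daily_file_rejected_by_weekly_reader(self, tmp_path):
        dailies = [summarize_day([], DATE)]
        path = tmp_path / "daily.csv"
        io.write_summaries(dailies, path)
        assert path.read_text().splitlines()[0].startswith("date,")
        with pytest.raises(ValueError, match="week"):
            io.read_weekly_summaries(path)


# -- CLI ---------------------------------------------------------------------

#: Tiny scenario for CLI runs: 3 Hz sampling and light traffic keep each
#: simulated day small while exercising the full pipeline.
TINY_SCENARIO = ScenarioConfig(
    hourly_rate_profile=(0.0,) * 9 + (12.0,) * 12 + (0.0,) * 3,
    short_pass_rate=2.0,
    hot_object_rate=1.0,
    sample_rate=3.0,
)


def _write_tiny_scenario(path: Path) -> Path:
    io.dump_scenario_config(TINY_SCENARIO, path)
    return path


class TestCLI:
    def test_simulate_deterministic_byte_identical(self, tmp_path):
        runner = CliRunner()
        cfg = _write_tiny_scenario(tmp_path / "scenario.toml")
        outs = []
        for name in ("a", "b"):
            out = tmp_path / name
            res = runner.invoke(
                cli_main,
                ["simulate", "--config", str(cfg), "--weeks", "1", "--days-per-week", "2",
                 "--seed", "5", "--out", str(out)],
            )
            assert res.exit_code == 0, res.output
            outs.append(out)
        files_a = sorted(p.relative_to(outs[0]) for p in outs[0].rglob("*") if p.is_file())
        files_b = sorted(p.relative_to(outs[1]) for p in outs[1].rglob("*") if p.is_file())
        assert files_a == files_b and files_a
        for rel in files_a:
            assert (outs[0] / rel).read_bytes() == (outs[1] / rel).read_bytes()

    def test_detect_on_baseline_recording_header_only(self, tmp_path):
        quiet = make_stream(np.full(3000, 26.0), sample_rate=3.0)
        rec_dir = tmp_path / "recordings"
        rec_dir.mkdir()
        io.write_recording(quiet, rec_dir / io.recording_filename(DATE))
        out = tmp_path / "detections.csv"
        res = CliRunner().invoke(
            cli_main, ["detect", "--method", "tti", "--in", str(tmp_path), "--out", str(out)]
        )
        assert res.exit_code == 0, res.output
        assert out.read_text() == "date,method,detect_time_s,temp_c,duration_s\n"

    def test_missing_input_usage_error(self, tmp_path):
        res = CliRunner().invoke(
            cli_main, ["detect", "--in", str(tmp_path / "nope"), "--out", "x.csv"]
        )
        assert res.exit_code != 0

    def test_full_chain_smoke(self, tmp_path):
        runner = CliRunner()
        cfg = _write_tiny_scenario(tmp_path / "scenario.toml")
        sim = tmp_path / "sim"
        res = runner.invoke(
            cli_main,
            ["simulate", "--config", str(cfg), "--weeks", "4", "--days-per-week", "2",
             "--seed", "1", "--out", str(sim)],
        )
        assert res.exit_code == 0, res.output
        assert (sim / "config.toml").exists()  # config echoed for provenance

        dets = tmp_path / "detections.csv"
        res = runner.invoke(
            cli_main, ["detect", "--method", "both", "--in", str(sim), "--out", str(dets)]
        )
        assert res.exit_code == 0, res.output
        methods = {d.method for d in io.read_detections(dets)}
        assert methods == {"TTI", "FTI"}

        weekly = tmp_path / "weekly.csv"
        res = runner.invoke(
            cli_main, ["summarize", "--in", str(dets), "--by", "week", "--out", str(weekly)]
        )
        assert res.exit_code == 0, res.output

        report = tmp_path / "corr.json"
        res = runner.invoke(
            cli_main,
            ["correlate", "--summaries", str(weekly), "--ari", str(sim / "ari.csv"),
             "--statistic", "n_persons", "--include-partial", "--out", str(report)],
        )
        assert res.exit_code == 0, res.output
        payload = json.loads(report.read_text())
        assert abs(payload["pearson_r"]) <= 1.0
        assert payload["n_points"] == 4

    def test_summarize_daily(self, tmp_path):
        dets_path = tmp_path / "d.csv"
        io.write_detections(
            [PersonDetection("TTI", 36000.0, 36.0, 2.0, DATE)] * 3, dets_path
        )
        out = tmp_path / "daily.csv"
        res = CliRunner().invoke(
            cli_main, ["summarize", "--in", str(dets_path), "--by", "day", "--out", str(out)]
        )
        assert res.exit_code == 0, res.output
        assert out.read_text().splitlines()[1].startswith("2022-04-22,3,")
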