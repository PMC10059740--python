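"""File formats tying the pipeline together.

All files are CSV with a comma delimiter, period decimal separator,
UTF-8 and LF endings; no dialect autodetection.  One recording file per
day, named ``YYYY-MM-DD.csv``; time is stored as seconds since midnight
(3 decimals), temperatures with 2 decimals.
"""

from __future__ import annotations

import datetime as _dt
import tomllib
import warnings
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from feverwatch.epistats import DailySummary, WeeklySummary
from feverwatch.synthgen import ARISeries, DailyStream, EventTruth, ScenarioConfig
from feverwatch.tti import PersonDetection

__all__ = [
    "RecordingParseError",
    "load_scenario_config",
    "dump_scenario_config",
    "read_ari",
    "read_detections",
    "read_recording",
    "read_truth",
    "read_weekly_summaries",
    "recording_filename",
    "write_ari",
    "write_detections",
    "write_recording",
    "write_summaries",
    "write_truth",
]

RECORDING_HEADER = "time_s,t_r1_max_c,t_r2_mean_c"
DETECTIONS_COLUMNS = ["date", "method", "detect_time_s", "temp_c", "duration_s"]

#: Time-column quantization of the recording format (3 decimals) plus the
#: declared sampling-interval tolerance.
_TIME_TOL_S = 5e-4 + 1e-6


class RecordingParseError(ValueError):
    """Malformed recording file; carries the 1-based line number if known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def recording_filename(date: _dt.date) -> str:
    return f"{date.isoformat()}.csv"


def write_recording(stream: DailyStream, path: str | Path) -> None:
    """Write one day of samples; time %.3f s, temperatures %.2f degC."""
    path = Path(path)
    data = np.column_stack([stream.times_s, stream.t_r1_max, stream.t_r2_mean])
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(RECORDING_HEADER + "\n")
        np.savetxt(fh, data, fmt="%.3f,%.2f,%.2f", newline="\n")


def _date_from_filename(path: Path) -> _dt.date | None:
    try:
        return _dt.date.fromisoformat(path.stem)
    except ValueError:
        return None


def read_recording(
    path: str | Path,
    date: _dt.date | None = None,
    default_sample_rate_hz: float = 9.0,
) -> DailyStream:
    """Parse a recording file back into a :class:`DailyStream`.

    The sample rate is inferred from the time column; each timestamp must
    match the uniform grid within the format quantization (0.5 ms) plus
    the declared interval tolerance.  Malformed rows raise
    :class:`RecordingParseError` naming the offending line.
    """
    path = Path(path)
    if date is None:
        date = _date_from_filename(path)
    try:
        df = pd.read_csv(path, dtype=float, header=0)
    except pd.errors.ParserError as exc:  # e.g. a row with too many fields
        raise RecordingParseError(str(exc)) from exc
    if list(df.columns) != RECORDING_HEADER.split(","):
        raise RecordingParseError(
            f"expected header {RECORDING_HEADER!r}, got {','.join(df.columns)!r}", line=1
        )
    if df.empty:
        warnings.warn(f"{path.name}: header-only recording, returning empty stream")
        return DailyStream(
            date=date or _dt.date(1970, 1, 1),
            sample_rate_hz=default_sample_rate_hz,
            t_r1_max=np.empty(0),
            t_r2_mean=np.empty(0),
        )
    bad = df.isna().any(axis=1)
    if bad.any():
        raise RecordingParseError("missing field", line=int(bad.idxmax()) + 2)
    t = df["time_s"].to_numpy()
    if len(t) > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            line = int(np.argmax(dt <= 0)) + 3
            raise RecordingParseError("time not strictly increasing", line=line)
        rate = round(1.0 / np.median(dt))
        grid = t[0] + np.arange(len(t)) / rate
        off = np.abs(t - grid)
        if off.max() > _TIME_TOL_S:
            raise RecordingParseError(
                "inconsistent sampling interval", line=int(off.argmax()) + 2
            )
    else:
        rate = default_sample_rate_hz
    return DailyStream(
        date=date or _dt.date(1970, 1, 1),
        sample_rate_hz=float(rate),
        t_r1_max=df["t_r1_max_c"].to_numpy(),
        t_r2_mean=df["t_r2_mean_c"].to_numpy(),
    )


def write_detections(detections: Sequence[PersonDetection], path: str | Path) -> None:
    """CSV ``date,method,detect_time_s,temp_c,duration_s``; duration empty for FTI."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(DETECTIONS_COLUMNS) + "\n")
        for d in detections:
            date = d.date.isoformat() if d.date else ""
            dur = f"{d.duration_s:.3f}" if d.duration_s is not None else ""
            fh.write(f"{date},{d.method},{d.detect_time_s:.3f},{d.temp_c:.3f},{dur}\n")


def read_detections(path: str | Path) -> list[PersonDetection]:
    df = pd.read_csv(path)
    if list(df.columns) != DETECTIONS_COLUMNS:
        raise ValueError(f"unexpected detections header: {list(df.columns)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            PersonDetection(
                method=row.method,
                detect_time_s=float(row.detect_time_s),
                temp_c=float(row.temp_c),
                duration_s=None if pd.isna(row.duration_s) else float(row.duration_s),
                date=_dt.date.fromisoformat(row.date) if isinstance(row.date, str) else None,
            )
        )
    return out


def write_truth(
    truth_by_date: Sequence[tuple[_dt.date, Sequence[EventTruth]]], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("date,kind,start_s,duration_s,peak_temp_c,fever\n")
        for date, events in truth_by_date:
            for ev in events:
                fh.write(
                    f"{date.isoformat()},{ev.kind},{ev.start_s:.3f},"
                    f"{ev.duration_s:.3f},{ev.peak_temp_c:.3f},{int(ev.fever)}\n"
                )


def read_truth(path: str | Path) -> dict[_dt.date, list[EventTruth]]:
    df = pd.read_csv(path)
    out: dict[_dt.date, list[EventTruth]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(_dt.date.fromisoformat(row.date), []).append(
            EventTruth(
                kind=row.kind,
                start_s=float(row.start_s),
                duration_s=float(row.duration_s),
                peak_temp_c=float(row.peak_temp_c),
                fever=bool(row.fever),
            )
        )
    return out


def write_ari(ari: ARISeries, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("week_index,incidence_per_100k\n")
        for w, v in zip(ari.week_index, ari.incidence_per_100k):
            fh.write(f"{w},{v:.4f}\n")


def read_ari(path: str | Path) -> ARISeries:
    df = pd.read_csv(path)
    if list(df.columns) != ["week_index", "incidence_per_100k"]:
        raise ValueError(f"unexpected ARI header: {list(df.columns)}")
    return ARISeries(
        week_index=tuple(int(w) for w in df["week_index"]),
        incidence_per_100k=tuple(float(v) for v in df["incidence_per_100k"]),
    )


def _fmt(value: float | None) -> str:
    return "" if value is None else f"{value:.6f}"


def write_summaries(
    summaries: Sequence[DailySummary] | Sequence[WeeklySummary], path: str | Path
) -> None:
    """One row per day or week; statistic columns empty when undefined."""
    if summaries and isinstance(summaries[0], WeeklySummary):
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("week,n_persons,mean_temp_c,sd_temp_c,frac_fever,skewness,n_days,is_partial\n")
            for s in summaries:
                fh.write(
                    f"{s.week_index},{s.n_persons},{_fmt(s.mean_temp_c)},{_fmt(s.sd_temp_c)},"
                    f"{_fmt(s.frac_fever)},{_fmt(s.skewness)},{s.n_days},{int(s.is_partial)}\n"
                )
    else:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("date,n_persons,mean_temp_c,sd_temp_c,frac_fever,skewness\n")
            for s in summaries:
                fh.write(
                    f"{s.date.isoformat()},{s.n_persons},{_fmt(s.mean_temp_c)},"
                    f"{_fmt(s.sd_temp_c)},{_fmt(s.frac_fever)},{_fmt(s.skewness)}\n"
                )


def read_weekly_summaries(path: str | Path) -> list[WeeklySummary]:
    df = pd.read_csv(path)
    if "week" not in df.columns:
        raise ValueError(
            "expected weekly summaries (with a 'week' column); "
            "re-run summarize with --by week"
        )
    out = []
    for row in df.itertuples(index=False):
        out.append(
            WeeklySummary(
                week_index=int(row.week),
                n_persons=int(row.n_persons),
                mean_temp_c=None if pd.isna(row.mean_temp_c) else float(row.mean_temp_c),
                sd_temp_c=None if pd.isna(row.sd_temp_c) else float(row.sd_temp_c),
                frac_fever=None if pd.isna(row.frac_fever) else float(row.frac_fever),
                skewness=None if pd.isna(row.skewness) else float(row.skewness),
                n_days=int(row.n_days),
                is_partial=bool(row.is_partial),
            )
        )
    return out


# -- scenario configuration (flat TOML) -------------------------------------

_TUPLE_FIELDS = {
    "hourly_rate_profile",
    "face_temp_bounds",
    "event_duration_bounds",
    "short_pass_duration_bounds",
    "hot_object_temp_bounds",
}


def load_scenario_config(path: str | Path) -> ScenarioConfig:
    """Read a flat TOML scenario file; unknown keys are rejected."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    known = set(ScenarioConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
    for key in _TUPLE_FIELDS & set(raw):
        raw[key] = tuple(raw[key])
    return ScenarioConfig(**raw)


def dump_scenario_config(config: ScenarioConfig, path: str | Path) -> None:
    """Write the scenario as flat TOML (echoed into output dirs for provenance)."""
    lines = []
    for key, value in asdict(config).items():
        if isinstance(value, tuple):
            lines.append(f"{key} = [{', '.join(repr(v) for v in value)}]")
        elif isinstance(value, bool):
            lines.append(f"{key} = {'true' if value else 'false'}")
        elif isinstance(value, str):
            lines.append(f'{key} = "{value}"')
        else:
            lines.append(f"{key} = {value!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
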