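"""Temperature-time identification (TTI) of persons in a continuous stream.

A person shows up as a run of R1 samples above a threshold.  Runs closer
than a merge gap belong to the same person; merged segments are then kept
only if their peak lies in a plausible human range and they last strictly
longer than a minimum duration.

Conventions (fixed, tested at the boundaries): run membership is strict
(``R1 > t_lim``), the plausibility range is inclusive at both ends, the
duration check is strict, and gaps merge when ``gap <= merge_gap_s``.
Gap and duration are sample counts divided by the sample rate; no
interpolation between samples.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from feverwatch.synthgen import DailyStream

__all__ = [
    "PersonDetection",
    "Segment",
    "TTIConfig",
    "detect_persons_tti",
    "filter_segments",
    "find_runs",
    "merge_runs",
]


@dataclass(frozen=True)
class TTIConfig:
    """Thresholds of the segmentation: all temperatures degC, times seconds."""

    t_lim: float = 33.0
    t_min_limit: float = 33.0
    t_max_limit: float = 40.0
    min_duration_s: float = 1.0
    merge_gap_s: float = 1.0

    def __post_init__(self) -> None:
        if self.t_min_limit > self.t_max_limit:
            raise ValueError("t_min_limit must not exceed t_max_limit")
        if self.min_duration_s <= 0:
            raise ValueError("min_duration_s must be positive")
        if self.merge_gap_s < 0:
            raise ValueError("merge_gap_s must be non-negative")


@dataclass(frozen=True)
class Segment:
    """Half-open index range [start_index, end_index) of above-threshold samples."""

    start_index: int
    end_index: int
    peak_temp_c: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.start_index >= self.end_index:
            raise ValueError("segment must contain at least one sample")


@dataclass(frozen=True)
class PersonDetection:
    """One identified person; ``duration_s`` is None for FTI detections."""

    method: str  # "TTI" | "FTI"
    detect_time_s: float
    temp_c: float
    duration_s: float | None = None
    date: _dt.date | None = None
    peak_time_s: float | None = None  # diagnostic, TTI only

    def __post_init__(self) -> None:
        if self.method not in ("TTI", "FTI"):
            raise ValueError(f"unknown method {self.method!r}")


def find_runs(stream: DailyStream, t_lim: float = 33.0) -> list[Segment]:
    """Maximal contiguous runs of R1 samples strictly above ``t_lim``."""
    r1 = stream.t_r1_max
    if r1.size == 0:
        raise ValueError("stream is empty")
    above = r1 > t_lim
    # Run boundaries via sign changes of the padded indicator.
    edges = np.diff(np.concatenate(([False], above, [False])).astype(np.int8))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    rate = stream.sample_rate_hz
    return [
        Segment(
            start_index=int(s),
            end_index=int(e),
            peak_temp_c=float(r1[s:e].max()),
            duration_s=(int(e) - int(s)) / rate,
        )
        for s, e in zip(starts, ends)
    ]


def merge_runs(
    runs: Sequence[Segment], merge_gap_s: float, sample_rate: float
) -> list[Segment]:
    """Merge consecutive runs whose separation is at most ``merge_gap_s``.

    Input runs must be sorted and disjoint.  The peak of a merged segment
    is the maximum of its constituents (gap samples are below threshold,
    so this equals the maximum over the merged span).
    """
    for a, b in zip(runs, runs[1:]):
        if b.start_index < a.end_index:
            raise ValueError("runs must be sorted and disjoint")
    merged: list[Segment] = []
    for run in runs:
        if merged and (run.start_index - merged[-1].end_index) / sample_rate <= merge_gap_s:
            prev = merged[-1]
            merged[-1] = Segment(
                start_index=prev.start_index,
                end_index=run.end_index,
                peak_temp_c=max(prev.peak_temp_c, run.peak_temp_c),
                duration_s=(run.end_index - prev.start_index) / sample_rate,
            )
        else:
            merged.append(run)
    return merged


def filter_segments(
    segments: Sequence[Segment],
    config: TTIConfig,
    sample_rate: float,
    date: _dt.date | None = None,
) -> list[PersonDetection]:
    """Keep segments with a plausible peak and a strictly long-enough duration."""
    out: list[PersonDetection] = []
    for seg in segments:
        if not config.t_min_limit <= seg.peak_temp_c <= config.t_max_limit:
            continue
        if not seg.duration_s > config.min_duration_s:
            continue
        out.append(
            PersonDetection(
                method="TTI",
                detect_time_s=seg.start_index / sample_rate,
                temp_c=seg.peak_temp_c,
                duration_s=seg.duration_s,
                date=date,
            )
        )
    return out


def detect_persons_tti(
    stream: DailyStream, config: TTIConfig | None = None
) -> list[PersonDetection]:
    """Full TTI pipeline: threshold runs, gap merge, range/duration filter.

    Detections carry the segment start time, the segment peak temperature
    and (diagnostically) the time of the peak sample.
    """
    config = config or TTIConfig()
    rate = stream.sample_rate_hz
    runs = find_runs(stream, config.t_lim)
    segments = merge_runs(runs, config.merge_gap_s, rate)
    detections = filter_segments(segments, config, rate, date=stream.date)
    # attach peak times from the stream for diagnostics
    out = []
    kept = [
        seg
        for seg in segments
        if config.t_min_limit <= seg.peak_temp_c <= config.t_max_limit
        and seg.duration_s > config.min_duration_s
    ]
    for det, seg in zip(detections, kept):
        peak_idx = seg.start_index + int(
            np.argmax(stream.t_r1_max[seg.start_index : seg.end_index])
        )
        out.append(
            PersonDetection(
                method=det.method,
                detect_time_s=det.detect_time_s,
                temp_c=det.temp_c,
                duration_s=det.duration_s,
                date=det.date,
                peak_time_s=peak_idx / rate,
            )
        )
    return out
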