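"""Alarm-driven single-frame capture and FTI person identification.

Emulates the recorder's alarm function: the first R1 sample above the
threshold triggers an alarm, one frame is captured at the first sample at
or after ``trigger + capture_delay``, and the alarm rearms only after a
sample at or below the threshold.  A ground-truth orientation oracle
(front/back of head) stands in for the image classifier: the captured
frame is labelled by the truth event overlapping the capture instant.

Face temperature identification (FTI) then takes the single captured
sample of every front-of-head frame as that person's temperature.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

from feverwatch.synthgen import DailyStream, EventTruth
from feverwatch.tti import PersonDetection, find_runs

__all__ = [
    "AlarmConfig",
    "CameraConfig",
    "CapturedFrame",
    "FTIOutput",
    "detect_persons_fti",
    "simulate_alarm_captures",
]


@dataclass(frozen=True)
class CameraConfig:
    """Native camera frame rate and the decimation used by the recorder."""

    fps: float = 27.0
    frame_decimation: int = 3

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.frame_decimation < 1:
            raise ValueError("frame_decimation must be >= 1")

    @property
    def sample_rate_hz(self) -> float:
        """Continuous-recorder output rate (every n-th native frame)."""
        return self.fps / self.frame_decimation


@dataclass(frozen=True)
class AlarmConfig:
    threshold_c: float = 33.0
    capture_delay_s: float = 0.6

    def __post_init__(self) -> None:
        if self.capture_delay_s < 0:
            raise ValueError("capture_delay_s must be non-negative")


@dataclass(frozen=True)
class CapturedFrame:
    """One alarm-triggered frame: capture time, R1 sample, orientation label."""

    capture_time_s: float
    temp_c: float
    label: str  # "head_front" | "head_back" | "none"

    def __post_init__(self) -> None:
        if self.label not in ("head_front", "head_back", "none"):
            raise ValueError(f"unknown label {self.label!r}")


_KIND_TO_LABEL = {
    "person_front": "head_front",
    "person_back": "head_back",
    "short_pass": "head_back",
    "hot_object": "none",
}


def _label_at(truth: Sequence[EventTruth], t: float) -> str:
    """Orientation oracle: label of the truth event covering time ``t``.

    Ties between overlapping events go to the later start.
    """
    best: EventTruth | None = None
    for ev in truth:
        if ev.start_s <= t < ev.end_s and (best is None or ev.start_s >= best.start_s):
            best = ev
    return _KIND_TO_LABEL[best.kind] if best is not None else "none"


def simulate_alarm_captures(
    stream: DailyStream,
    truth: Sequence[EventTruth],
    config: AlarmConfig | None = None,
) -> list[CapturedFrame]:
    """Run the armed/triggered/rearm state machine over one day.

    Each maximal above-threshold run corresponds to exactly one alarm
    cycle (trigger at its first sample, rearm at the first sample at or
    below threshold after it), hence at most one frame per run.  A
    trigger whose capture instant falls past the end of the stream yields
    no frame.
    """
    config = config or AlarmConfig()
    rate = stream.sample_rate_hz
    n = len(stream)
    delay_samples = math.ceil(config.capture_delay_s * rate)
    frames: list[CapturedFrame] = []
    for run in find_runs(stream, config.threshold_c):
        cap = run.start_index + delay_samples
        if cap >= n:
            continue
        t = cap / rate
        frames.append(
            CapturedFrame(
                capture_time_s=t,
                temp_c=float(stream.t_r1_max[cap]),
                label=_label_at(truth, t),
            )
        )
    return frames


class FTIOutput(NamedTuple):
    """FTI detections plus back-of-head frames kept for diagnostics."""

    detections: list[PersonDetection]
    back_frames: list[CapturedFrame]


def detect_persons_fti(
    frames: Sequence[CapturedFrame], date: _dt.date | None = None
) -> FTIOutput:
    """One FTI detection per front-of-head frame; backs tallied separately.

    Frames without a head (hot objects, empty field of view) yield
    nothing.
    """
    detections = [
        PersonDetection(
            method="FTI",
            detect_time_s=f.capture_time_s,
            temp_c=f.temp_c,
            duration_s=None,
            date=date,
        )
        for f in frames
        if f.label == "head_front"
    ]
    backs = [f for f in frames if f.label == "head_back"]
    return FTIOutput(detections=detections, back_frames=backs)
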