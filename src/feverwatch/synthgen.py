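"""Synthetic generator for doorway IR temperature recordings.

Produces full-day continuous streams (maximum face-region temperature R1
and mean ambient-region temperature R2, uniformly sampled) together with
the ground-truth event list needed to score detection algorithms, and
multi-week studies whose weekly fever prevalence is linearly coupled to a
synthetic acute-respiratory-infection (ARI) incidence series.

Arrivals follow a non-homogeneous Poisson process with an hourly rate
profile (thinning algorithm).  Each pass renders a trapezoidal excursion
of the R1 stream above the cool baseline; per-sample Gaussian sensor
noise is added on top.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "ARIModel",
    "ARISeries",
    "DEFAULT_HOURLY_PROFILE",
    "DailyStream",
    "EventTruth",
    "ScenarioConfig",
    "fever_probability",
    "generate_day",
    "generate_study",
    "iter_study_days",
    "simulate_arrivals",
]

SECONDS_PER_DAY = 86_400

#: Default hourly arrival-rate profile (persons/hour, index = hour of day).
#: Shaped after a pharmacy open 9-21 with a morning peak near 10 o'clock
#: and a sustained afternoon plateau above 60/h; integrates to 650/day.
DEFAULT_HOURLY_PROFILE: tuple[float, ...] = (
    0, 0, 0, 0, 0, 0, 0, 0, 0,  # 0-8: closed
    45, 65, 50, 45,             # 9-12
    62, 63, 64, 63, 62, 61,     # 13-18: afternoon plateau
    40, 30,                     # 19-20
    0, 0, 0,                    # 21-23: closed
)


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of the simulated doorway scenario.

    Temperatures are degrees Celsius, durations seconds, rates per hour
    or per day as named.  Validated on construction.
    """

    open_hour: int = 9
    close_hour: int = 21
    hourly_rate_profile: tuple[float, ...] = DEFAULT_HOURLY_PROFILE
    p_front: float = 0.7
    face_temp_mean: float = 35.1
    face_temp_sd: float = 0.9
    face_temp_bounds: tuple[float, float] = (33.5, 39.5)
    back_temp_offset: float = 3.0
    fever_temp_mean: float = 37.8
    fever_temp_sd: float = 0.4
    p_fever_base: float = 0.01
    fever_ari_slope: float = 2e-5
    event_duration_bounds: tuple[float, float] = (1.2, 4.0)
    short_pass_rate: float = 30.0
    short_pass_duration_bounds: tuple[float, float] = (0.3, 0.95)
    hot_object_rate: float = 5.0
    hot_object_temp_bounds: tuple[float, float] = (34.0, 60.0)
    baseline_r1_mean: float = 26.0
    baseline_r2_mean: float = 20.0
    noise_sd: float = 0.08
    sample_rate: float = 9.0
    min_event_gap_s: float = 1.5
    allow_overlap: bool = False
    # Rise/fall time of the rendered excursion.  Kept short so that the
    # above-threshold run of a person event spans nearly the full event
    # duration (people fill region R1 almost immediately when the door
    # opens); long ramps would make >1.2 s events invisible to a 1 s
    # duration filter.
    ramp_s: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_front", "p_fever_base"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for name in (
            "face_temp_bounds",
            "event_duration_bounds",
            "short_pass_duration_bounds",
            "hot_object_temp_bounds",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be an ordered interval, got ({lo}, {hi})")
        if not 0 <= self.open_hour <= self.close_hour <= 24:
            raise ValueError("opening hours must satisfy 0 <= open <= close <= 24")
        if self.baseline_r1_mean >= 33.0 or self.baseline_r2_mean >= 33.0:
            raise ValueError("baseline temperatures must stay below 33 degC")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if len(self.hourly_rate_profile) != 24:
            raise ValueError("hourly_rate_profile needs 24 entries")
        if any(r < 0 for r in self.hourly_rate_profile):
            raise ValueError("arrival rates must be non-negative")
        if self.short_pass_rate < 0 or self.hot_object_rate < 0:
            raise ValueError("event rates must be non-negative")
        if self.short_pass_duration_bounds[1] >= 1.0:
            raise ValueError("short passes must last under 1 s")

    def with_(self, **kwargs) -> "ScenarioConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class EventTruth:
    """Ground-truth doorway event used to score detections."""

    kind: str  # person_front | person_back | short_pass | hot_object
    start_s: float
    duration_s: float
    peak_temp_c: float
    fever: bool = False

    KINDS = ("person_front", "person_back", "short_pass", "hot_object")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not 0 <= self.start_s < SECONDS_PER_DAY:
            raise ValueError("start_s must lie within the day")
        if self.kind == "short_pass" and self.duration_s >= 1.0:
            raise ValueError("short_pass events must last under 1 s")

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s

    @property
    def is_person(self) -> bool:
        return self.kind in ("person_front", "person_back")


@dataclass
class DailyStream:
    """One day of uniformly sampled R1-max / R2-mean temperatures.

    Sample ``i`` is taken at ``i / sample_rate_hz`` seconds after
    midnight.
    """

    date: _dt.date
    sample_rate_hz: float
    t_r1_max: np.ndarray
    t_r2_mean: np.ndarray

    def __post_init__(self) -> None:
        self.t_r1_max = np.asarray(self.t_r1_max, dtype=float)
        self.t_r2_mean = np.asarray(self.t_r2_mean, dtype=float)
        if self.t_r1_max.shape != self.t_r2_mean.shape:
            raise ValueError("R1 and R2 traces must have equal length")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    def __len__(self) -> int:
        return int(self.t_r1_max.shape[0])

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self)) / self.sample_rate_hz


@dataclass(frozen=True)
class ARISeries:
    """Weekly ARI incidence per 100,000 population."""

    week_index: tuple[int, ...]
    incidence_per_100k: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.week_index) != len(self.incidence_per_100k):
            raise ValueError("week_index and incidence must have equal length")
        if any(v < 0 for v in self.incidence_per_100k):
            raise ValueError("incidence must be non-negative")

    def __len__(self) -> int:
        return len(self.week_index)


@dataclass(frozen=True)
class ARIModel:
    """Sinusoidal seasonal model for the weekly ARI incidence.

    incidence(w) = max(0, baseline + amplitude * sin(2 pi w / period) + eps)
    with eps ~ N(0, noise_sd).
    """

    baseline: float = 800.0
    amplitude: float = 600.0
    period: float = 26.0
    noise_sd: float = 40.0

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def fever_probability(config: ScenarioConfig, incidence_per_100k: float) -> float:
    """Weekly fever prevalence linearly coupled to ARI incidence, clamped to [0, 1]."""
    p = config.p_fever_base + config.fever_ari_slope * incidence_per_100k
    return min(1.0, max(0.0, p))


def simulate_arrivals(
    profile: Sequence[float],
    open_hour: float = 9,
    close_hour: float = 21,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw arrival times (seconds since midnight) from a non-homogeneous
    Poisson process with piecewise-constant hourly rates, via thinning.

    Arrivals outside ``[open_hour, close_hour)`` are suppressed.  Returns
    a sorted float array.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.shape != (24,):
        raise ValueError("profile needs 24 hourly rates")
    if np.any(profile < 0):
        raise ValueError("arrival rates must be non-negative")
    rng = _as_rng(seed)

    t0, t1 = open_hour * 3600.0, close_hour * 3600.0
    lam_max = float(profile.max()) / 3600.0  # per second
    if lam_max == 0.0 or t1 <= t0:
        return np.empty(0, dtype=float)

    # Homogeneous candidates at lam_max over the open interval, thinned by
    # the hour-of-day rate ratio.
    n_cand = rng.poisson(lam_max * (t1 - t0))
    cand = np.sort(rng.uniform(t0, t1, size=n_cand))
    hours = np.minimum((cand // 3600).astype(int), 23)
    accept = rng.uniform(size=n_cand) < profile[hours] / 3600.0 / lam_max
    return cand[accept]


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    """Rejection-sampled truncated normal draw (bounds are wide; cheap)."""
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(mean, lo), hi))  # pragma: no cover - pathological bounds


def _draw_events(
    config: ScenarioConfig, p_fever: float, rng: np.random.Generator
) -> list[EventTruth]:
    events: list[EventTruth] = []
    arrivals = simulate_arrivals(
        config.hourly_rate_profile, config.open_hour, config.close_hour, rng
    )
    dlo, dhi = config.event_duration_bounds
    for t in arrivals:
        fever = bool(rng.uniform() < p_fever)
        if fever:
            face = _truncated_normal(
                rng, config.fever_temp_mean, config.fever_temp_sd, 33.5, 42.0
            )
        else:
            face = _truncated_normal(
                rng,
                config.face_temp_mean,
                config.face_temp_sd,
                *config.face_temp_bounds,
            )
        front = bool(rng.uniform() < config.p_front)
        peak = face if front else face - config.back_temp_offset
        events.append(
            EventTruth(
                kind="person_front" if front else "person_back",
                start_s=float(t),
                duration_s=float(rng.uniform(dlo, dhi)),
                peak_temp_c=peak,
                fever=fever,
            )
        )

    open_s, close_s = config.open_hour * 3600.0, config.close_hour * 3600.0
    span = max(close_s - open_s, 0.0)
    if span > 0:
        slo, shi = config.short_pass_duration_bounds
        for _ in range(rng.poisson(config.short_pass_rate)):
            face = _truncated_normal(
                rng,
                config.face_temp_mean,
                config.face_temp_sd,
                *config.face_temp_bounds,
            )
            events.append(
                EventTruth(
                    kind="short_pass",
                    start_s=float(rng.uniform(open_s, close_s)),
                    duration_s=float(rng.uniform(slo, shi)),
                    peak_temp_c=face - config.back_temp_offset,
                )
            )
        hlo, hhi = config.hot_object_temp_bounds
        for _ in range(rng.poisson(config.hot_object_rate)):
            events.append(
                EventTruth(
                    kind="hot_object",
                    start_s=float(rng.uniform(open_s, close_s)),
                    duration_s=float(rng.uniform(dlo, dhi)),
                    peak_temp_c=float(rng.uniform(hlo, hhi)),
                )
            )

    events.sort(key=lambda e: e.start_s)
    if not config.allow_overlap:
        events = _separate_events(events, config.min_event_gap_s)
    return events


def _separate_events(events: list[EventTruth], gap_s: float) -> list[EventTruth]:
    """Push overlapping/too-close events apart to a minimum start-after-end gap.

    The automatic door separates people; true overlaps are only produced
    when explicitly enabled.  Events pushed past midnight are dropped.
    """
    out: list[EventTruth] = []
    prev_end = -math.inf
    for ev in events:
        start = max(ev.start_s, prev_end + gap_s)
        if start + ev.duration_s >= SECONDS_PER_DAY:
            continue
        if start != ev.start_s:
            ev = replace(ev, start_s=start)
        out.append(ev)
        prev_end = ev.end_s
    return out


def _render_stream(
    config: ScenarioConfig,
    date: _dt.date,
    events: Sequence[EventTruth],
    rng: np.random.Generator,
) -> DailyStream:
    rate = config.sample_rate
    n = int(round(SECONDS_PER_DAY * rate))
    r1 = np.full(n, config.baseline_r1_mean)
    for ev in events:
        ramp = min(config.ramp_s, ev.duration_s / 2.0)
        i0 = int(math.ceil(ev.start_s * rate))
        i1 = int(math.floor(ev.end_s * rate))
        if i1 < i0 or i0 >= n:
            continue
        i1 = min(i1, n - 1)
        rel = np.arange(i0, i1 + 1) / rate - ev.start_s
        if ramp > 0:
            shape = np.minimum(1.0, np.minimum(rel, ev.duration_s - rel) / ramp)
            shape = np.clip(shape, 0.0, 1.0)
        else:
            shape = np.ones_like(rel)
        profile = config.baseline_r1_mean + (ev.peak_temp_c - config.baseline_r1_mean) * shape
        np.maximum(r1[i0 : i1 + 1], profile, out=r1[i0 : i1 + 1])
    if config.noise_sd > 0:
        r1 = r1 + rng.normal(0.0, config.noise_sd, size=n)
        r2 = config.baseline_r2_mean + rng.normal(0.0, config.noise_sd, size=n)
    else:
        r2 = np.full(n, config.baseline_r2_mean)
    return DailyStream(date=date, sample_rate_hz=rate, t_r1_max=r1, t_r2_mean=r2)


def generate_day(
    config: ScenarioConfig,
    date: _dt.date,
    p_fever: float | None = None,
    seed: int | np.random.Generator | None = None,
) -> tuple[DailyStream, list[EventTruth]]:
    """Simulate one day: draw events, render the R1/R2 streams, return truth.

    ``p_fever`` defaults to ``config.p_fever_base``.
    """
    if p_fever is None:
        p_fever = config.p_fever_base
    if not 0.0 <= p_fever <= 1.0:
        raise ValueError(f"p_fever must be in [0, 1], got {p_fever}")
    rng = _as_rng(config.seed if seed is None else seed)
    events = _draw_events(config, p_fever, rng)
    stream = _render_stream(config, date, events, rng)
    return stream, events


def _day_rng(seed: int, day_index: int) -> np.random.Generator:
    # Independent, reproducible substream per (seed, day).
    return np.random.default_rng([seed, 1, day_index])


def simulate_ari_series(
    model: ARIModel, n_weeks: int, seed: int | np.random.Generator | None = None
) -> ARISeries:
    """Draw the weekly incidence series from the seasonal model."""
    if n_weeks < 1:
        raise ValueError("n_weeks must be >= 1")
    rng = _as_rng(seed)
    w = np.arange(n_weeks)
    inc = model.baseline + model.amplitude * np.sin(2 * np.pi * w / model.period)
    if model.noise_sd > 0:
        inc = inc + rng.normal(0.0, model.noise_sd, size=n_weeks)
    inc = np.maximum(inc, 0.0)
    return ARISeries(week_index=tuple(int(i) for i in w), incidence_per_100k=tuple(float(v) for v in inc))


def iter_study_days(
    config: ScenarioConfig,
    n_weeks: int,
    days_per_week: int = 7,
    ari_model: ARIModel | None = None,
    seed: int | None = None,
    start_date: _dt.date = _dt.date(2022, 4, 22),
) -> Iterator[tuple[int, _dt.date, DailyStream, list[EventTruth]]]:
    """Lazily yield ``(week_index, date, stream, truth)`` for a study.

    Memory-friendly companion to :func:`generate_study`: each day is
    generated on demand from its own ``(seed, day)`` substream, so a long
    study never holds more than one day in memory.
    """
    if n_weeks < 1:
        raise ValueError("n_weeks must be >= 1")
    if not 1 <= days_per_week <= 7:
        raise ValueError("days_per_week must be in 1..7")
    ari_model = ari_model or ARIModel()
    base_seed = config.seed if seed is None else seed
    ari = simulate_ari_series(ari_model, n_weeks, np.random.default_rng([base_seed, 0]))
    for week in range(n_weeks):
        p_fever = fever_probability(config, ari.incidence_per_100k[week])
        for d in range(days_per_week):
            day_index = week * 7 + d
            date = start_date + _dt.timedelta(days=day_index)
            stream, truth = generate_day(
                config, date, p_fever, _day_rng(base_seed, day_index)
            )
            yield week, date, stream, truth


def generate_study(
    config: ScenarioConfig,
    n_weeks: int,
    days_per_week: int = 7,
    ari_model: ARIModel | None = None,
    seed: int | None = None,
    start_date: _dt.date = _dt.date(2022, 4, 22),
) -> tuple[list[tuple[DailyStream, list[EventTruth]]], ARISeries]:
    """Simulate a multi-week study with ARI-coupled fever prevalence.

    Returns all day streams materialized; for studies longer than a few
    weeks prefer :func:`iter_study_days` (a 9 Hz day is ~780k samples).
    """
    ari_model = ari_model or ARIModel()
    base_seed = config.seed if seed is None else seed
    ari = simulate_ari_series(ari_model, n_weeks, np.random.default_rng([base_seed, 0]))
    days = [
        (stream, truth)
        for _, _, stream, truth in iter_study_days(
            config, n_weeks, days_per_week, ari_model, base_seed, start_date
        )
    ]
    return days, ari
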