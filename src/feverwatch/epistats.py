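"""Daily/weekly surveillance statistics and ARI correlation.

Fever rule: a detection counts as feverish when its temperature is
strictly above the threshold (default 37.5 degC).  Standard deviations
use the n-1 denominator; skewness is the Fisher-Pearson moment
coefficient g1.  Weekly statistics pool the individual detection
temperatures of the week (they are not averages of daily statistics).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _sps

from feverwatch.synthgen import ARISeries
from feverwatch.tti import PersonDetection

__all__ = [
    "CorrelationResult",
    "DailySummary",
    "FEVER_THRESHOLD_C",
    "WeeklySummary",
    "correlate_with_ari",
    "pearson",
    "skewness",
    "summarize_day",
    "weekly_aggregate",
    "zscore_normalize",
]

#: Cut between "healthy" and "possibly sick" detections, degC (strict >).
FEVER_THRESHOLD_C = 37.5

STATISTICS = ("n_persons", "frac_fever", "skewness", "mean_temp")


@dataclass(frozen=True)
class DailySummary:
    date: _dt.date
    n_persons: int
    hourly_counts: tuple[int, ...]
    mean_temp_c: float | None
    sd_temp_c: float | None
    frac_fever: float | None
    skewness: float | None

    def __post_init__(self) -> None:
        if sum(self.hourly_counts) != self.n_persons:
            raise ValueError("hourly_counts must sum to n_persons")
        if self.frac_fever is not None and not 0.0 <= self.frac_fever <= 1.0:
            raise ValueError("frac_fever must lie in [0, 1]")


@dataclass(frozen=True)
class WeeklySummary:
    week_index: int
    n_persons: int
    mean_temp_c: float | None
    sd_temp_c: float | None
    frac_fever: float | None
    skewness: float | None
    n_days: int
    is_partial: bool


@dataclass(frozen=True)
class CorrelationResult:
    pearson_r: float
    slope: float
    intercept: float
    n_points: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.pearson_r <= 1.0 + 1e-12:
            raise ValueError("|pearson_r| must not exceed 1")
        if self.n_points < 3:
            raise ValueError("n_points must be >= 3")


def skewness(values: Sequence[float]) -> float:
    """Fisher-Pearson moment skewness g1 = m3 / m2**1.5.

    Raises ``ValueError`` for fewer than 3 values or zero variance.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("skewness needs at least 3 values")
    if np.ptp(x) == 0:
        raise ValueError("skewness undefined for zero variance")
    return float(_sps.skew(x, bias=True))


def _temp_stats(
    temps: np.ndarray, fever_threshold_c: float
) -> tuple[float | None, float | None, float | None, float | None]:
    """(mean, sd, frac_fever, skewness) with the < 3 / zero-variance rules."""
    n = temps.size
    frac = float(np.mean(temps > fever_threshold_c)) if n else None
    if n < 3:
        return None, None, frac, None
    mean = float(np.mean(temps))
    sd = float(np.std(temps, ddof=1))
    skew = skewness(temps) if np.ptp(temps) > 0 else None
    return mean, sd, frac, skew


def summarize_day(
    detections: Sequence[PersonDetection],
    date: _dt.date,
    fever_threshold_c: float = FEVER_THRESHOLD_C,
) -> DailySummary:
    """Daily counts, hourly histogram and temperature statistics."""
    for det in detections:
        if det.date is not None and det.date != date:
            raise ValueError(f"detection dated {det.date} passed to summary for {date}")
    temps = np.array([d.temp_c for d in detections], dtype=float)
    hours = [min(int(d.detect_time_s // 3600), 23) for d in detections]
    hourly = [0] * 24
    for h in hours:
        hourly[h] += 1
    mean, sd, frac, skew = _temp_stats(temps, fever_threshold_c)
    return DailySummary(
        date=date,
        n_persons=len(detections),
        hourly_counts=tuple(hourly),
        mean_temp_c=mean,
        sd_temp_c=sd,
        frac_fever=frac,
        skewness=skew,
    )


def weekly_aggregate(
    daily_summaries: Sequence[DailySummary],
    detections: Sequence[PersonDetection],
    week_length_days: int = 7,
    fever_threshold_c: float = FEVER_THRESHOLD_C,
) -> list[WeeklySummary]:
    """Pool detections into consecutive weeks counted from the first date.

    Weekly mean/sd/frac_fever/skewness are recomputed from the pooled
    detection temperatures of the week.  A week covering fewer than
    ``week_length_days`` summarized days is flagged partial.
    """
    if not daily_summaries:
        return []
    if any(d.date is None for d in detections):
        raise ValueError("weekly aggregation needs dated detections")
    origin = min(s.date for s in daily_summaries)
    day_weeks = {s.date: (s.date - origin).days // week_length_days for s in daily_summaries}
    n_weeks = max(day_weeks.values()) + 1
    temps_by_week: list[list[float]] = [[] for _ in range(n_weeks)]
    for det in detections:
        if det.date not in day_weeks:
            raise ValueError(f"detection dated {det.date} has no daily summary")
        temps_by_week[day_weeks[det.date]].append(det.temp_c)
    days_by_week = [0] * n_weeks
    for s in daily_summaries:
        days_by_week[day_weeks[s.date]] += 1
    out = []
    for w in range(n_weeks):
        temps = np.asarray(temps_by_week[w], dtype=float)
        mean, sd, frac, skew = _temp_stats(temps, fever_threshold_c)
        out.append(
            WeeklySummary(
                week_index=w,
                n_persons=temps.size,
                mean_temp_c=mean,
                sd_temp_c=sd,
                frac_fever=frac,
                skewness=skew,
                n_days=days_by_week[w],
                is_partial=days_by_week[w] < week_length_days,
            )
        )
    return out


def zscore_normalize(series: Sequence[float]) -> np.ndarray:
    """(x - mean) / sd with the n-1 denominator; mean 0 / sd 1 output."""
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("normalization needs at least 2 points")
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise ValueError("cannot normalize a constant series")
    return (x - np.mean(x)) / sd


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Product-moment correlation plus least-squares line of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("pearson needs at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson undefined for constant input")
    dx = x - x.mean()
    dy = y - y.mean()
    r = float(np.dot(dx, dy) / np.sqrt(np.dot(dx, dx) * np.dot(dy, dy)))
    r = max(-1.0, min(1.0, r))
    fit = _sps.linregress(x, y)
    return CorrelationResult(
        pearson_r=r, slope=float(fit.slope), intercept=float(fit.intercept), n_points=x.size
    )


def correlate_with_ari(
    weekly: Sequence[WeeklySummary],
    ari: ARISeries,
    statistic: str = "frac_fever",
    include_partial: bool = False,
) -> CorrelationResult:
    """Correlate a weekly surveillance statistic with the ARI incidence.

    Both series are z-score normalized over the overlapping weeks before
    the correlation.  Partial weeks are excluded unless requested; weeks
    where the statistic is undefined are dropped.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"statistic must be one of {STATISTICS}")
    ari_by_week = dict(zip(ari.week_index, ari.incidence_per_100k))
    xs, ys = [], []
    for w in weekly:
        if w.is_partial and not include_partial:
            continue
        if w.week_index not in ari_by_week:
            continue
        value = {
            "n_persons": float(w.n_persons),
            "frac_fever": w.frac_fever,
            "skewness": w.skewness,
            "mean_temp": w.mean_temp_c,
        }[statistic]
        if value is None:
            continue
        xs.append(value)
        ys.append(ari_by_week[w.week_index])
    if len(xs) < 3:
        raise ValueError("need at least 3 overlapping weeks with defined statistics")
    return pearson(zscore_normalize(xs), zscore_normalize(ys))
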