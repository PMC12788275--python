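"""Per-participant lifelog feature derivation.

Six predictors are derived from the raw streams: usual gait speed (see
:mod:`frailtylog.gait`), the 30 s chair-stand repetition count from the
in-app accelerometer task, daily and hourly mean step counts from timestamped
pedometer records, and period means of two daily self-reports — RPE (rating
of perceived exertion, 1-15) and subjective health (1 = very good ... 4 =
very bad, so larger means worse).

Conventions:

* Calendar days and clock hours are local civil time, by default UTC+9
  (the study region's timezone); the offset is configurable.
* Daily mean steps averages per-day totals over days that have at least one
  record (a recorded all-zero day counts as 0).
* Hourly mean steps averages per-hour totals over *active* hours (>= 1
  step).  Under these definitions, daily mean = hourly mean x (mean active
  hours per recorded day) exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "DEFAULT_TZ_OFFSET_HOURS",
    "StsParams",
    "LifelogFeatureSet",
    "daily_mean_steps",
    "hourly_mean_steps",
    "mean_active_hours_per_day",
    "count_sts_reps",
    "aggregate_rpe",
    "aggregate_subjective_health",
]

DEFAULT_TZ_OFFSET_HOURS = 9.0

RPE_RANGE = (1, 15)
HEALTH_RANGE = (1, 4)


class FeatureValidationError(ValueError):
    """Raised for out-of-range self-reports or malformed traces."""


@dataclass(frozen=True)
class StsParams:
    """Chair-stand repetition counting parameters.

    The trace is de-meaned, smoothed with a trailing mean of ``smooth_s``
    seconds, and repetitions are counted as peaks with prominence of at least
    ``min_prominence`` m/s^2 separated by at least ``min_separation_s``.
    """

    smooth_s: float = 0.5
    min_prominence: float = 0.5
    min_separation_s: float = 1.0
    min_duration_s: float = 25.0
    max_duration_s: float = 35.0


@dataclass
class LifelogFeatureSet:
    """Derived predictors for one participant (None = not measurable)."""

    participant_id: object
    usual_gait_speed: float | None = None
    sts_counts: float | None = None
    daily_mean_steps: float | None = None
    hourly_mean_steps: float | None = None
    rpe: float | None = None
    subjective_health: float | None = None


def _local_seconds(t: np.ndarray, tz_offset_hours: float) -> np.ndarray:
    return np.asarray(t, dtype=float) + tz_offset_hours * 3600.0


def _day_sums(records: pd.DataFrame, tz_offset_hours: float) -> pd.Series:
    local = _local_seconds(records["t"].to_numpy(), tz_offset_hours)
    day = np.floor(local / 86400.0).astype(np.int64)
    return records.groupby(day)["steps"].sum()


def daily_mean_steps(
    records: pd.DataFrame, tz_offset_hours: float = DEFAULT_TZ_OFFSET_HOURS
) -> float | None:
    """Mean of per-local-day step totals over days with >= 1 record."""
    if len(records) == 0:
        return None
    if (records["steps"].to_numpy() < 0).any():
        raise FeatureValidationError("step counts must be non-negative")
    return float(_day_sums(records, tz_offset_hours).mean())


def _hour_sums(records: pd.DataFrame, tz_offset_hours: float) -> pd.Series:
    local = _local_seconds(records["t"].to_numpy(), tz_offset_hours)
    hour = np.floor(local / 3600.0).astype(np.int64)
    return records.groupby(hour)["steps"].sum()


def hourly_mean_steps(
    records: pd.DataFrame, tz_offset_hours: float = DEFAULT_TZ_OFFSET_HOURS
) -> float | None:
    """Mean of per-clock-hour step totals over active hours (>= 1 step)."""
    if len(records) == 0:
        return None
    sums = _hour_sums(records, tz_offset_hours)
    active = sums[sums >= 1]
    if len(active) == 0:
        return None
    return float(active.mean())


def mean_active_hours_per_day(
    records: pd.DataFrame, tz_offset_hours: float = DEFAULT_TZ_OFFSET_HOURS
) -> float | None:
    """Active hours (>= 1 step) divided by days with >= 1 record."""
    if len(records) == 0:
        return None
    n_days = _day_sums(records, tz_offset_hours).size
    sums = _hour_sums(records, tz_offset_hours)
    return float((sums >= 1).sum() / n_days)


def count_sts_reps(t, az, rate: float | None = None, params: StsParams = StsParams()) -> int:
    """Count chair-rise repetitions in a ~30 s vertical-acceleration trace.

    ``t`` is in seconds (relative), ``az`` in m/s^2.  The sampling rate is
    inferred from the timestamps unless given.  Traces outside the accepted
    duration window raise :class:`FeatureValidationError`.
    """
    t = np.asarray(t, dtype=float)
    az = np.asarray(az, dtype=float)
    if t.ndim != 1 or t.shape != az.shape or len(t) < 2:
        raise FeatureValidationError("trace must be two equal-length 1-d arrays")
    duration = float(t[-1] - t[0])
    if rate is None:
        rate = (len(t) - 1) / duration
    # Nominal duration includes the final sampling interval.
    if not params.min_duration_s <= duration + 1.0 / rate <= params.max_duration_s:
        raise FeatureValidationError(
            f"trace duration {duration:.2f}s outside [{params.min_duration_s}, {params.max_duration_s}]s"
        )
    x = az - az.mean()
    win = max(1, int(round(params.smooth_s * rate)))
    x = pd.Series(x).rolling(win, min_periods=1).mean().to_numpy()
    # The separation constraint carries a 10% tolerance: repetitions at
    # exactly the boundary cadence jitter by a few samples under sensor
    # noise and must not be dropped by the greedy peak pruning.
    peaks, _ = find_peaks(
        x,
        prominence=params.min_prominence,
        distance=max(1, int(round(0.9 * params.min_separation_s * rate))),
    )
    return int(len(peaks))


def _aggregate_ordinal(values, lo: int, hi: int, what: str) -> float | None:
    arr = np.asarray(list(values), dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        return None
    if not np.all(arr == np.round(arr)):
        raise FeatureValidationError(f"{what} values must be integers")
    if arr.min() < lo or arr.max() > hi:
        raise FeatureValidationError(f"{what} values must lie in [{lo}, {hi}]")
    return float(arr.mean())


def aggregate_rpe(reports) -> float | None:
    """Mean RPE (1-15) over reported days; None if no reports."""
    return _aggregate_ordinal(reports, *RPE_RANGE, "RPE")


def aggregate_subjective_health(reports) -> float | None:
    """Mean subjective-health rating (1-4, higher = worse); None if none."""
    return _aggregate_ordinal(reports, *HEALTH_RANGE, "subjective health")
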