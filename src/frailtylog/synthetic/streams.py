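"""Raw lifelog stream simulators: GPS, pedometer, chair-stand trace, reports.

GPS tracks are generated in a local east/north frame (exact ground-truth
speed control) and mapped to WGS84 with an incremental equirectangular
conversion, so the haversine distance between consecutive fixes reproduces
the planted step length to well below 1e-6 m.  Positional error is an AR(1)
process per axis — marginal SD ``gps_noise_sd``, correlation time
``gps_noise_tau_s`` — which models the slowly drifting bias of consumer GPS
rather than white noise.  Occasional single-point glitches produce the
out-of-band speed spikes the refinement pipeline must reject.

Timestamps count forward from a local-midnight epoch (``BASE_EPOCH``); all
streams for one participant are reproducible from ``(config.seed,
participant index)`` alone.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import (
    BASE_EPOCH,
    CohortConfig,
    ParticipantTruth,
    STREAM_ACCEL,
    STREAM_GPS,
    STREAM_REPORTS,
    STREAM_STEPS,
)

__all__ = [
    "simulate_gps_log",
    "simulate_pedometer",
    "simulate_sts_accel",
    "simulate_self_reports",
    "make_walk_log",
]

EARTH_RADIUS_M = 6_371_000.0
_GPS_COLUMNS = ["t", "lat", "lon", "activity"]
_MISLABEL_CHOICES = np.array(["ON_FOOT", "STILL", "OTHER"])

# local diurnal step-weight profile (probability of an hour being active)
_HOUR_WEIGHTS = np.array(
    [0.2, 0.1, 0.1, 0.1, 0.2, 0.5, 1.5, 3.0, 4.0, 4.0, 3.5, 3.5,
     3.0, 3.0, 3.0, 3.5, 3.5, 3.0, 2.5, 2.0, 1.5, 1.0, 0.5, 0.3]
)


def _latlon_from_local(x: np.ndarray, y: np.ndarray, lat0: float, lon0: float):
    """Incremental equirectangular mapping of local metres to WGS84 degrees."""
    deg = 180.0 / np.pi
    lat = lat0 + (y / EARTH_RADIUS_M) * deg
    dx = np.diff(x, prepend=x[:1])
    lat_prev = np.concatenate([[lat0], lat[:-1]])
    mid = np.radians((lat_prev + lat) / 2.0)
    dlon = dx / (EARTH_RADIUS_M * np.cos(mid)) * deg
    lon = lon0 + np.cumsum(dlon)
    return lat, lon


def _walk_displacements(
    n: int, speed: float, dt: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-straight track: occasional heading changes (~1/min)."""
    heading = np.full(n, rng.uniform(0.0, 2.0 * np.pi))
    turn = rng.random(n) < dt / 60.0
    turn[0] = False
    angles = np.where(turn, rng.uniform(-np.pi / 3.0, np.pi / 3.0, n), 0.0)
    heading = heading + np.cumsum(angles)
    step = speed * dt
    return step * np.cos(heading), step * np.sin(heading)


def _ar1_noise(n: int, dt: float, sd: float, tau: float, rng: np.random.Generator) -> np.ndarray:
    if sd <= 0 or n == 0:
        return np.zeros(n)
    rho = np.exp(-dt / tau)
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    out = np.empty(n)
    out[0] = sd * rng.standard_normal()
    shocks = innov_sd * rng.standard_normal(n)
    for i in range(1, n):
        out[i] = rho * out[i - 1] + shocks[i]
    return out


def make_walk_log(
    speed: float,
    duration_s: float = 900.0,
    dt: float = 1.0,
    *,
    noise_sd: float = 0.0,
    noise_tau_s: float = 600.0,
    seed: int = 0,
    lat0: float = 37.5,
    lon0: float = 127.0,
    heading_deg: float = 45.0,
    label: str = "WALKING",
    t0: float = BASE_EPOCH,
) -> pd.DataFrame:
    """One straight labeled walking bout at an exactly known speed.

    A controlled fixture for the gait pipeline: with ``noise_sd = 0`` every
    consecutive-fix great-circle speed equals ``speed`` to numerical
    precision; with noise, the AR(1) positional error of the cohort
    simulator is applied.
    """
    n = int(round(duration_s / dt))
    rng = np.random.default_rng(seed)
    h = np.radians(heading_deg)
    step = speed * dt
    x = step * np.cos(h) * np.arange(n)
    y = step * np.sin(h) * np.arange(n)
    x = x + _ar1_noise(n, dt, noise_sd, noise_tau_s, rng)
    y = y + _ar1_noise(n, dt, noise_sd, noise_tau_s, rng)
    lat, lon = _latlon_from_local(x, y, lat0, lon0)
    return pd.DataFrame(
        {"t": t0 + dt * np.arange(n), "lat": lat, "lon": lon, "activity": label}
    )


def simulate_gps_log(truth: ParticipantTruth, config: CohortConfig) -> pd.DataFrame:
    """Two weeks of labeled position fixes for one participant.

    Walking bouts move at ``true_gait_speed``; interleaved vehicle segments
    (~12 m/s) and still segments provide non-walking context.  Walking
    points carry the ``WALKING`` label except a ``mislabel_rate`` fraction;
    mislabeling never fabricates a ``WALKING`` label on other segments.
    Unavailable participants (gait mask off) yield an empty log.
    """
    cfg = config
    if not truth.observed.get("gait_speed", True):
        return pd.DataFrame(columns=_GPS_COLUMNS)
    rng = np.random.default_rng([cfg.seed, STREAM_GPS, truth.index])
    dt = float(cfg.sampling_interval)
    lat0 = 37.50 + rng.uniform(-0.05, 0.05)
    lon0 = 127.00 + rng.uniform(-0.05, 0.05)

    segments = []  # (t_start, kind, n_points, speed)
    prev_end = 0.0
    for day in range(cfg.days):
        cursor = max(day * 86400.0 + 8 * 3600.0 + rng.uniform(0, 3600.0), prev_end + 60.0)
        n_bouts = rng.poisson(cfg.bouts_per_day)
        if rng.random() < 0.3:
            segments.append((cursor, "vehicle", int(round(300.0 / dt)), 12.0))
            cursor += 300.0 + rng.uniform(300.0, 900.0)
        for _ in range(n_bouts):
            if rng.random() < 0.5:
                segments.append((cursor, "still", int(round(240.0 / dt)), 0.0))
                cursor += 240.0 + rng.uniform(30.0, 120.0)
            dur = rng.uniform(cfg.bout_min_s, cfg.bout_max_s)
            segments.append((cursor, "walk", int(round(dur / dt)), truth.true_gait_speed))
            cursor += dur + rng.uniform(1200.0, 3600.0)
        prev_end = cursor

    if not segments:
        return pd.DataFrame(columns=_GPS_COLUMNS)

    ts, xs, ys, labels = [], [], [], []
    pos = np.zeros(2)
    for t_start, kind, n, speed in segments:
        if n <= 0:
            continue
        if kind == "walk":
            dx, dy = _walk_displacements(n, speed, dt, rng)
        elif kind == "vehicle":
            h = rng.uniform(0, 2 * np.pi)
            dx = np.full(n, speed * dt * np.cos(h))
            dy = np.full(n, speed * dt * np.sin(h))
        else:
            dx = np.zeros(n)
            dy = np.zeros(n)
        dx[0] = 0.0
        dy[0] = 0.0
        x = pos[0] + np.cumsum(dx)
        y = pos[1] + np.cumsum(dy)
        pos = np.array([x[-1], y[-1]])
        ts.append(t_start + dt * np.arange(n))
        xs.append(x)
        ys.append(y)
        true_label = {"walk": "WALKING", "vehicle": "IN_VEHICLE", "still": "STILL"}[kind]
        lab = np.full(n, true_label, dtype=object)
        if cfg.mislabel_rate > 0:
            flip = rng.random(n) < cfg.mislabel_rate
            if true_label == "WALKING":
                lab[flip] = rng.choice(_MISLABEL_CHOICES, size=int(flip.sum()))
            else:
                others = np.array([l for l in ("ON_FOOT", "STILL", "OTHER", "IN_VEHICLE")
                                   if l != true_label])
                lab[flip] = rng.choice(others, size=int(flip.sum()))
        labels.append(lab)

    t = np.concatenate(ts)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    activity = np.concatenate(labels)

    x = x + _ar1_noise(len(x), dt, cfg.gps_noise_sd, cfg.gps_noise_tau_s, rng)
    y = y + _ar1_noise(len(y), dt, cfg.gps_noise_sd, cfg.gps_noise_tau_s, rng)
    if cfg.glitch_rate > 0:
        glitch = rng.random(len(x)) < cfg.glitch_rate
        ng = int(glitch.sum())
        x[glitch] += rng.normal(0.0, 50.0, ng)
        y[glitch] += rng.normal(0.0, 50.0, ng)

    lat, lon = _latlon_from_local(x, y, lat0, lon0)
    # BASE_EPOCH is the UTC epoch of a local (+9) midnight, so offsets in
    # local seconds add directly.
    return pd.DataFrame(
        {"t": BASE_EPOCH + t, "lat": lat, "lon": lon, "activity": activity}
    )


def simulate_pedometer(truth: ParticipantTruth, config: CohortConfig) -> pd.DataFrame:
    """Hourly pedometer records with a diurnal activity profile.

    Each day's total is lognormal around ``true_daily_steps`` (day-to-day CV
    ``steps_day_cv``) and is spread multinomially over a handful of active
    daytime hours; all 24 hourly records are emitted (overnight mostly 0).
    """
    cfg = config
    if not truth.observed.get("steps", True) or cfg.days == 0:
        return pd.DataFrame(columns=["t", "steps"])
    rng = np.random.default_rng([cfg.seed, STREAM_STEPS, truth.index])
    sigma = float(cfg.steps_day_cv)
    records_t, records_s = [], []
    p_hours = _HOUR_WEIGHTS / _HOUR_WEIGHTS.sum()
    for day in range(cfg.days):
        if truth.true_daily_steps <= 0:
            total = 0
        else:
            total = int(round(truth.true_daily_steps * np.exp(sigma * rng.standard_normal() - sigma**2 / 2)))
        counts = np.zeros(24, dtype=int)
        if total > 0:
            k = int(np.clip(1 + rng.poisson(max(cfg.active_hours_mean - 1.0, 0.0)), 1, 16))
            hours = rng.choice(24, size=k, replace=False, p=p_hours)
            counts[hours] = rng.multinomial(total, np.full(k, 1.0 / k))
        t_local = day * 86400.0 + np.arange(24) * 3600.0 + 1800.0
        records_t.append(BASE_EPOCH + t_local)
        records_s.append(counts)
    return pd.DataFrame(
        {"t": np.concatenate(records_t), "steps": np.concatenate(records_s)}
    )


def simulate_sts_accel(truth: ParticipantTruth, config: CohortConfig) -> pd.DataFrame | None:
    """30 s vertical-acceleration trace with ``true_sts_reps`` rise cycles.

    The signal is a sinusoid at ``reps / 30`` Hz (amplitude
    ``sts_amplitude`` m/s^2) over a gravity baseline plus Gaussian sensor
    noise.  Returns ``None`` for participants without the in-app task.
    """
    cfg = config
    if not truth.observed.get("sts_reps", True):
        return None
    rng = np.random.default_rng([cfg.seed, STREAM_ACCEL, truth.index])
    t = np.arange(0.0, 30.0, 1.0 / cfg.accel_rate_hz)
    reps = int(truth.true_sts_reps)
    az = np.full_like(t, 9.81)
    if reps > 0:
        az = az + cfg.sts_amplitude * np.sin(2.0 * np.pi * (reps / 30.0) * t)
    if cfg.sts_noise_sd > 0:
        az = az + rng.normal(0.0, cfg.sts_noise_sd, len(t))
    return pd.DataFrame({"t_s": t, "az_ms2": az})


def simulate_self_reports(truth: ParticipantTruth, config: CohortConfig) -> pd.DataFrame:
    """Daily RPE (1-15) and subjective-health (1-4) reports.

    Reports are the rounded true levels plus ordinal noise, clipped to their
    scales; each report type is emitted only if its availability mask is on.
    """
    cfg = config
    rpe_on = truth.observed.get("rpe", True)
    health_on = truth.observed.get("health", True)
    if cfg.days == 0 or not (rpe_on or health_on):
        return pd.DataFrame(columns=["date", "rpe", "health"])
    rng = np.random.default_rng([cfg.seed, STREAM_REPORTS, truth.index])
    base = pd.Timestamp("2023-09-01")
    dates = [(base + pd.Timedelta(days=d)).date().isoformat() for d in range(cfg.days)]
    rpe = np.clip(
        np.round(truth.true_rpe_level + rng.normal(0.0, cfg.rpe_noise_sd, cfg.days)), 1, 15
    )
    health = np.clip(
        np.round(truth.true_health_level + rng.normal(0.0, cfg.health_noise_sd, cfg.days)), 1, 4
    )
    return pd.DataFrame(
        {
            "date": dates,
            "rpe": rpe if rpe_on else np.nan,
            "health": health if health_on else np.nan,
        }
    )
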