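"""Usual gait speed from labeled ambient GPS logs.

A participant's log is a time-sorted table of position fixes with an activity
label (``WALKING``, ``ON_FOOT``, ``IN_VEHICLE``, ``STILL``, ``OTHER``).  The
refinement pipeline, in fixed order:

1. keep only points labeled exactly ``WALKING``;
2. group consecutive points whose time gaps are <= 300 s into clusters and
   drop clusters with fewer than 100 points;
3. compute instantaneous point-to-point speeds (haversine distance / gap);
4. band-filter speeds to the physiological walking range [0.3, 2.0] m/s;
5. drop clusters lasting < 600 s or with radius < 100 m (radius = maximum
   great-circle distance from the coordinate centroid);
6. drop clusters with more than half of their points inside an exclusion
   polygon (automated stand-in for manual map verification);
7. smooth each cluster's surviving speeds with a 50-point trailing moving
   average;
8. the pooled mean of all smoothed speeds is the usual gait speed.

All thresholds are inclusive at their boundary (a 300 s gap joins, a speed of
exactly 0.3 or 2.0 survives, a 100-point / 600 s / 100 m cluster is kept).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely import contains_xy
from shapely.geometry import shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "EARTH_RADIUS_M",
    "ACTIVITY_LABELS",
    "GaitParams",
    "GaitSpeedResult",
    "haversine_m",
    "extract_walking_points",
    "build_clusters",
    "compute_speeds",
    "apply_speed_band",
    "cluster_duration_s",
    "cluster_radius_m",
    "qc_clusters",
    "apply_environment_mask",
    "load_mask_geojson",
    "smooth_speeds",
    "usual_gait_speed",
    "estimate_gait_speed",
]

EARTH_RADIUS_M = 6_371_000.0
ACTIVITY_LABELS = frozenset({"WALKING", "ON_FOOT", "IN_VEHICLE", "STILL", "OTHER"})


class OrderingError(ValueError):
    """Raised when a GPS log is not sorted by time."""


@dataclass(frozen=True)
class GaitParams:
    """Thresholds of the refinement pipeline (defaults as described above)."""

    min_points: int = 100
    max_gap_s: float = 300.0
    band_lo: float = 0.3
    band_hi: float = 2.0
    min_duration_s: float = 600.0
    min_radius_m: float = 100.0
    window: int = 50

    def __post_init__(self) -> None:
        if self.min_points < 2:
            raise ValueError("min_points must be >= 2")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if not 0 <= self.band_lo <= self.band_hi:
            raise ValueError("speed band must satisfy 0 <= lo <= hi")


@dataclass
class GaitSpeedResult:
    """Outcome of the pipeline for one participant.

    ``usual_gait_speed`` is ``None`` when no cluster survives QC — absence is
    a value, not an error.
    """

    usual_gait_speed: float | None
    n_valid_clusters: int
    n_speed_samples: int
    qc_log: list[dict] = field(default_factory=list)


def haversine_m(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in metres (vectorized, Earth radius 6371 km)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(a, dtype=float)) for a in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return EARTH_RADIUS_M * 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def extract_walking_points(log: pd.DataFrame) -> pd.DataFrame:
    """Subsequence of points labeled exactly ``WALKING`` (order preserved)."""
    if len(log) == 0:
        return log.copy()
    return log[log["activity"] == "WALKING"].copy()


def build_clusters(
    points: pd.DataFrame,
    *,
    max_gap_s: float = 300.0,
    min_points: int = 100,
) -> list[pd.DataFrame]:
    """Maximal runs with consecutive gaps <= ``max_gap_s``, >= ``min_points``.

    Input must be time-sorted; duplicate timestamps are dropped (first kept).
    """
    if len(points) == 0:
        return []
    t = points["t"].to_numpy(dtype=float)
    if np.any(np.diff(t) < 0):
        raise OrderingError("GPS log must be sorted by timestamp")
    points = points[np.concatenate(([True], np.diff(t) > 0))]
    t = points["t"].to_numpy(dtype=float)
    breaks = np.flatnonzero(np.diff(t) > max_gap_s) + 1
    clusters = []
    for chunk in np.split(np.arange(len(points)), breaks):
        if len(chunk) >= min_points:
            clusters.append(points.iloc[chunk].reset_index(drop=True))
    return clusters


def compute_speeds(cluster: pd.DataFrame) -> tuple[np.ndarray, int]:
    """Instantaneous speeds between consecutive fixes.

    Returns ``(speeds, n_degenerate)``: up to n-1 speeds in m/s; pairs with a
    zero time gap are dropped (counted in ``n_degenerate``) rather than
    failing the cluster.
    """
    if len(cluster) < 2:
        raise ValueError("cluster must contain at least 2 points")
    t = cluster["t"].to_numpy(dtype=float)
    lat = cluster["lat"].to_numpy(dtype=float)
    lon = cluster["lon"].to_numpy(dtype=float)
    dt = np.diff(t)
    dist = haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:])
    ok = dt > 0
    return dist[ok] / dt[ok], int((~ok).sum())


def apply_speed_band(speeds: Sequence[float], lo: float = 0.3, hi: float = 2.0) -> np.ndarray:
    """Keep speeds in [lo, hi] m/s, boundaries inclusive; idempotent."""
    s = np.asarray(speeds, dtype=float)
    return s[(s >= lo) & (s <= hi)]


def cluster_duration_s(cluster: pd.DataFrame) -> float:
    t = cluster["t"].to_numpy(dtype=float)
    return float(t[-1] - t[0])


def cluster_radius_m(cluster: pd.DataFrame) -> float:
    """Maximum great-circle distance from the unweighted coordinate centroid."""
    lat = cluster["lat"].to_numpy(dtype=float)
    lon = cluster["lon"].to_numpy(dtype=float)
    return float(np.max(haversine_m(lat.mean(), lon.mean(), lat, lon)))


def qc_clusters(
    clusters: Iterable[pd.DataFrame],
    *,
    min_duration_s: float = 600.0,
    min_radius_m: float = 100.0,
) -> tuple[list[pd.DataFrame], list[dict]]:
    """Keep clusters with duration >= 600 s and radius >= 100 m.

    Each exclusion is logged as ``{"cluster": i, "reason": ...,
    "duration_s": ..., "radius_m": ...}``.
    """
    valid: list[pd.DataFrame] = []
    log: list[dict] = []
    for i, cl in enumerate(clusters):
        dur = cluster_duration_s(cl)
        rad = cluster_radius_m(cl)
        reasons = []
        if dur < min_duration_s:
            reasons.append("duration")
        if rad < min_radius_m:
            reasons.append("radius")
        if reasons:
            log.append({"cluster": i, "reason": "+".join(reasons), "duration_s": dur, "radius_m": rad})
        else:
            valid.append(cl)
    return valid, log


def load_mask_geojson(path_or_obj) -> list[BaseGeometry]:
    """Read exclusion polygons from a GeoJSON file path or parsed object."""
    if isinstance(path_or_obj, (str, bytes)) or hasattr(path_or_obj, "read"):
        if hasattr(path_or_obj, "read"):
            obj = json.load(path_or_obj)
        else:
            with open(path_or_obj) as fh:
                obj = json.load(fh)
    else:
        obj = path_or_obj
    geoms: list[BaseGeometry] = []
    if obj.get("type") == "FeatureCollection":
        for feat in obj["features"]:
            geoms.append(shape(feat["geometry"]))
    elif obj.get("type") == "Feature":
        geoms.append(shape(obj["geometry"]))
    else:
        geoms.append(shape(obj))
    for g in geoms:
        if not g.is_valid:
            raise ValueError(f"invalid mask geometry: {g.geom_type}")
    return geoms


def apply_environment_mask(
    clusters: Iterable[pd.DataFrame],
    mask: Sequence[BaseGeometry] | None,
) -> tuple[list[pd.DataFrame], list[dict]]:
    """Drop clusters with more than half of their points inside any polygon.

    Polygons are WGS84 (lon/lat) shapely geometries.  An empty mask is the
    identity.  A cluster with exactly 50% of points inside is retained.
    """
    clusters = list(clusters)
    if not mask:
        return clusters, []
    for g in mask:
        if not g.is_valid:
            raise ValueError("invalid mask geometry")
    kept: list[pd.DataFrame] = []
    log: list[dict] = []
    for i, cl in enumerate(clusters):
        lon = cl["lon"].to_numpy(dtype=float)
        lat = cl["lat"].to_numpy(dtype=float)
        inside = np.zeros(len(cl), dtype=bool)
        for g in mask:
            inside |= contains_xy(g, lon, lat)
        frac = inside.mean()
        if frac > 0.5:
            log.append({"cluster": i, "reason": "environment", "fraction_inside": float(frac)})
        else:
            kept.append(cl)
    return kept, log


def smooth_speeds(speeds: Sequence[float], window: int = 50) -> np.ndarray:
    """Trailing moving average, length preserving.

    Element ``i`` is the mean of the last ``min(i + 1, window)`` values, so
    the start of the series uses partial windows.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    s = pd.Series(np.asarray(speeds, dtype=float))
    return s.rolling(window, min_periods=1).mean().to_numpy()


def usual_gait_speed(smoothed_per_cluster: Sequence[np.ndarray]) -> float | None:
    """Pooled mean over all smoothed speed samples (equal sample weights)."""
    arrays = [np.asarray(a, dtype=float) for a in smoothed_per_cluster if len(a) > 0]
    if not arrays:
        return None
    pooled = np.concatenate(arrays)
    return float(pooled.mean())


def estimate_gait_speed(
    log: pd.DataFrame,
    mask: Sequence[BaseGeometry] | None = None,
    params: GaitParams = GaitParams(),
) -> GaitSpeedResult:
    """Run the full refinement pipeline on one participant's labeled log."""
    qc_log: list[dict] = []
    walking = extract_walking_points(log)
    if len(walking) == 0:
        return GaitSpeedResult(None, 0, 0, [{"reason": "no_walking_points"}])
    clusters = build_clusters(walking, max_gap_s=params.max_gap_s, min_points=params.min_points)

    band_speeds: list[np.ndarray] = []
    kept_clusters: list[pd.DataFrame] = []
    n_degenerate = 0
    for cl in clusters:
        speeds, n_deg = compute_speeds(cl)
        n_degenerate += n_deg
        band_speeds.append(apply_speed_band(speeds, params.band_lo, params.band_hi))
        kept_clusters.append(cl)
    if n_degenerate:
        qc_log.append({"reason": "degenerate_pairs_dropped", "count": n_degenerate})

    valid, dropped = qc_clusters(
        kept_clusters, min_duration_s=params.min_duration_s, min_radius_m=params.min_radius_m
    )
    qc_log.extend(dropped)
    valid_ids = {id(cl) for cl in valid}
    speeds_by_cluster = [s for cl, s in zip(kept_clusters, band_speeds) if id(cl) in valid_ids]

    masked, mask_log = apply_environment_mask(valid, mask)
    qc_log.extend(mask_log)
    masked_ids = {id(cl) for cl in masked}
    speeds_by_cluster = [s for cl, s in zip(valid, speeds_by_cluster) if id(cl) in masked_ids]

    smoothed = [smooth_speeds(s, params.window) for s in speeds_by_cluster if len(s) > 0]
    n_samples = int(sum(len(s) for s in smoothed))
    n_valid = sum(1 for s in speeds_by_cluster if len(s) > 0)
    speed = usual_gait_speed(smoothed)
    return GaitSpeedResult(speed, n_valid, n_samples, qc_log)
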