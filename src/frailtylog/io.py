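"""CSV dialects shared by the simulator and the analysis stages.

All tabular interchange is plain CSV with documented headers:

* GPS:        ``participant_id, timestamp_iso8601_utc, lat, lon, activity``
* steps:      ``participant_id, timestamp_iso8601_utc, steps``
* reports:    ``participant_id, date, rpe, health``
* accelerometer: ``participant_id, t_s, az_ms2``
* CGA measures / clinical covariates / feature tables: one row per
  participant with named measure columns.

Exclusion masks are GeoJSON polygons (WGS84), read via
:func:`frailtylog.gait.load_mask_geojson`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "epoch_to_iso",
    "iso_to_epoch",
    "write_gps_csv",
    "read_gps_csv",
    "write_steps_csv",
    "read_steps_csv",
    "write_table_csv",
    "read_table_csv",
]


def epoch_to_iso(t) -> pd.Series:
    ts = pd.to_datetime(np.asarray(t, dtype=float) * 1e9, utc=True)
    return pd.Series(ts).dt.strftime("%Y-%m-%dT%H:%M:%S.%f").str.slice(0, 23) + "Z"


def iso_to_epoch(s) -> np.ndarray:
    ts = pd.to_datetime(pd.Series(s), utc=True, format="ISO8601")
    return ts.astype("int64").to_numpy() / 1e9


def write_gps_csv(df: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "participant_id": df["participant_id"],
            "timestamp_iso8601_utc": epoch_to_iso(df["t"]).to_numpy(),
            "lat": df["lat"],
            "lon": df["lon"],
            "activity": df["activity"],
        }
    )
    out.to_csv(path, index=False, float_format="%.8f")


def read_gps_csv(path: str | Path) -> pd.DataFrame:
    raw = pd.read_csv(path)
    return pd.DataFrame(
        {
            "participant_id": raw["participant_id"],
            "t": iso_to_epoch(raw["timestamp_iso8601_utc"]),
            "lat": raw["lat"].astype(float),
            "lon": raw["lon"].astype(float),
            "activity": raw["activity"],
        }
    )


def write_steps_csv(df: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "participant_id": df["participant_id"],
            "timestamp_iso8601_utc": epoch_to_iso(df["t"]).to_numpy(),
            "steps": df["steps"].astype(int),
        }
    )
    out.to_csv(path, index=False)


def read_steps_csv(path: str | Path) -> pd.DataFrame:
    raw = pd.read_csv(path)
    return pd.DataFrame(
        {
            "participant_id": raw["participant_id"],
            "t": iso_to_epoch(raw["timestamp_iso8601_utc"]),
            "steps": raw["steps"].astype(int),
        }
    )


def write_table_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_table_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
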