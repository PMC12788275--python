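"""Direct per-participant analysis-table generation.

``generate_observed_table`` produces the merged one-row-per-participant
table (FI, covariates, observed lifelog features) without rendering the raw
GPS/pedometer/accelerometer streams: each observed feature is the truth plus
the aggregation-level measurement error implied by two weeks of monitoring.
This is the cheap path for statistical studies over many replicate cohorts;
the raw-stream pipeline (see :mod:`frailtylog.pipeline`) produces the same
schema and is validated against it end to end.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .. import frailty as _frailty
from .cohort import CohortConfig, generate_cohort, truths_frame
from .deficits import simulate_cga_measures

__all__ = ["generate_observed_table", "COVARIATES", "LIFELOGS", "attach_observed_features"]

#: step-1 (clinical) predictors, in the published model order
COVARIATES = ("age", "sex_female", "height_cm", "weight_kg", "smm_kg", "fat_pct", "sppb")
#: step-2 (lifelog) predictors entering the hierarchical model
LIFELOGS = ("usual_gait_speed", "sts_counts", "daily_mean_steps", "rpe", "subjective_health")

#: approximate gait-speed estimation error of the GPS pipeline (m/s)
GAIT_MEASUREMENT_SD = 0.03


def attach_observed_features(
    table: pd.DataFrame, config: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Add observed lifelog columns = truth + two-week aggregation error."""
    cfg = config
    n = len(table)
    days = max(cfg.days, 1)

    gait = table["true_gait_speed"] + rng.normal(0.0, GAIT_MEASUREMENT_SD, n)
    sts = table["true_sts_reps"].astype(float)
    sd_daily = cfg.steps_day_cv / np.sqrt(days)
    daily = table["true_daily_steps"] * np.exp(
        sd_daily * rng.standard_normal(n) - sd_daily**2 / 2
    )
    active_hours = np.clip(rng.normal(cfg.active_hours_mean, 0.6, n), 1.0, 16.0)
    hourly = daily / active_hours
    rpe = np.clip(
        table["true_rpe_level"] + rng.normal(0.0, cfg.rpe_noise_sd / np.sqrt(days), n), 1, 15
    )
    health = np.clip(
        table["true_health_level"] + rng.normal(0.0, cfg.health_noise_sd / np.sqrt(days), n),
        1,
        4,
    )

    out = table.copy()
    out["usual_gait_speed"] = np.where(out["observed_gait_speed"], gait, np.nan)
    out["sts_counts"] = np.where(out["observed_sts_reps"], sts, np.nan)
    out["daily_mean_steps"] = np.where(out["observed_steps"], daily, np.nan)
    out["hourly_mean_steps"] = np.where(out["observed_steps"], hourly, np.nan)
    out["rpe"] = np.where(out["observed_rpe"], rpe, np.nan)
    out["subjective_health"] = np.where(out["observed_health"], health, np.nan)
    return out


def generate_observed_table(config: CohortConfig) -> pd.DataFrame:
    """Cohort analysis table: truth, covariates, FI and observed features."""
    truths = generate_cohort(config)
    table = truths_frame(truths)
    if len(table) == 0:
        return table
    cga = simulate_cga_measures(truths, config)
    fi = _frailty.score_cohort(cga)
    table = table.merge(fi[["participant_id", "fi"]], on="participant_id")
    table = table.merge(
        cga[["participant_id", "weight_kg", "smm_kg", "bmi"]], on="participant_id"
    )
    table["sex_female"] = (table["sex"] == "F").astype(float)
    rng = np.random.default_rng([config.seed, 7])
    return attach_observed_features(table, config, rng)
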