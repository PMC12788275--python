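"""End-to-end orchestration: simulate -> features -> FI -> analysis.

The interchange contract between stages is a single merged per-participant
table carrying the FI outcome, the clinical covariates and the six lifelog
features; every statistical model then defines its own complete-case sample
by listwise deletion (see :mod:`frailtylog.stats`).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as _feat
from . import frailty as _frailty
from . import gait as _gait
from . import io as _io
from . import stats as _stats
from .synthetic import (
    CohortConfig,
    generate_cohort,
    simulate_cga_measures,
    simulate_gps_log,
    simulate_pedometer,
    simulate_self_reports,
    simulate_sts_accel,
    truths_frame,
)
from .synthetic.observed import COVARIATES, LIFELOGS

__all__ = [
    "RawData",
    "AnalysisResults",
    "simulate_raw",
    "extract_features",
    "build_participant_table",
    "analyze",
    "run_pipeline",
    "COVARIATES",
    "LIFELOGS",
    "CORRELATION_FEATURES",
]

#: features correlated with FI, in the published table order (hourly steps is
#: reported in correlations but excluded from the regression models)
CORRELATION_FEATURES = (
    "usual_gait_speed",
    "sts_counts",
    "daily_mean_steps",
    "hourly_mean_steps",
    "rpe",
    "subjective_health",
)


@dataclass
class RawData:
    """All raw streams of a simulated cohort."""

    truths: pd.DataFrame
    gps: pd.DataFrame
    steps: pd.DataFrame
    accel: pd.DataFrame
    reports: pd.DataFrame
    cga: pd.DataFrame
    clinical: pd.DataFrame


@dataclass
class AnalysisResults:
    correlations: pd.DataFrame
    hierarchical: _stats.HierarchicalRegressionResult
    lifelog_only: _stats.ModelFit
    kfold: tuple[float, float, np.ndarray]
    huber: _stats.ModelFit
    sensitivity: dict = field(default_factory=dict)
    samples: dict = field(default_factory=dict)


def simulate_raw(config: CohortConfig, out_dir: str | Path | None = None) -> RawData:
    """Generate every raw stream; optionally write the CSV bundle."""
    truths = generate_cohort(config)

    def _cat(frames: list[pd.DataFrame], cols: list[str]) -> pd.DataFrame:
        frames = [f for f in frames if f is not None and len(f)]
        if not frames:
            return pd.DataFrame(columns=cols)
        return pd.concat(frames, ignore_index=True)

    gps, steps, accel, reports = [], [], [], []
    for t in truths:
        g = simulate_gps_log(t, config)
        g.insert(0, "participant_id", t.id)
        gps.append(g)
        s = simulate_pedometer(t, config)
        s.insert(0, "participant_id", t.id)
        steps.append(s)
        a = simulate_sts_accel(t, config)
        if a is not None:
            a.insert(0, "participant_id", t.id)
        accel.append(a)
        r = simulate_self_reports(t, config)
        r.insert(0, "participant_id", t.id)
        reports.append(r)

    cga = simulate_cga_measures(truths, config)
    tf = truths_frame(truths)
    clinical_cols = ["participant_id", "sex", "age", "height_cm", "fat_pct", "sppb"]
    clinical = tf[clinical_cols].copy() if len(tf) else pd.DataFrame(columns=clinical_cols)
    raw = RawData(
        truths=tf,
        gps=_cat(gps, ["participant_id", "t", "lat", "lon", "activity"]),
        steps=_cat(steps, ["participant_id", "t", "steps"]),
        accel=_cat(accel, ["participant_id", "t_s", "az_ms2"]),
        reports=_cat(reports, ["participant_id", "date", "rpe", "health"]),
        cga=cga,
        clinical=clinical,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _io.write_gps_csv(raw.gps, out / "gps.csv")
        _io.write_steps_csv(raw.steps, out / "steps.csv")
        raw.accel.to_csv(out / "accel.csv", index=False)
        raw.reports.to_csv(out / "reports.csv", index=False)
        raw.cga.to_csv(out / "cga.csv", index=False)
        raw.clinical.to_csv(out / "clinical.csv", index=False)
        raw.truths.to_csv(out / "truths.csv", index=False)
    return raw


def extract_features(
    raw: RawData,
    *,
    gait_params: _gait.GaitParams = _gait.GaitParams(),
    sts_params: _feat.StsParams = _feat.StsParams(),
    mask=None,
    tz_offset_hours: float = _feat.DEFAULT_TZ_OFFSET_HOURS,
) -> pd.DataFrame:
    """Derive the six lifelog features for every participant."""
    ids = list(raw.clinical["participant_id"]) if len(raw.clinical) else sorted(
        set(raw.gps.get("participant_id", []))
    )
    gps_by = dict(tuple(raw.gps.groupby("participant_id"))) if len(raw.gps) else {}
    steps_by = dict(tuple(raw.steps.groupby("participant_id"))) if len(raw.steps) else {}
    accel_by = dict(tuple(raw.accel.groupby("participant_id"))) if len(raw.accel) else {}
    reports_by = dict(tuple(raw.reports.groupby("participant_id"))) if len(raw.reports) else {}

    rows = []
    for pid in ids:
        fs = _feat.LifelogFeatureSet(participant_id=pid)
        g = gps_by.get(pid)
        if g is not None and len(g):
            res = _gait.estimate_gait_speed(g.sort_values("t"), mask=mask, params=gait_params)
            fs.usual_gait_speed = res.usual_gait_speed
        s = steps_by.get(pid)
        if s is not None and len(s):
            fs.daily_mean_steps = _feat.daily_mean_steps(s, tz_offset_hours)
            fs.hourly_mean_steps = _feat.hourly_mean_steps(s, tz_offset_hours)
        a = accel_by.get(pid)
        if a is not None and len(a):
            fs.sts_counts = float(
                _feat.count_sts_reps(a["t_s"].to_numpy(), a["az_ms2"].to_numpy(), params=sts_params)
            )
        r = reports_by.get(pid)
        if r is not None and len(r):
            fs.rpe = _feat.aggregate_rpe(r["rpe"].to_numpy())
            fs.subjective_health = _feat.aggregate_subjective_health(r["health"].to_numpy())
        rows.append(
            {
                "participant_id": pid,
                "usual_gait_speed": fs.usual_gait_speed,
                "sts_counts": fs.sts_counts,
                "daily_mean_steps": fs.daily_mean_steps,
                "hourly_mean_steps": fs.hourly_mean_steps,
                "rpe": fs.rpe,
                "subjective_health": fs.subjective_health,
            }
        )
    return pd.DataFrame(rows)


def build_participant_table(
    features: pd.DataFrame,
    cga: pd.DataFrame,
    clinical: pd.DataFrame,
    registry: _frailty.DeficitRegistry | None = None,
) -> pd.DataFrame:
    """Merge FI, covariates and lifelog features into the analysis table."""
    fi = _frailty.score_cohort(cga, registry)
    table = clinical.merge(fi, on="participant_id", how="left")
    table = table.merge(
        cga[["participant_id", "weight_kg", "smm_kg", "bmi"]], on="participant_id", how="left"
    )
    table["sex_female"] = (table["sex"] == "F").astype(float)
    return table.merge(features, on="participant_id", how="left")


def analyze(
    table: pd.DataFrame,
    *,
    outcome: str = "fi",
    covariates=COVARIATES,
    lifelogs=LIFELOGS,
    kfold_k: int = 5,
    seed: int = 0,
) -> AnalysisResults:
    """Run the full statistical suite on the merged participant table."""
    covariates = list(covariates)
    lifelogs = list(lifelogs)

    corr_rows = []
    for feat in CORRELATION_FEATURES:
        if feat not in table.columns:
            continue
        sub = table[[outcome, feat]].dropna()
        res = _stats.pearson_with_ci(sub[feat], sub[outcome])
        corr_rows.append(
            {
                "feature": feat,
                "n": res.n,
                "r": res.r,
                "p": res.p,
                "ci_lo": res.ci[0],
                "ci_hi": res.ci[1],
            }
        )
    correlations = pd.DataFrame(corr_rows)

    hier_rows, n_all, n_hier = _stats.assemble_complete_cases(
        table, [outcome, *covariates, *lifelogs]
    )
    hier = _stats.hierarchical_fit(
        hier_rows[outcome], hier_rows[covariates], hier_rows[lifelogs]
    )
    huber = _stats.huber_fit(hier_rows[outcome], hier_rows[covariates + lifelogs])

    lif_rows, _, n_lif = _stats.assemble_complete_cases(table, [outcome, *lifelogs])
    lifelog_only = _stats.fit_linear_model(lif_rows[outcome], lif_rows[lifelogs])
    kf = _stats.kfold_r2(lif_rows[outcome], lif_rows[lifelogs], k=kfold_k, seed=seed)

    sensitivity = _stats.run_sensitivity_suite(
        table,
        outcome=outcome,
        covariates=covariates,
        lifelogs=lifelogs,
        drop_one=tuple(v for v in ("daily_mean_steps", "usual_gait_speed") if v in lifelogs),
    )
    return AnalysisResults(
        correlations=correlations,
        hierarchical=hier,
        lifelog_only=lifelog_only,
        kfold=kf,
        huber=huber,
        sensitivity=sensitivity,
        samples={"n_rows": n_all, "n_hierarchical": n_hier, "n_lifelog_only": n_lif},
    )


def _config_hash(config: CohortConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(
    config: CohortConfig,
    out_dir: str | Path,
    *,
    gait_params: _gait.GaitParams = _gait.GaitParams(),
    mask=None,
    write_raw: bool = False,
) -> AnalysisResults:
    """simulate -> extract -> score -> analyze, writing result tables + log.

    Deterministic for a given (config, seed): running twice produces
    byte-identical tables.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    raw = simulate_raw(config, out_dir=out / "raw" if write_raw else None)
    features = extract_features(raw, gait_params=gait_params, mask=mask)
    table = build_participant_table(features, raw.cga, raw.clinical)
    _io.write_table_csv(features, out / "features.csv")
    _io.write_table_csv(
        table[["participant_id", "fi", "n_present", "n_missing"]], out / "fi.csv"
    )
    _io.write_table_csv(table, out / "participant_table.csv")
    results = analyze(table, seed=config.seed)
    _io.write_table_csv(results.correlations, out / "correlations.csv")

    from . import report as _report

    (out / "report.txt").write_text(_report.render_tables(results))
    import sklearn
    import scipy
    import statsmodels

    log = {
        "config_hash": _config_hash(config),
        "config": asdict(config),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "statsmodels": statsmodels.__version__,
            "sklearn": sklearn.__version__,
        },
        "rows": {
            "participants": int(len(raw.clinical)),
            "gps_points": int(len(raw.gps)),
            "step_records": int(len(raw.steps)),
            "reports": int(len(raw.reports)),
            **results.samples,
        },
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return results
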