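"""Cohort generator: determinism, planted effects, stream contracts."""

import numpy as np
import pandas as pd
import pytest

from frailtylog.features import count_sts_reps
from frailtylog.frailty import compute_fi
from frailtylog.gait import build_clusters, compute_speeds, extract_walking_points
from frailtylog.synthetic import (
    CohortConfig,
    ConfigError,
    DEFAULT_EFFECT_MAP,
    deficit_propensity,
    generate_cohort,
    simulate_cga_measures,
    simulate_deficits,
    simulate_gps_log,
    simulate_pedometer,
    simulate_self_reports,
    simulate_sts_accel,
    truths_frame,
)
from frailtylog.synthetic.deficits import calibrated_item_loading
from frailtylog.frailty import default_registry, score_cohort


def test_config_validation():
    with pytest.raises(ConfigError):
        CohortConfig(n_participants=-1)
    with pytest.raises(ConfigError):
        CohortConfig(effect_map={**DEFAULT_EFFECT_MAP, "gait_speed": -1.2})
    with pytest.raises(ConfigError):
        CohortConfig(missingness_map={"gait_speed": 1.4})
    with pytest.raises(ConfigError):
        CohortConfig(mislabel_rate=2.0)
    with pytest.raises(ConfigError):
        CohortConfig(sampling_interval=0.0)


def test_empty_cohort_and_default_effect_map():
    assert generate_cohort(CohortConfig(n_participants=0)) == []
    # default planted gait-speed correlation is the published value
    assert CohortConfig().effect_map["gait_speed"] == pytest.approx(-0.370)


def test_determinism_and_seed_sensitivity(small_config, small_cohort):
    again = generate_cohort(small_config)
    pd.testing.assert_frame_equal(truths_frame(again), truths_frame(small_cohort))
    other = generate_cohort(CohortConfig(n_participants=8, seed=43, days=3))
    assert not truths_frame(other).equals(truths_frame(small_cohort))
    t = small_cohort[0]
    pd.testing.assert_frame_equal(
        simulate_gps_log(t, small_config), simulate_gps_log(t, small_config)
    )


def test_planted_correlations_converge_at_large_n():
    custom = dict(DEFAULT_EFFECT_MAP)
    custom["daily_steps"] = -0.5
    cfg = CohortConfig(n_participants=5000, seed=1, effect_map=custom)
    tf = truths_frame(generate_cohort(cfg))
    r = np.corrcoef(tf["latent_frailty"], tf["true_daily_steps"])[0, 1]
    assert r == pytest.approx(-0.5, abs=0.05)
    for col, key in [
        ("true_gait_speed", "gait_speed"),
        ("true_sts_reps", "sts_reps"),
        ("true_rpe_level", "rpe"),
        ("true_health_level", "health"),
    ]:
        got = np.corrcoef(tf["latent_frailty"], tf[col])[0, 1]
        assert got == pytest.approx(DEFAULT_EFFECT_MAP[key], abs=0.05)


def test_availability_matches_missingness_map():
    cfg = CohortConfig(n_participants=2000, seed=6, days=2)
    tf = truths_frame(generate_cohort(cfg))
    for key, p in cfg.missingness_map.items():
        frac = tf[f"observed_{key}"].mean()
        assert frac == pytest.approx(p, abs=3 * np.sqrt(p * (1 - p) / 2000))


def test_truth_supports():
    cfg = CohortConfig(n_participants=400, seed=2, days=2)
    tf = truths_frame(generate_cohort(cfg))
    assert tf["true_gait_speed"].between(0.3, 2.0, inclusive="neither").all()
    assert (tf["true_daily_steps"] >= 0).all()
    assert (tf["true_sts_reps"] >= 0).all()
    assert tf["true_rpe_level"].between(1, 15).all()
    assert tf["true_health_level"].between(1, 4).all()


def test_gps_log_contract(small_config, small_cohort):
    t = small_cohort[0]
    t.observed["gait_speed"] = True
    log = simulate_gps_log(t, small_config)
    assert (np.diff(log["t"]) > 0).all()
    assert log["lat"].between(-90, 90).all() and log["lon"].between(-180, 180).all()
    assert set(log["activity"]) <= {"WALKING", "ON_FOOT", "IN_VEHICLE", "STILL", "OTHER"}


def test_gps_noiseless_bout_speed_exact():
    cfg = CohortConfig(
        n_participants=1, seed=3, gps_noise_sd=0.0, mislabel_rate=0.0,
        glitch_rate=0.0, days=2, bouts_per_day=2.0,
    )
    t = generate_cohort(cfg)[0]
    t.observed["gait_speed"] = True
    log = simulate_gps_log(t, cfg)
    walking = extract_walking_points(log)
    assert len(walking) > 0
    for cl in build_clusters(walking, min_points=2):
        speeds, _ = compute_speeds(cl)
        # within-bout steps move at exactly the true speed; bout-to-bout
        # transitions are separated by > 300 s so never share a cluster
        assert np.abs(speeds - t.true_gait_speed).max() < 1e-6


def test_gps_mislabeling_and_degenerate_configs(small_cohort):
    cfg = CohortConfig(n_participants=8, seed=42, days=3, mislabel_rate=1.0)
    t = small_cohort[0]
    t.observed["gait_speed"] = True
    assert (simulate_gps_log(t, cfg)["activity"] == "WALKING").sum() == 0
    cfg0 = CohortConfig(n_participants=8, seed=42, days=3, bouts_per_day=0.0)
    log0 = simulate_gps_log(t, cfg0)
    assert len(log0) == 0 or (log0["activity"] != "WALKING").all()


def test_pedometer_contract(small_cohort):
    t = small_cohort[0]
    t.observed["steps"] = True
    assert len(simulate_pedometer(t, CohortConfig(n_participants=8, seed=42, days=0))) == 0
    cfg = CohortConfig(n_participants=8, seed=42, days=200)
    t.true_daily_steps = 0.0
    assert (simulate_pedometer(t, cfg)["steps"] == 0).all()
    t.true_daily_steps = 3000.0
    recs = simulate_pedometer(t, cfg)
    assert (recs["steps"] >= 0).all()
    per_day = recs.groupby(np.floor((recs["t"] + 9 * 3600) / 86400))["steps"].sum()
    assert per_day.mean() == pytest.approx(3000, rel=0.05)
    # overnight hours (local 0-5 h) carry almost no steps
    hours = np.floor(((recs["t"] + 9 * 3600) % 86400) / 3600)
    night = recs["steps"][(hours < 6)].sum()
    assert night <= 0.1 * recs["steps"].sum()


def test_sts_trace_contract(small_config, small_cohort):
    t = small_cohort[1]
    t.observed["sts_reps"] = True
    trace = simulate_sts_accel(t, small_config)
    dt = 1.0 / small_config.accel_rate_hz
    assert abs((trace["t_s"].iloc[-1] + dt) - 30.0) <= dt  # 30 s +/- one sample
    t.true_sts_reps = 17
    trace = simulate_sts_accel(t, small_config)
    assert count_sts_reps(trace["t_s"].to_numpy(), trace["az_ms2"].to_numpy()) == 17
    t.true_sts_reps = 0
    flat = simulate_sts_accel(t, small_config)
    assert count_sts_reps(flat["t_s"].to_numpy(), flat["az_ms2"].to_numpy()) == 0


def test_self_reports_support_and_zero_noise(small_cohort):
    cfg = CohortConfig(n_participants=8, seed=42, days=10)
    t = small_cohort[2]
    t.observed["rpe"] = True
    t.observed["health"] = True
    rep = simulate_self_reports(t, cfg)
    assert rep["rpe"].between(1, 15).all() and rep["health"].between(1, 4).all()
    quiet = CohortConfig(n_participants=8, seed=42, days=4, rpe_noise_sd=0.0, health_noise_sd=0.0)
    rep0 = simulate_self_reports(t, quiet)
    assert (rep0["rpe"] == np.clip(round(t.true_rpe_level), 1, 15)).all()
    assert (rep0["health"] == np.clip(round(t.true_health_level), 1, 4)).all()


def test_deficit_propensity_monotone_in_latent_frailty():
    lam = calibrated_item_loading(DEFAULT_EFFECT_MAP["fi"])
    grid = np.linspace(-3, 3, 25)
    prop = deficit_propensity(grid, np.zeros_like(grid), np.zeros_like(grid), lam)
    assert (np.diff(prop, axis=0) >= -1e-12).all()
    assert ((prop >= 0) & (prop <= 1)).all()


def test_simulate_deficits_profile(small_config, small_cohort):
    prof = simulate_deficits(small_cohort[0], small_config)
    assert prof.registry_size == 50
    vals = prof.values.dropna()
    assert vals.between(0, 1).all()
    res = compute_fi(prof)
    assert 0 <= res.fi <= 1


def test_fi_correlation_matches_planted_value():
    cfg = CohortConfig(n_participants=2000, seed=8, days=2)
    truths = generate_cohort(cfg)
    cga = simulate_cga_measures(truths, cfg)
    fi = score_cohort(cga)["fi"]
    latent = np.array([t.latent_frailty for t in truths])
    r = np.corrcoef(latent, fi)[0, 1]
    assert r > 0
    assert r == pytest.approx(DEFAULT_EFFECT_MAP["fi"], abs=0.05)


def test_cga_scoring_consistency_with_registry(small_config, small_cohort):
    """Raw measures scored through the registry stay within item level sets."""
    cga = simulate_cga_measures(small_cohort, small_config)
    reg = default_registry(smm_cutoffs_kg={"F": 17.0, "M": 22.0})
    for _, row in cga.iterrows():
        prof = reg.score(row)
        for item in reg.items:
            v = prof.values[item.name]
            if not np.isnan(v):
                assert v in item.levels
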