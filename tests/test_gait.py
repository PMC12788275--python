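"""GPS refinement pipeline: filtering, clustering, QC, smoothing, pooling."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from frailtylog.gait import (
    EARTH_RADIUS_M,
    GaitParams,
    OrderingError,
    apply_environment_mask,
    apply_speed_band,
    build_clusters,
    cluster_radius_m,
    compute_speeds,
    estimate_gait_speed,
    extract_walking_points,
    haversine_m,
    qc_clusters,
    smooth_speeds,
    usual_gait_speed,
)
from frailtylog.synthetic.streams import make_walk_log

from conftest import walking_log


def test_haversine_small_arc_along_meridian():
    dlat = 1.2 / EARTH_RADIUS_M * 180.0 / np.pi
    assert haversine_m(37.0, 127.0, 37.0 + dlat, 127.0) == pytest.approx(1.2, abs=1e-6)
    assert haversine_m(37.0, 127.0, 37.0, 127.0) == 0.0


def test_extract_walking_points_is_label_subsequence():
    log = walking_log(9)
    log["activity"] = ["WALKING", "ON_FOOT", "WALKING", "STILL", "WALKING",
                       "IN_VEHICLE", "WALKING", "OTHER", "ON_FOOT", "WALKING"]
    out = extract_walking_points(log)
    assert list(out["t"]) == [0.0, 2.0, 4.0, 6.0, 9.0]
    # ON_FOOT is not Walking; all-walking logs pass through unchanged
    all_walk = walking_log(5)
    pd.testing.assert_frame_equal(extract_walking_points(all_walk), all_walk)
    assert len(extract_walking_points(log.iloc[:0])) == 0


def test_build_clusters_gap_and_size_rules():
    # 99 points at 1 Hz: below the 100-point minimum
    assert build_clusters(walking_log(98)) == []
    # 250 points with a 400 s gap after point 120 -> clusters of 120 and 130
    log = walking_log(249)
    t = log["t"].to_numpy().copy()
    t[120:] += 400.0
    log["t"] = t
    clusters = build_clusters(log)
    assert [len(c) for c in clusters] == [120, 130]
    # a gap of exactly 300 s joins (inclusive boundary)
    log2 = walking_log(199)
    t2 = log2["t"].to_numpy().copy()
    t2[100:] += 299.0  # gap becomes exactly 300 s
    log2["t"] = t2
    assert [len(c) for c in build_clusters(log2)] == [200]


def test_build_clusters_rejects_unsorted_logs():
    log = walking_log(120)
    with pytest.raises(OrderingError):
        build_clusters(log.iloc[::-1].reset_index(drop=True))


def test_compute_speeds_count_and_degenerate_pairs():
    log = walking_log([1.0, 1.5, 2.0])
    speeds, n_deg = compute_speeds(log)
    assert len(speeds) == len(log) - 1 and n_deg == 0
    assert speeds == pytest.approx([1.0, 1.5, 2.0], abs=1e-6)
    # duplicate timestamp: pair dropped and counted, not fatal
    log2 = log.copy()
    log2.loc[2, "t"] = log2.loc[1, "t"]
    speeds2, n_deg2 = compute_speeds(log2)
    assert n_deg2 == 1 and len(speeds2) == 2
    # identical coordinates one second apart move at 0 m/s
    still = walking_log([0.0])
    assert compute_speeds(still)[0] == pytest.approx([0.0])


def test_speed_band_inclusive_and_idempotent():
    assert list(apply_speed_band([0.2, 0.5, 2.5])) == [0.5]
    assert list(apply_speed_band([0.3, 2.0])) == [0.3, 2.0]
    assert list(apply_speed_band([])) == []
    once = apply_speed_band(np.linspace(0, 3, 40))
    assert np.array_equal(apply_speed_band(once), once)


def test_qc_cluster_thresholds_and_reasons():
    nine_min = walking_log(539)  # 540 s span < 600 s
    jitter = walking_log(700)
    # collapse the jitter cluster to a ~50 m radius blob
    jitter["lat"] = 37.0 + 25.0 / EARTH_RADIUS_M * 180 / np.pi * np.sin(
        np.arange(len(jitter))
    )
    fifteen_min = walking_log(899)  # straight 1.2 m/s, ~1079 m extent
    valid, log = qc_clusters([nine_min, jitter, fifteen_min])
    assert len(valid) == 1 and valid[0] is fifteen_min
    reasons = {entry["cluster"]: entry["reason"] for entry in log}
    assert "duration" in reasons[0]
    assert "radius" in reasons[1]
    assert cluster_radius_m(fifteen_min) > 500.0


def test_environment_mask_majority_rule():
    log = walking_log(199)
    assert apply_environment_mask([log], None)[0] == [log]
    everywhere = Polygon([(120, 30), (130, 30), (130, 40), (120, 40)])
    kept, dropped = apply_environment_mask([log], [everywhere])
    assert kept == [] and dropped[0]["reason"] == "environment"
    # polygon covering only 40% of points: cluster retained
    lat40 = np.sort(log["lat"])[int(0.4 * len(log))]
    partial = Polygon([(126, 36), (128, 36), (128, lat40), (126, lat40)])
    kept2, _ = apply_environment_mask([log], [partial])
    assert kept2 == [log]


def test_smoothing_matches_brute_force_trailing_mean(rng):
    x = rng.normal(1.2, 0.3, 137)
    out = smooth_speeds(x, window=50)
    brute = np.array([x[max(0, i - 49): i + 1].mean() for i in range(len(x))])
    assert np.max(np.abs(out - brute)) <= 1e-12
    assert len(out) == len(x)
    # constants are fixed points; short inputs use partial windows
    assert smooth_speeds(np.full(10, 0.9), 50) == pytest.approx(np.full(10, 0.9))
    ten = np.arange(10.0)
    assert smooth_speeds(ten, 50)[9] == pytest.approx(ten.mean())


def test_usual_gait_speed_pools_samples_equally():
    assert usual_gait_speed([]) is None
    assert usual_gait_speed([np.full(100, 1.2)]) == pytest.approx(1.2)
    pooled = usual_gait_speed([np.full(100, 1.0), np.full(300, 1.4)])
    assert pooled == pytest.approx(1.3)


@pytest.mark.parametrize("v", [0.4, 0.9, 1.2, 1.9])
def test_noiseless_recovery_across_speeds(v):
    res = estimate_gait_speed(make_walk_log(v, 900.0))
    assert res.usual_gait_speed == pytest.approx(v, abs=1e-3)
    assert res.n_valid_clusters == 1


def test_noise_robustness_under_default_gps_error():
    """5 m AR(1) positional error, 15-min bouts: error <= 0.15 m/s."""
    for v in (0.6, 1.12, 1.6):
        errs = [
            abs(estimate_gait_speed(make_walk_log(v, 900.0, noise_sd=5.0, seed=s)).usual_gait_speed - v)
            for s in range(20)
        ]
        assert max(errs) <= 0.15


def test_contamination_never_reaches_the_mean():
    clean = make_walk_log(1.2, 900.0)
    vehicle = make_walk_log(
        12.0, 300.0, label="IN_VEHICLE", t0=clean["t"].iloc[-1] + 30.0, lat0=37.6
    )
    spiked = clean.copy()
    spiked.loc[450, "lat"] += 0.001  # ~111 m single-point glitch
    combined = pd.concat([spiked, vehicle], ignore_index=True)
    res = estimate_gait_speed(combined)
    baseline = estimate_gait_speed(clean)
    # the glitch removes a couple of in-band samples; vehicle adds none
    assert res.usual_gait_speed == pytest.approx(baseline.usual_gait_speed, abs=5e-3)
    walk = extract_walking_points(combined)
    speeds, _ = compute_speeds(build_clusters(walk)[0])
    assert (apply_speed_band(speeds) <= 2.0).all()


def test_valid_clusters_satisfy_every_threshold():
    """QC-surviving clusters obey all four stated thresholds on any input."""
    params = GaitParams()
    for seed in range(5):
        r = np.random.default_rng(seed)
        pieces = []
        t0 = 0.0
        for _ in range(4):
            dur = float(r.uniform(120, 1200))
            piece = make_walk_log(
                float(r.uniform(0.2, 2.4)), dur, noise_sd=5.0, seed=seed, t0=t0
            )
            pieces.append(piece)
            t0 += dur + float(r.uniform(10, 900))
        log = pd.concat(pieces, ignore_index=True)
        walking = extract_walking_points(log)
        clusters = build_clusters(walking, max_gap_s=params.max_gap_s, min_points=params.min_points)
        valid, _ = qc_clusters(clusters)
        for cl in valid:
            assert len(cl) >= params.min_points
            assert np.diff(cl["t"]).max() <= params.max_gap_s
            assert cl["t"].iloc[-1] - cl["t"].iloc[0] >= params.min_duration_s
            assert cluster_radius_m(cl) >= params.min_radius_m
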