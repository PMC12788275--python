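"""Cohort ground truth: latent factors, feature truths, availability masks.

The generator plants a standard-normal latent frailty factor ``L`` per
participant and derives every stream from it:

* five lifelog feature truths (gait speed, chair-stand repetitions, daily
  steps, RPE level, subjective-health level) with configurable linear
  correlations to ``L`` (``effect_map``), plus orthogonal *domain* factors —
  a physical-capacity factor shared by the sensor features and a
  self-perception factor shared by the self-reports — so that the feature
  set carries multivariate information about frailty beyond a single axis;
* a 50-item deficit liability model whose shared loading on ``L`` is
  calibrated so that the scored Frailty Index attains the planted
  ``effect_map["fi"]`` correlation with ``L`` (an FI reliability of 0.85 by
  default);
* per-feature availability masks with the study's marginal availability,
  sharing a latent *adherence* factor (independent of all health variables)
  whose loading is calibrated so the expected complete-case fraction over
  the five modeled features matches the analysis sample implied by the
  study's degrees of freedom (72/300).

Daily-step truths are lognormal; their planted correlation is
pre-compensated for the lognormal transform so the *linear* sample
correlation with ``L`` converges to the ``effect_map`` value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import brentq
from scipy.stats import norm

__all__ = [
    "CohortConfig",
    "ParticipantTruth",
    "generate_cohort",
    "truths_frame",
    "FEATURES",
    "MASK_KEYS",
    "DEFAULT_EFFECT_MAP",
    "DEFAULT_DOMAIN_MAP",
    "DEFAULT_MISSINGNESS_MAP",
    "BASE_EPOCH",
]

# Epoch seconds of a local (UTC+9) midnight; all simulated timestamps count
# forward from here so local calendar-day arithmetic is exact.
BASE_EPOCH = 1_693_494_000.0

FEATURES = ("gait_speed", "sts_reps", "daily_steps", "rpe", "health")
#: availability mask keys; daily and hourly steps share the pedometer mask
MASK_KEYS = ("gait_speed", "sts_reps", "steps", "rpe", "health")

#: planted correlations with latent frailty (lifelog truths + scored FI).
#: The ``fi`` entry is the FI's reliability with respect to the latent
#: factor; the 50-item registry's intrinsic item noise caps it near 0.78.
DEFAULT_EFFECT_MAP: dict[str, float] = {
    "gait_speed": -0.370,
    "sts_reps": -0.224,
    "daily_steps": -0.119,
    "rpe": 0.135,
    "health": 0.232,
    "fi": 0.72,
}

#: planted correlations with the orthogonal domain factors: sensor features
#: share the physical-capacity factor, self-reports the perception factor.
#: Defaults follow the centering rule r_D = r_L * (1 - rho_L) / rho_D (with
#: rho_L/rho_D the calibrated FI-factor correlations), so the *observable*
#: feature-FI correlations center on the same published values the latent
#: correlations are planted at, compensating the FI's item-noise attenuation.
DEFAULT_DOMAIN_MAP: dict[str, float] = {
    "gait_speed": -0.317,
    "sts_reps": -0.192,
    "daily_steps": -0.102,
    "rpe": 0.125,
    "health": 0.215,
}

#: per-feature availability (probability a participant contributes the feature)
DEFAULT_MISSINGNESS_MAP: dict[str, float] = {
    "gait_speed": 94 / 300,
    "sts_reps": 253 / 300,
    "steps": 290 / 300,
    "rpe": 248 / 300,
    "health": 255 / 300,
}

# Marginal scales of the feature truths (population mean/SD of the study's
# lifelog table; steps are lognormal with the matching mean/SD).
GAIT_MEAN, GAIT_SD = 1.12, 0.13
STS_MEAN, STS_SD = 17.36, 5.12
STEPS_MEAN, STEPS_SD = 3343.93, 3049.45
RPE_MEAN, RPE_SD = 5.88, 2.17
HEALTH_MEAN, HEALTH_SD = 2.05, 0.42

# rng stream tags (second word of the seed sequence)
STREAM_TRUTH, STREAM_GPS, STREAM_STEPS, STREAM_ACCEL, STREAM_REPORTS, STREAM_CGA = range(1, 7)


class ConfigError(ValueError):
    """Raised for invalid probabilities, correlations or loadings."""


@dataclass
class CohortConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults reproduce the source study's structure: 300 participants, two
    weeks of monitoring, the published effect sizes and per-feature
    availability.  ``bouts_per_day`` is the Poisson mean of daily walking
    bouts; bout durations are uniform on
    [``bout_min_s``, ``bout_max_s``].
    """

    n_participants: int = 300
    seed: int = 0
    effect_map: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECT_MAP))
    domain_map: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DOMAIN_MAP))
    missingness_map: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSINGNESS_MAP)
    )
    # GPS stream
    gps_noise_sd: float = 5.0
    gps_noise_tau_s: float = 600.0
    sampling_interval: float = 1.0
    days: int = 14
    bouts_per_day: float = 1.5
    bout_min_s: float = 480.0
    bout_max_s: float = 1500.0
    mislabel_rate: float = 0.05
    glitch_rate: float = 0.005
    # chair-stand accelerometer
    accel_rate_hz: float = 50.0
    sts_amplitude: float = 2.0
    sts_noise_sd: float = 0.2
    # pedometer
    steps_day_cv: float = 0.4
    active_hours_mean: float = 4.4
    # self-reports
    rpe_noise_sd: float = 1.5
    health_noise_sd: float = 0.5
    # deficits
    item_missing_rate: float = 0.02
    # availability structure; None = calibrate to complete_case_rate
    adherence_loading: float | None = None
    complete_case_rate: float = 72 / 300

    def __post_init__(self) -> None:
        if self.n_participants < 0:
            raise ConfigError("n_participants must be >= 0")
        for name, val in self.effect_map.items():
            if not -1.0 < val < 1.0:
                raise ConfigError(f"effect_map[{name!r}] = {val} outside (-1, 1)")
        for name, val in self.domain_map.items():
            if not -1.0 < val < 1.0:
                raise ConfigError(f"domain_map[{name!r}] = {val} outside (-1, 1)")
        for name, val in self.missingness_map.items():
            if not 0.0 <= val <= 1.0:
                raise ConfigError(f"missingness_map[{name!r}] = {val} outside [0, 1]")
        for name in ("mislabel_rate", "glitch_rate", "item_missing_rate", "complete_case_rate"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ConfigError(f"{name} = {val} outside [0, 1]")
        if self.sampling_interval <= 0:
            raise ConfigError("sampling_interval must be > 0")
        if self.days < 0 or self.bouts_per_day < 0:
            raise ConfigError("days and bouts_per_day must be >= 0")
        for feat in FEATURES:
            r = self.effect_map.get(feat, 0.0)
            d = self.domain_map.get(feat, 0.0)
            if r * r + d * d >= 1.0:
                raise ConfigError(f"loadings for {feat!r} exceed unit variance")


@dataclass
class ParticipantTruth:
    """Ground truth for one participant (latent state + behavioral truths)."""

    id: str
    index: int
    seed: int
    latent_frailty: float
    phys_factor: float
    percept_factor: float
    adherence: float
    true_gait_speed: float
    true_daily_steps: float
    true_sts_reps: int
    true_rpe_level: float
    true_health_level: float
    deficit_propensity: np.ndarray
    observed: dict[str, bool]
    sex: str
    age: float
    height_cm: float
    fat_pct: float
    sppb: float


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    return float(np.log(mean) - sigma2 / 2.0), float(np.sqrt(sigma2))


#: factor by which a planted linear correlation must be inflated on the
#: underlying normal scale so that corr(L, exp(sigma * X)) hits the target
def _lognormal_corr_compensation(sigma: float) -> float:
    return float(np.sqrt(np.expm1(sigma**2)) / sigma)


def _mix(rng_normals: np.ndarray, loads: list[tuple[np.ndarray, float]]) -> np.ndarray:
    """Linear factor combination with unit marginal variance."""
    total = np.zeros_like(rng_normals)
    explained = 0.0
    for factor, w in loads:
        total += w * factor
        explained += w * w
    if explained >= 1.0:
        raise ConfigError("factor loadings exceed unit variance")
    return total + np.sqrt(1.0 - explained) * rng_normals


@lru_cache(maxsize=32)
def _calibrated_adherence_loading(
    availabilities: tuple[float, ...], target_joint: float
) -> float:
    """Loading of the shared adherence factor matching the joint availability.

    Availability indicators are probit-linked to a common standard-normal
    adherence factor; the loading ``gamma`` solves
    ``E_A[prod_f Phi((z_f - gamma A)/sqrt(1-gamma^2))] = target_joint`` via
    Gauss-Hermite quadrature.  ``gamma = 0`` reduces to independent masks.
    """
    avail = np.asarray(availabilities, dtype=float)
    if np.any(avail <= 0.0):
        return 0.0  # joint availability is 0 regardless of the loading
    z = norm.ppf(avail)
    indep = float(np.prod(avail))
    if target_joint <= indep + 1e-12:
        return 0.0
    upper = float(np.prod(np.min(avail)))  # gamma -> 1 limit: min availability
    if target_joint >= np.min(avail) - 1e-9:
        raise ConfigError(
            f"complete-case target {target_joint:.3f} unreachable "
            f"(min availability {np.min(avail):.3f})"
        )
    nodes, weights = hermgauss(81)
    a = nodes * np.sqrt(2.0)
    w = weights / np.sqrt(np.pi)

    def joint(gamma: float) -> float:
        s = np.sqrt(1.0 - gamma**2)
        probs = norm.cdf((z[None, :] - gamma * a[:, None]) / s)
        return float(w @ probs.prod(axis=1))

    return float(brentq(lambda g: joint(g) - target_joint, 1e-9, 0.99, xtol=1e-6))


def _draw_masks(cfg: CohortConfig, adherence: np.ndarray, rng: np.random.Generator) -> dict[str, np.ndarray]:
    avail = tuple(float(cfg.missingness_map.get(k, 1.0)) for k in MASK_KEYS)
    gamma = cfg.adherence_loading
    if gamma is None:
        gamma = _calibrated_adherence_loading(avail, float(cfg.complete_case_rate))
    if not 0.0 <= gamma < 1.0:
        raise ConfigError("adherence_loading must be in [0, 1)")
    s = np.sqrt(1.0 - gamma**2)
    out = {}
    for key, p in zip(MASK_KEYS, avail):
        v = gamma * adherence + s * rng.standard_normal(len(adherence))
        out[key] = v < norm.ppf(p) if 0.0 < p < 1.0 else np.full(len(adherence), p >= 1.0)
    return out


def generate_cohort(config: CohortConfig) -> list[ParticipantTruth]:
    """Draw the full cohort ground truth (deterministic in config + seed)."""
    from . import deficits as _def  # local import to avoid a cycle

    cfg = config
    n = cfg.n_participants
    rng = np.random.default_rng([cfg.seed, STREAM_TRUTH])
    L = rng.standard_normal(n)
    P = rng.standard_normal(n)
    S = rng.standard_normal(n)
    A = rng.standard_normal(n)

    em, dm = cfg.effect_map, cfg.domain_map

    gait = GAIT_MEAN + GAIT_SD * _mix(
        rng.standard_normal(n), [(L, em.get("gait_speed", 0.0)), (P, dm.get("gait_speed", 0.0))]
    )
    gait = np.clip(gait, 0.35, 1.95)

    sts = STS_MEAN + STS_SD * _mix(
        rng.standard_normal(n), [(L, em.get("sts_reps", 0.0)), (P, dm.get("sts_reps", 0.0))]
    )
    sts = np.maximum(np.round(sts), 0).astype(int)

    mu_ln, sigma_ln = _lognormal_params(STEPS_MEAN, STEPS_SD)
    comp = _lognormal_corr_compensation(sigma_ln)
    steps_score = _mix(
        rng.standard_normal(n),
        [(L, comp * em.get("daily_steps", 0.0)), (P, comp * dm.get("daily_steps", 0.0))],
    )
    steps = np.exp(mu_ln + sigma_ln * steps_score)

    rpe = RPE_MEAN + RPE_SD * _mix(
        rng.standard_normal(n), [(L, em.get("rpe", 0.0)), (S, dm.get("rpe", 0.0))]
    )
    rpe = np.clip(rpe, 1.0, 15.0)

    health = HEALTH_MEAN + HEALTH_SD * _mix(
        rng.standard_normal(n), [(L, em.get("health", 0.0)), (S, dm.get("health", 0.0))]
    )
    health = np.clip(health, 1.0, 4.0)

    sex = np.where(rng.random(n) < 0.7933, "F", "M")
    age = 73.30 + 5.37 * _mix(rng.standard_normal(n), [(L, 0.15)])
    height = np.where(
        sex == "F",
        154.8 + 5.5 * rng.standard_normal(n),
        164.5 + 6.0 * rng.standard_normal(n),
    )
    fat = 31.46 + 7.38 * _mix(rng.standard_normal(n), [(L, 0.10)])
    sppb = 11.17 + 1.52 * _mix(rng.standard_normal(n), [(L, -0.20), (P, -0.15)])
    sppb = np.clip(np.round(sppb), 0, 12)

    masks = _draw_masks(cfg, A, rng)

    lam = _def.calibrated_item_loading(float(em.get("fi", DEFAULT_EFFECT_MAP["fi"])))
    propensity = _def.deficit_propensity(L, P, S, lam)

    width = max(4, len(str(max(n, 1))))
    truths = []
    for i in range(n):
        truths.append(
            ParticipantTruth(
                id=f"P{i + 1:0{width}d}",
                index=i,
                seed=cfg.seed,
                latent_frailty=float(L[i]),
                phys_factor=float(P[i]),
                percept_factor=float(S[i]),
                adherence=float(A[i]),
                true_gait_speed=float(gait[i]),
                true_daily_steps=float(steps[i]),
                true_sts_reps=int(sts[i]),
                true_rpe_level=float(rpe[i]),
                true_health_level=float(health[i]),
                deficit_propensity=propensity[i],
                observed={k: bool(masks[k][i]) for k in MASK_KEYS},
                sex=str(sex[i]),
                age=float(age[i]),
                height_cm=float(height[i]),
                fat_pct=float(fat[i]),
                sppb=float(sppb[i]),
            )
        )
    return truths


def truths_frame(truths: list[ParticipantTruth]):
    """Tabular view of the cohort ground truth (one row per participant)."""
    import pandas as pd

    rows = []
    for t in truths:
        row = {
            "participant_id": t.id,
            "latent_frailty": t.latent_frailty,
            "phys_factor": t.phys_factor,
            "percept_factor": t.percept_factor,
            "true_gait_speed": t.true_gait_speed,
            "true_daily_steps": t.true_daily_steps,
            "true_sts_reps": t.true_sts_reps,
            "true_rpe_level": t.true_rpe_level,
            "true_health_level": t.true_health_level,
            "sex": t.sex,
            "age": t.age,
            "height_cm": t.height_cm,
            "fat_pct": t.fat_pct,
            "sppb": t.sppb,
        }
        for k, v in t.observed.items():
            row[f"observed_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
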