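"""Synthetic CGA deficit items on a shared liability model.

Every deficit item ``j`` has a standard-normal liability
``U_j = lam * L + mu_j * D_j + sqrt(1 - lam^2 - mu_j^2) * eps_j`` where ``L``
is latent frailty, ``D_j`` an orthogonal domain factor (physical capacity for
performance/mobility items, self-perception for the condition checklist) and
``eps_j`` item-specific noise.  Crossing ordered thresholds on ``U_j`` yields
the item's graded deficit levels; thresholds are set from the item's marginal
prevalence (chosen to match the study population's descriptive magnitudes,
giving a mean FI near 0.09).

The shared loading ``lam`` is not a free parameter: it is calibrated by
root-finding on a fixed internal Monte Carlo so that the *scored* FI attains
the planted ``corr(FI, L)`` (the ``effect_map["fi"]`` entry, an FI
reliability).  Raw CGA measures (BMI, grip kg, Mini-Cog score, ...) are
monotone transforms of the same liabilities, so scoring them through
:mod:`frailtylog.frailty` reproduces the liability-level deficits exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .. import frailty as _frailty

__all__ = [
    "LiabilityItem",
    "liability_items",
    "calibrated_item_loading",
    "max_achievable_fi_corr",
    "deficit_propensity",
    "simulate_cga_measures",
    "simulate_deficits",
    "theoretical_smm_cutoffs",
]

# Marginal prevalences of the 21 chronic-condition indicators (sum ~= 2.7,
# the study's mean medical-history count), spread from common to rare.
CONDITION_PREVALENCES = (
    0.45, 0.35, 0.30, 0.25, 0.20, 0.18, 0.15, 0.12, 0.10, 0.09, 0.08,
    0.07, 0.06, 0.05, 0.05, 0.04, 0.04, 0.03, 0.03, 0.02, 0.02,
)
ADL_PREV, IADL_PREV, NAGI_PREV, ROSOW_PREV = 0.018, 0.009, 0.0925, 0.05
WEIGHT_LOSS_PREV = 0.09
BALANCE_PREV = 0.15
SMM_PREV = 0.20  # lowest sex-specific quintile by construction

# Raw-measure marginals (monotone transforms of the item liabilities).
BMI_MEAN, BMI_SD = 23.72, 3.15
GAIT6_MEAN, GAIT6_SD = 1.05, 0.33
CHAIR5_MEAN, CHAIR5_SD = 11.5, 3.0
SMM_MARGINALS = {"F": (20.0, 3.0), "M": (26.5, 4.0)}
GRIP_MARGINALS = {"F": (21.0, 4.5), "M": (32.0, 7.0)}
# Mini-Cog score distribution, scores 0..5 (mean ~= 4.0).
MINI_COG_PROBS = (0.03, 0.04, 0.06, 0.12, 0.35, 0.40)

DOMAIN_LOADING_P = 0.60  # performance / mobility items
DOMAIN_LOADING_S = 0.35  # condition checklist (self-reported symptoms)

_MC_SIZE = 60_000
_MC_SEED = 987_654_321


@dataclass(frozen=True)
class LiabilityItem:
    """Threshold representation of one deficit item.

    ``cum_probs[k]`` is P(deficit level <= levels[k]); the deficit equals
    ``levels[i]`` with ``i`` the number of thresholds strictly below the
    liability (ties resolve to the healthier side).  ``lam_scale`` rescales
    the shared frailty loading for items that are weak frailty markers
    (body-composition items), keeping their covariate counterparts from
    dominating the clinical model.
    """

    name: str
    domain: str | None  # 'P', 'S' or None
    mu: float
    levels: tuple[float, ...]
    cum_probs: tuple[float, ...]
    lam_scale: float = 1.0

    @property
    def z_cuts(self) -> np.ndarray:
        return norm.ppf(np.asarray(self.cum_probs))

    def values_from_liability(self, u: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.z_cuts, u, side="left")
        return np.asarray(self.levels, dtype=float)[idx]


def _binary(
    name: str, p: float, domain: str | None = None, mu: float = 0.0, lam_scale: float = 1.0
) -> LiabilityItem:
    return LiabilityItem(name, domain, mu, (0.0, 1.0), (1.0 - p,), lam_scale)


@lru_cache(maxsize=1)
def liability_items() -> tuple[LiabilityItem, ...]:
    """The 50 items, in registry order."""
    items: list[LiabilityItem] = []
    for i, p in enumerate(CONDITION_PREVALENCES, start=1):
        items.append(_binary(f"cond_{i:02d}", p, "S", DOMAIN_LOADING_S))
    for i in range(1, 7):
        items.append(_binary(f"adl_{i}", ADL_PREV))
    for i in range(1, 9):
        items.append(_binary(f"iadl_{i}", IADL_PREV))
    for i in range(1, 5):
        items.append(_binary(f"nagi_{i}", NAGI_PREV, "P", DOMAIN_LOADING_P))
    for i in range(1, 4):
        items.append(_binary(f"rosow_{i}", ROSOW_PREV, "P", DOMAIN_LOADING_P))
    items.append(_binary("weight_loss", WEIGHT_LOSS_PREV, lam_scale=0.5))
    bmi_prev = float(norm.cdf((_frailty.LOW_BMI_THRESHOLD - BMI_MEAN) / BMI_SD))
    items.append(_binary("low_bmi", bmi_prev, lam_scale=0.4))
    items.append(_binary("low_smm", SMM_PREV, "P", 0.20, lam_scale=0.4))
    cum = np.cumsum(MINI_COG_PROBS[::-1])[:-1]  # healthy side first
    items.append(
        LiabilityItem("mini_cog", None, 0.0, (0.0, 0.3, 0.7, 0.7, 0.7, 1.0), tuple(cum))
    )
    gait_cum = tuple(
        float(norm.cdf((GAIT6_MEAN - c) / GAIT6_SD)) for c in _frailty.DEFAULT_GAIT_CUTPOINTS
    )
    items.append(
        LiabilityItem("slow_gait", "P", DOMAIN_LOADING_P, _frailty.DEFAULT_GAIT_LEVELS, gait_cum)
    )
    chair_cum = tuple(
        float(norm.cdf((c - CHAIR5_MEAN) / CHAIR5_SD)) for c in _frailty.DEFAULT_CHAIR_CUTPOINTS_S
    )
    items.append(
        LiabilityItem(
            "slow_chair_rise", "P", DOMAIN_LOADING_P, _frailty.DEFAULT_CHAIR_LEVELS, chair_cum
        )
    )
    grip_prev = 0.0
    sex_shares = {"F": 0.7933, "M": 0.2067}
    for sex, (m, s) in GRIP_MARGINALS.items():
        cut = _frailty.DEFAULT_GRIP_CUTOFFS_KG[sex]
        grip_prev += sex_shares[sex] * float(norm.sf((m - cut) / s))
    items.append(_binary("low_grip", grip_prev, "P", DOMAIN_LOADING_P))
    items.append(_binary("poor_balance", BALANCE_PREV, "P", DOMAIN_LOADING_P))
    assert len(items) == 50
    return tuple(items)


def _liabilities(
    L: np.ndarray, P: np.ndarray, S: np.ndarray, lam: float, eps: np.ndarray
) -> np.ndarray:
    """(n, 50) liability matrix for the given shared loading."""
    items = liability_items()
    mus = np.array([it.mu for it in items])
    lams = lam * np.array([it.lam_scale for it in items])
    dom = np.stack(
        [P if it.domain == "P" else (S if it.domain == "S" else np.zeros_like(P)) for it in items],
        axis=1,
    )
    unique_sd = np.sqrt(1.0 - lams**2 - mus**2)
    return lams[None, :] * L[:, None] + mus[None, :] * dom + unique_sd[None, :] * eps


def _deficit_matrix(U: np.ndarray) -> np.ndarray:
    items = liability_items()
    out = np.empty_like(U)
    for j, it in enumerate(items):
        out[:, j] = it.values_from_liability(U[:, j])
    return out


@lru_cache(maxsize=1)
def _mc_draws() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    rng = np.random.Generator(np.random.Philox(_MC_SEED))
    L = rng.standard_normal(_MC_SIZE)
    P = rng.standard_normal(_MC_SIZE)
    S = rng.standard_normal(_MC_SIZE)
    eps = rng.standard_normal((_MC_SIZE, 50))
    return L, P, S, eps


def _fi_corr(lam: float) -> float:
    L, P, S, eps = _mc_draws()
    fi = _deficit_matrix(_liabilities(L, P, S, lam, eps)).mean(axis=1)
    return float(np.corrcoef(fi, L)[0, 1])


def _max_loading() -> float:
    bound = min(
        np.sqrt(1.0 - it.mu**2) / it.lam_scale for it in liability_items() if it.lam_scale > 0
    )
    return float(min(bound, 1.0) - 1e-3)


@lru_cache(maxsize=8)
def max_achievable_fi_corr() -> float:
    """corr(FI, L) at the largest admissible shared loading."""
    return _fi_corr(_max_loading())


@lru_cache(maxsize=32)
def calibrated_item_loading(target_fi_corr: float) -> float:
    """Shared item loading achieving the planted corr(FI, latent frailty)."""
    if not 0.0 < target_fi_corr < 1.0:
        raise ValueError("planted FI correlation must be in (0, 1)")
    hi = _max_loading()
    top = _fi_corr(hi)
    if target_fi_corr > top:
        raise ValueError(
            f"planted corr(FI, L) = {target_fi_corr} exceeds the maximum "
            f"{top:.3f} achievable with the 50-item registry"
        )
    return float(brentq(lambda lam: _fi_corr(lam) - target_fi_corr, 0.01, hi, xtol=1e-4))


def deficit_propensity(
    L: np.ndarray, P: np.ndarray, S: np.ndarray, lam: float
) -> np.ndarray:
    """(n, 50) expected deficit value given the factors (monotone in L)."""
    items = liability_items()
    L, P, S = (np.atleast_1d(np.asarray(a, dtype=float)) for a in (L, P, S))
    out = np.empty((len(L), len(items)))
    for j, it in enumerate(items):
        dom = P if it.domain == "P" else (S if it.domain == "S" else np.zeros_like(P))
        lam_j = lam * it.lam_scale
        mean = lam_j * L + it.mu * dom
        sd = float(np.sqrt(1.0 - lam_j**2 - it.mu**2))
        cdfs = norm.cdf((it.z_cuts[None, :] - mean[:, None]) / sd)
        probs = np.diff(np.concatenate([np.zeros((len(L), 1)), cdfs, np.ones((len(L), 1))], axis=1))
        out[:, j] = probs @ np.asarray(it.levels, dtype=float)
    return out


def theoretical_smm_cutoffs() -> dict[str, float]:
    """Population (rather than cohort-sample) lowest-quintile SMM cutoffs."""
    z80 = norm.ppf(1.0 - SMM_PREV)
    return {sex: m - s * z80 for sex, (m, s) in SMM_MARGINALS.items()}


def _measures_from_liabilities(
    U: np.ndarray, sex: np.ndarray, height_cm: np.ndarray
) -> pd.DataFrame:
    """Raw CGA measures as monotone transforms of the item liabilities."""
    items = liability_items()
    cols: dict[str, np.ndarray] = {}
    by_name = {it.name: j for j, it in enumerate(items)}

    for it in items:
        if it.name in (
            "weight_loss", "low_bmi", "low_smm", "mini_cog",
            "slow_gait", "slow_chair_rise", "low_grip", "poor_balance",
        ):
            continue
        if it.name == "poor_balance":
            continue
        cols[it.name] = it.values_from_liability(U[:, by_name[it.name]])

    u = lambda name: U[:, by_name[name]]
    z_wl = norm.ppf(1.0 - WEIGHT_LOSS_PREV)
    cols["weight_loss_kg"] = np.maximum(0.0, 4.5 + 2.5 * (u("weight_loss") - z_wl))
    cols["bmi"] = BMI_MEAN - BMI_SD * u("low_bmi")
    smm_mean = np.array([SMM_MARGINALS[s][0] for s in sex])
    smm_sd = np.array([SMM_MARGINALS[s][1] for s in sex])
    cols["smm_kg"] = smm_mean - smm_sd * u("low_smm")
    mc_idx = np.searchsorted(items[by_name["mini_cog"]].z_cuts, u("mini_cog"), side="left")
    cols["mini_cog"] = (5 - mc_idx).astype(float)
    cols["gait_6m_ms"] = np.maximum(0.1, GAIT6_MEAN - GAIT6_SD * u("slow_gait"))
    cols["chair5_s"] = np.maximum(3.0, CHAIR5_MEAN + CHAIR5_SD * u("slow_chair_rise"))
    grip_mean = np.array([GRIP_MARGINALS[s][0] for s in sex])
    grip_sd = np.array([GRIP_MARGINALS[s][1] for s in sex])
    cols["grip_kg"] = grip_mean - grip_sd * u("low_grip")
    z_bal = norm.ppf(1.0 - BALANCE_PREV)
    cols["balance_impaired"] = (u("poor_balance") > z_bal).astype(float)

    df = pd.DataFrame(cols)
    df["sex"] = sex
    df["weight_kg"] = df["bmi"] * (np.asarray(height_cm) / 100.0) ** 2
    return df


def simulate_cga_measures(truths, config) -> pd.DataFrame:
    """Raw CGA measure table for a cohort (one row per participant).

    Per-item missingness (``config.item_missing_rate``) is applied to the
    measure columns, exercising the FI's adjusted denominator downstream.
    Deterministic per participant: the draw depends only on
    ``(config.seed, participant index)``.
    """
    from .cohort import DEFAULT_EFFECT_MAP, STREAM_CGA

    lam = calibrated_item_loading(
        float(config.effect_map.get("fi", DEFAULT_EFFECT_MAP["fi"]))
    )
    rows = []
    for t in truths:
        rng = np.random.default_rng([config.seed, STREAM_CGA, t.index])
        eps = rng.standard_normal((1, 50))
        U = _liabilities(
            np.array([t.latent_frailty]),
            np.array([t.phys_factor]),
            np.array([t.percept_factor]),
            lam,
            eps,
        )
        df = _measures_from_liabilities(U, np.array([t.sex]), np.array([t.height_cm]))
        if config.item_missing_rate > 0:
            # InBody-style clinic measures (BMI, SMM, weight) are taken for
            # everyone; item missingness hits questionnaire/performance items.
            measure_cols = [
                c for c in df.columns if c not in ("sex", "weight_kg", "bmi", "smm_kg")
            ]
            drop = rng.random(len(measure_cols)) < config.item_missing_rate
            for c, d in zip(measure_cols, drop):
                if d:
                    df.loc[:, c] = np.nan
        df.insert(0, "participant_id", t.id)
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    return out


def simulate_deficits(truth, config) -> _frailty.DeficitProfile:
    """Score one participant's simulated CGA measures into a deficit profile.

    Uses the population (theoretical) SMM cutoffs since a single participant
    carries no cohort quantile.
    """
    measures = simulate_cga_measures([truth], config).iloc[0]
    registry = _frailty.default_registry(smm_cutoffs_kg=theoretical_smm_cutoffs())
    return registry.score(measures)
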