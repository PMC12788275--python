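"""Deficit-accumulation Frailty Index (FI) scoring.

The FI follows the cumulative-deficit model: each health deficit is coded on
[0, 1] (0 = deficit absent, 1 = fully present, graded values in between) and
the index is the sum of deficit values divided by the number of deficits
assessed.  With the default 50-item registry a fully healthy profile scores 0
and a maximally deficient one scores 1.  When some items are missing the
denominator is reduced to the number of non-missing items, so the FI is always
the proportion of deficits present among the deficits actually measured.

The default registry reconstructs a CGA-style 50-item set:

* 21 chronic-condition indicators (medical history),
* 6 ADL items (Katz) and 8 IADL items (Lawton-Brody),
* 4 Nagi functional-limitation items and 3 Rosow-Breslau mobility items,
* weight loss > 4.5 kg in the past year, BMI <= 18.5 kg/m^2, low skeletal
  muscle mass (sex-specific cutoff, by default the cohort's lowest quintile),
* Mini-Cog (graded 0/0.3/0.7/1),
* gait speed and chair-rise time (graded), handgrip strength (sex-specific
  cutoffs) and a balance indicator.

Item composition, cutpoints and thresholds are configuration; the defaults
are documented in ``docs/methods.md``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import math

import numpy as np
import pandas as pd

__all__ = [
    "DeficitItem",
    "DeficitProfile",
    "FrailtyIndexResult",
    "DeficitRegistry",
    "map_mini_cog",
    "map_threshold_items",
    "map_graded_performance",
    "compute_fi",
    "default_registry",
    "smm_quintile_cutoffs",
    "score_row",
    "score_cohort",
    "DEFAULT_GRIP_CUTOFFS_KG",
    "DEFAULT_GAIT_CUTPOINTS",
    "DEFAULT_GAIT_LEVELS",
    "DEFAULT_CHAIR_CUTPOINTS_S",
    "DEFAULT_CHAIR_LEVELS",
]

# Sex-specific handgrip cutoffs (kg): common Asian sarcopenia working-group
# values; the deficit fires strictly below the cutoff.
DEFAULT_GRIP_CUTOFFS_KG: dict[str, float] = {"M": 28.0, "F": 18.0}

# Graded gait speed (m/s): faster is healthier, ties resolve to the
# less-frail grade (>= 1.0 -> 0).
DEFAULT_GAIT_CUTPOINTS: tuple[float, ...] = (1.0, 0.6)
DEFAULT_GAIT_LEVELS: tuple[float, ...] = (0.0, 0.5, 1.0)

# Graded five-repetition chair-rise time (s): shorter is healthier,
# ties resolve to the less-frail grade (<= 11.2 -> 0).
DEFAULT_CHAIR_CUTPOINTS_S: tuple[float, ...] = (11.2, 16.7)
DEFAULT_CHAIR_LEVELS: tuple[float, ...] = (0.0, 0.5, 1.0)

WEIGHT_LOSS_THRESHOLD_KG = 4.5
LOW_BMI_THRESHOLD = 18.5


class FrailtyValidationError(ValueError):
    """Raised for out-of-range raw measures or inconsistent configuration."""


class UndefinedFIError(ValueError):
    """Raised when every deficit item is missing and the FI is undefined."""


def map_mini_cog(score: int) -> float:
    """Convert a Mini-Cog screen score (0-5) to a graded deficit value.

    A perfect screen (5) carries no deficit, 4 a mild one (0.3), scores of
    1-3 a substantial one (0.7) and 0 the full deficit (1).
    """
    if isinstance(score, float) and not float(score).is_integer():
        raise FrailtyValidationError(f"Mini-Cog score must be an integer, got {score!r}")
    s = int(score)
    if not 0 <= s <= 5:
        raise FrailtyValidationError(f"Mini-Cog score must be in 0..5, got {score!r}")
    if s == 5:
        return 0.0
    if s == 4:
        return 0.3
    if s >= 1:
        return 0.7
    return 1.0


def map_graded_performance(
    measure: float,
    cutpoints: Sequence[float],
    levels: Sequence[float],
    *,
    higher_is_better: bool = True,
) -> float:
    """Grade a continuous performance measure into a deficit value.

    ``cutpoints`` are ordered from the healthiest boundary to the frailest;
    ``levels`` holds one deficit value per interval (``len(cutpoints) + 1``),
    nondecreasing in severity.  A measure exactly on a cutpoint is assigned to
    the less-frail side.

    With ``higher_is_better`` (e.g. gait speed) the cutpoints must be strictly
    decreasing and values >= the first cutpoint take ``levels[0]``; with
    ``higher_is_better=False`` (e.g. completion time) they must be strictly
    increasing and values <= the first cutpoint take ``levels[0]``.
    """
    cuts = list(cutpoints)
    lv = list(levels)
    if len(lv) != len(cuts) + 1:
        raise FrailtyValidationError("need exactly one level per interval")
    diffs = np.diff(cuts)
    if higher_is_better:
        if len(cuts) > 1 and not np.all(diffs < 0):
            raise FrailtyValidationError("cutpoints must be strictly decreasing")
    else:
        if len(cuts) > 1 and not np.all(diffs > 0):
            raise FrailtyValidationError("cutpoints must be strictly increasing")
    if any(b < a for a, b in zip(lv, lv[1:])):
        raise FrailtyValidationError("deficit levels must be nondecreasing in severity")
    x = float(measure)
    for i, c in enumerate(cuts):
        if (x >= c) if higher_is_better else (x <= c):
            return lv[i]
    return lv[-1]


def map_threshold_items(
    measures: Mapping[str, float],
    *,
    grip_cutoffs_kg: Mapping[str, float] | None = None,
    smm_cutoffs_kg: Mapping[str, float] | None = None,
) -> dict[str, float | None]:
    """Map threshold-type raw measures to binary deficits.

    Expects (possibly missing/NaN) keys ``weight_loss_kg``, ``bmi``,
    ``grip_kg``, ``smm_kg`` and requires ``sex`` ('F'/'M') for the
    sex-specific items.  Returns a dict of deficit values with ``None`` for
    missing measures.  ``smm_cutoffs_kg`` is typically derived from the cohort
    (see :func:`smm_quintile_cutoffs`); without it the SMM item is missing.
    """
    grip_cutoffs_kg = dict(grip_cutoffs_kg or DEFAULT_GRIP_CUTOFFS_KG)
    out: dict[str, float | None] = {}

    def _get(key: str) -> float | None:
        v = measures.get(key)
        if v is None:
            return None
        v = float(v)
        return None if math.isnan(v) else v

    wl = _get("weight_loss_kg")
    out["weight_loss"] = None if wl is None else float(wl > WEIGHT_LOSS_THRESHOLD_KG)
    bmi = _get("bmi")
    out["low_bmi"] = None if bmi is None else float(bmi <= LOW_BMI_THRESHOLD)

    sex = measures.get("sex")
    needs_sex = any(_get(k) is not None for k in ("grip_kg", "smm_kg"))
    if needs_sex:
        if sex not in ("F", "M"):
            raise FrailtyValidationError(
                "sex ('F' or 'M') is required for grip/SMM deficits"
            )
    grip = _get("grip_kg")
    out["low_grip"] = None if grip is None else float(grip < grip_cutoffs_kg[sex])
    smm = _get("smm_kg")
    if smm is None or smm_cutoffs_kg is None:
        out["low_smm"] = None
    else:
        out["low_smm"] = float(smm < float(smm_cutoffs_kg[sex]))
    return out


@dataclass(frozen=True)
class DeficitItem:
    """One deficit in the registry.

    ``mapper`` takes the participant's raw-measure mapping and returns the
    deficit value in [0, 1], or ``None`` when the underlying measure is
    missing.
    """

    name: str
    kind: str  # 'binary' | 'graded' | 'threshold'
    levels: tuple[float, ...]
    mapper: Callable[[Mapping[str, object]], float | None]

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "graded", "threshold"):
            raise FrailtyValidationError(f"unknown item kind {self.kind!r}")
        for v in self.levels:
            if not 0.0 <= v <= 1.0:
                raise FrailtyValidationError(f"{self.name}: level {v} outside [0, 1]")

    def evaluate(self, measures: Mapping[str, object]) -> float | None:
        v = self.mapper(measures)
        if v is None:
            return None
        v = float(v)
        if not 0.0 <= v <= 1.0:
            raise FrailtyValidationError(f"{self.name}: deficit {v} outside [0, 1]")
        return v


@dataclass
class DeficitProfile:
    """Per-item deficit values for one participant (NaN = missing)."""

    values: pd.Series  # indexed by item name, float with NaN for missing
    registry_size: int

    def __post_init__(self) -> None:
        n_present = int(self.values.notna().sum())
        if self.registry_size < n_present:
            raise FrailtyValidationError("registry smaller than number of scored items")


@dataclass(frozen=True)
class FrailtyIndexResult:
    fi: float
    n_present: int
    n_missing: int


def compute_fi(profile: DeficitProfile) -> FrailtyIndexResult:
    """Normalized FI: sum of non-missing deficit values over their count.

    With a complete profile the denominator equals the registry size (50 by
    default); missing items shrink the denominator.  All-missing profiles have
    no defined FI and raise :class:`UndefinedFIError`.
    """
    vals = profile.values.to_numpy(dtype=float)
    present = ~np.isnan(vals)
    n_present = int(present.sum())
    n_missing = profile.registry_size - n_present
    if n_present == 0:
        raise UndefinedFIError("all deficit items missing; FI undefined")
    fi = float(vals[present].sum() / n_present)
    return FrailtyIndexResult(fi=fi, n_present=n_present, n_missing=n_missing)


def _indicator_mapper(column: str) -> Callable[[Mapping[str, object]], float | None]:
    def mapper(m: Mapping[str, object]) -> float | None:
        v = m.get(column)
        if v is None:
            return None
        v = float(v)
        if math.isnan(v):
            return None
        if v not in (0.0, 1.0):
            raise FrailtyValidationError(f"{column}: indicator must be 0/1, got {v}")
        return v

    return mapper


@dataclass
class DeficitRegistry:
    """An ordered deficit-item set with a scoring entry point."""

    items: list[DeficitItem] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.items)

    @property
    def names(self) -> list[str]:
        return [it.name for it in self.items]

    def score(self, measures: Mapping[str, object]) -> DeficitProfile:
        vals = pd.Series(
            {it.name: (np.nan if (v := it.evaluate(measures)) is None else v) for it in self.items},
            dtype=float,
        )
        return DeficitProfile(values=vals, registry_size=self.size)


def default_registry(
    *,
    grip_cutoffs_kg: Mapping[str, float] | None = None,
    smm_cutoffs_kg: Mapping[str, float] | None = None,
    gait_cutpoints: Sequence[float] = DEFAULT_GAIT_CUTPOINTS,
    gait_levels: Sequence[float] = DEFAULT_GAIT_LEVELS,
    chair_cutpoints_s: Sequence[float] = DEFAULT_CHAIR_CUTPOINTS_S,
    chair_levels: Sequence[float] = DEFAULT_CHAIR_LEVELS,
) -> DeficitRegistry:
    """The default 50-item registry.

    21 conditions + 6 ADL + 8 IADL + 4 Nagi + 3 Rosow-Breslau + weight loss +
    low BMI + low SMM + Mini-Cog + gait speed + chair-rise time + grip +
    balance = 50 items.
    """
    items: list[DeficitItem] = []
    for i in range(1, 22):
        items.append(DeficitItem(f"cond_{i:02d}", "binary", (0.0, 1.0), _indicator_mapper(f"cond_{i:02d}")))
    for i in range(1, 7):
        items.append(DeficitItem(f"adl_{i}", "binary", (0.0, 1.0), _indicator_mapper(f"adl_{i}")))
    for i in range(1, 9):
        items.append(DeficitItem(f"iadl_{i}", "binary", (0.0, 1.0), _indicator_mapper(f"iadl_{i}")))
    for i in range(1, 5):
        items.append(DeficitItem(f"nagi_{i}", "binary", (0.0, 1.0), _indicator_mapper(f"nagi_{i}")))
    for i in range(1, 4):
        items.append(DeficitItem(f"rosow_{i}", "binary", (0.0, 1.0), _indicator_mapper(f"rosow_{i}")))

    def _threshold_mapper(key: str) -> Callable[[Mapping[str, object]], float | None]:
        def mapper(m: Mapping[str, object]) -> float | None:
            return map_threshold_items(
                m, grip_cutoffs_kg=grip_cutoffs_kg, smm_cutoffs_kg=smm_cutoffs_kg
            )[key]

        return mapper

    items.append(DeficitItem("weight_loss", "threshold", (0.0, 1.0), _threshold_mapper("weight_loss")))
    items.append(DeficitItem("low_bmi", "threshold", (0.0, 1.0), _threshold_mapper("low_bmi")))
    items.append(DeficitItem("low_smm", "threshold", (0.0, 1.0), _threshold_mapper("low_smm")))

    def _mini_cog_mapper(m: Mapping[str, object]) -> float | None:
        v = m.get("mini_cog")
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return map_mini_cog(int(v))

    items.append(DeficitItem("mini_cog", "graded", (0.0, 0.3, 0.7, 1.0), _mini_cog_mapper))

    def _gait_mapper(m: Mapping[str, object]) -> float | None:
        v = m.get("gait_6m_ms")
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return map_graded_performance(float(v), gait_cutpoints, gait_levels, higher_is_better=True)

    items.append(DeficitItem("slow_gait", "graded", tuple(gait_levels), _gait_mapper))

    def _chair_mapper(m: Mapping[str, object]) -> float | None:
        v = m.get("chair5_s")
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return map_graded_performance(float(v), chair_cutpoints_s, chair_levels, higher_is_better=False)

    items.append(DeficitItem("slow_chair_rise", "graded", tuple(chair_levels), _chair_mapper))
    items.append(DeficitItem("low_grip", "threshold", (0.0, 1.0), _threshold_mapper("low_grip")))
    items.append(DeficitItem("poor_balance", "binary", (0.0, 1.0), _indicator_mapper("balance_impaired")))

    reg = DeficitRegistry(items=items)
    assert reg.size == 50
    return reg


def smm_quintile_cutoffs(cohort: pd.DataFrame) -> dict[str, float]:
    """Sex-specific lowest-quintile SMM cutoffs computed from a cohort table.

    Expects columns ``sex`` ('F'/'M') and ``smm_kg``; participants strictly
    below their sex's 20th percentile carry the low-SMM deficit.
    """
    out: dict[str, float] = {}
    for sex, grp in cohort.groupby("sex"):
        vals = grp["smm_kg"].dropna()
        if len(vals) == 0:
            raise FrailtyValidationError(f"no SMM values for sex {sex!r}")
        out[str(sex)] = float(np.percentile(vals, 20))
    return out


def score_row(measures: Mapping[str, object], registry: DeficitRegistry) -> FrailtyIndexResult:
    return compute_fi(registry.score(measures))


def score_cohort(
    cohort: pd.DataFrame,
    registry: DeficitRegistry | None = None,
    *,
    id_column: str = "participant_id",
) -> pd.DataFrame:
    """Score every row of a raw-measure cohort table.

    When ``registry`` is omitted, the default registry is used with SMM
    cutoffs computed from the cohort itself (lowest sex-specific quintile).
    Returns one row per participant: ``fi``, ``n_present``, ``n_missing``.
    """
    if registry is None:
        registry = default_registry(smm_cutoffs_kg=smm_quintile_cutoffs(cohort))
    records = []
    for _, row in cohort.iterrows():
        res = compute_fi(registry.score(row))
        records.append(
            {
                id_column: row[id_column],
                "fi": res.fi,
                "n_present": res.n_present,
                "n_missing": res.n_missing,
            }
        )
    return pd.DataFrame.from_records(records)
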