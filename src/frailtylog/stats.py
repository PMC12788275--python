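"""Cross-sectional association suite for FI ~ lifelog models.

Implements the analysis plan: Pearson correlations with Fisher-z confidence
intervals, hierarchical OLS with the R^2-change F test, variance inflation
factors, a lifelog-only model, drop-one and single-predictor sensitivity
fits, Huber robust regression (IRLS with MAD scale), and k-fold
cross-validated out-of-sample R^2.

Every analysis sample is formed by listwise deletion over the variables the
model uses (the study's printed degrees of freedom imply the same rule).
Standardized coefficients are computed by z-scoring outcome and predictors on
the analysis sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from sklearn.linear_model import LinearRegression
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold
from statsmodels.stats.outliers_influence import variance_inflation_factor

__all__ = [
    "CorrelationResult",
    "ModelFit",
    "HierarchicalRegressionResult",
    "assemble_complete_cases",
    "pearson_with_ci",
    "fit_linear_model",
    "hierarchical_fit",
    "vif",
    "huber_fit",
    "kfold_r2",
    "run_sensitivity_suite",
]

HUBER_TUNING_DEFAULT = 1.345


class DegenerateSampleError(ValueError):
    """Raised when listwise deletion leaves no analysis rows."""


class UndefinedCorrelationError(ValueError):
    """Raised for constant input or too few pairs."""


class CollinearityError(ValueError):
    """Raised when the design matrix is rank deficient."""


class ConvergenceError(RuntimeError):
    """Raised when IRLS fails to converge within the iteration budget."""


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    ci: tuple[float, float]
    n: int


@dataclass
class ModelFit:
    """OLS (or robust) fit summary.

    ``params``/``se``/``t``/``p``/``ci`` include the intercept (``const``);
    ``beta`` and ``vif`` cover the predictors only.  For robust fits ``r2``
    is the squared correlation between fitted and observed values and
    ``f_stat``/``f_df``/``f_p`` hold the Wald chi-square test of all slopes.
    """

    params: pd.Series
    se: pd.Series
    beta: pd.Series
    t: pd.Series
    p: pd.Series
    ci: pd.DataFrame
    r2: float
    f_stat: float
    f_df: tuple[float, float]
    f_p: float
    n: int
    vif: pd.Series
    kind: str = "ols"
    extra: dict = field(default_factory=dict)


@dataclass
class HierarchicalRegressionResult:
    step1: ModelFit
    step2: ModelFit
    delta_r2: float
    f_change: float
    df_change: tuple[int, int]
    p_change: float


def assemble_complete_cases(
    table: pd.DataFrame, variables: Sequence[str]
) -> tuple[pd.DataFrame, int, int]:
    """Listwise deletion over ``variables``; returns (rows, n_before, n_after)."""
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise KeyError(f"unknown variables: {missing}")
    n_before = len(table)
    out = table.dropna(subset=list(variables))
    if len(out) == 0:
        raise DegenerateSampleError("no complete cases for requested variables")
    return out, n_before, len(out)


def pearson_with_ci(x, y, alpha: float = 0.05) -> CorrelationResult:
    """Product-moment correlation with t-based p and Fisher-z CI.

    The CI is tanh(atanh(r) +/- z_{1-alpha/2} / sqrt(n - 3)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise UndefinedCorrelationError(f"need at least 4 pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    r, p = sps.pearsonr(x, y)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = sps.norm.ppf(1 - alpha / 2) / np.sqrt(n - 3)
    ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    return CorrelationResult(r=float(r), p=float(p), ci=ci, n=n)


def _design(X: pd.DataFrame) -> pd.DataFrame:
    Xd = sm.add_constant(X.astype(float), has_constant="add")
    return Xd


def vif(X: pd.DataFrame) -> pd.Series:
    """VIF_j = 1 / (1 - R^2_j) from regressing predictor j on the others.

    Auxiliary regressions include an intercept.  Perfectly collinear
    predictors yield ``inf``.
    """
    Xd = _design(X)
    vals = {}
    arr = Xd.to_numpy(dtype=float)
    for j, name in enumerate(X.columns):
        with np.errstate(divide="ignore"):
            vals[name] = float(variance_inflation_factor(arr, list(Xd.columns).index(name)))
    return pd.Series(vals)


def fit_linear_model(y: pd.Series, X: pd.DataFrame) -> ModelFit:
    """OLS with intercept, standardized betas, overall F and per-predictor VIF."""
    y = pd.Series(y).astype(float)
    X = pd.DataFrame(X).astype(float)
    n, k = len(y), X.shape[1]
    if n <= k + 1:
        raise DegenerateSampleError(f"need n > k + 1 (n={n}, k={k})")
    Xd = _design(X)
    if np.linalg.matrix_rank(Xd.to_numpy()) < Xd.shape[1]:
        raise CollinearityError("design matrix is rank deficient")
    res = sm.OLS(y.to_numpy(), Xd).fit()
    sy = y.std(ddof=1)
    beta = pd.Series(
        {c: res.params[c] * X[c].std(ddof=1) / sy for c in X.columns}, dtype=float
    )
    ci = res.conf_int()
    ci.columns = ["lo", "hi"]
    return ModelFit(
        params=res.params,
        se=res.bse,
        beta=beta,
        t=res.tvalues,
        p=res.pvalues,
        ci=ci,
        r2=float(res.rsquared),
        f_stat=float(res.fvalue),
        f_df=(float(res.df_model), float(res.df_resid)),
        f_p=float(res.f_pvalue),
        n=n,
        vif=vif(X),
        kind="ols",
        extra={"rss": float(res.ssr), "fitted": np.asarray(res.fittedvalues)},
    )


def hierarchical_fit(
    y: pd.Series, X1: pd.DataFrame, X2_add: pd.DataFrame
) -> HierarchicalRegressionResult:
    """Nested OLS on the identical sample with the R^2-change F test.

    F_change = (dR^2 / dk) / ((1 - R^2_2) / (n - k_2 - 1)) on (dk, n - k_2 - 1)
    degrees of freedom, equivalent to the RSS formulation for nested models.
    """
    if not (len(y) == len(X1) == len(X2_add)):
        raise ValueError("step samples differ in length")
    if isinstance(y, pd.Series):
        if not (y.index.equals(X1.index) and y.index.equals(X2_add.index)):
            raise ValueError("step samples must share the same rows")
    overlap = set(X1.columns) & set(X2_add.columns)
    if overlap:
        raise ValueError(f"added predictors duplicate step-1 columns: {sorted(overlap)}")
    X2 = pd.concat([X1, X2_add], axis=1)
    step1 = fit_linear_model(y, X1)
    step2 = fit_linear_model(y, X2)
    n = step2.n
    k2 = X2.shape[1]
    dk = X2_add.shape[1]
    delta = step2.r2 - step1.r2
    denom_df = n - k2 - 1
    denom = (1 - step2.r2) / denom_df
    if denom <= 0:  # perfect step-2 fit: the F statistic diverges
        f_change = float("inf") if delta > 0 else 0.0
    else:
        f_change = (delta / dk) / denom
    p_change = float(sps.f.sf(f_change, dk, denom_df))
    return HierarchicalRegressionResult(
        step1=step1,
        step2=step2,
        delta_r2=float(delta),
        f_change=float(f_change),
        df_change=(dk, denom_df),
        p_change=p_change,
    )


def huber_fit(
    y: pd.Series,
    X: pd.DataFrame,
    tuning: float = HUBER_TUNING_DEFAULT,
    *,
    tol: float = 1e-8,
    maxiter: int = 500,
) -> ModelFit:
    """Huber's T robust regression via IRLS.

    Scale is estimated by the median absolute deviation; the reported
    "R^2" is the squared correlation between fitted and observed values and
    the joint slope test is a Wald chi-square.
    """
    y = pd.Series(y).astype(float)
    X = pd.DataFrame(X).astype(float)
    n, k = len(y), X.shape[1]
    if n <= k + 1:
        raise DegenerateSampleError(f"need n > k + 1 (n={n}, k={k})")
    Xd = _design(X)
    rlm = sm.RLM(y.to_numpy(), Xd, M=sm.robust.norms.HuberT(t=tuning))
    res = rlm.fit(scale_est="mad", conv="coefs", tol=tol, maxiter=maxiter)
    n_iter = len(res.fit_history.get("params", []))
    if n_iter >= maxiter:
        raise ConvergenceError(f"IRLS did not converge within {maxiter} iterations")
    fitted = np.asarray(res.fittedvalues)
    r_fo = np.corrcoef(fitted, y.to_numpy())[0, 1]
    r2 = float(r_fo**2)
    # Wald chi-square: all slopes jointly zero.
    constraint = np.zeros((k, k + 1))
    constraint[:, 1:] = np.eye(k)
    wald = res.wald_test(constraint, use_f=False, scalar=True)
    chi2 = float(np.squeeze(wald.statistic))
    chi2_p = float(np.squeeze(wald.pvalue))
    sy = y.std(ddof=1)
    beta = pd.Series(
        {c: res.params[c] * X[c].std(ddof=1) / sy for c in X.columns}, dtype=float
    )
    ci = res.conf_int()
    ci.columns = ["lo", "hi"]
    zvals = res.params / res.bse
    pvals = pd.Series(2 * sps.norm.sf(np.abs(zvals)), index=res.params.index)
    return ModelFit(
        params=res.params,
        se=res.bse,
        beta=beta,
        t=zvals,
        p=pvals,
        ci=ci,
        r2=r2,
        f_stat=chi2,
        f_df=(float(k), float("nan")),
        f_p=chi2_p,
        n=n,
        vif=vif(X),
        kind="huber",
        extra={"scale": float(res.scale), "n_iter": n_iter, "fitted": fitted},
    )


def kfold_r2(
    y: pd.Series, X: pd.DataFrame, k: int = 5, seed: int = 0
) -> tuple[float, float, np.ndarray]:
    """Out-of-fold R^2 of the OLS model under seeded k-fold shuffling.

    Each fold is scored as 1 - SS_res / SS_tot with SS_tot about the held-out
    fold's own mean, so values may be negative.  Returns (mean, SD across
    folds with ddof=1, per-fold scores).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(pd.DataFrame(X), dtype=float)
    n = len(y)
    if n < 2 * k:
        raise ValueError(f"need n >= 2k rows (n={n}, k={k})")
    scores = []
    for train, test in KFold(n_splits=k, shuffle=True, random_state=seed).split(X):
        if len(test) < 2:
            raise ValueError("fold with fewer than 2 rows")
        model = LinearRegression().fit(X[train], y[train])
        scores.append(r2_score(y[test], model.predict(X[test])))
    scores = np.asarray(scores)
    return float(scores.mean()), float(scores.std(ddof=1)), scores


def run_sensitivity_suite(
    table: pd.DataFrame,
    *,
    outcome: str,
    covariates: Sequence[str],
    lifelogs: Sequence[str],
    drop_one: Sequence[str] = ("daily_mean_steps", "usual_gait_speed"),
) -> dict[str, HierarchicalRegressionResult | ModelFit]:
    """The robustness model family around the full hierarchical model.

    Produces the full covariates+lifelogs hierarchical model, one drop-one
    hierarchical model per entry of ``drop_one``, and one covariates-plus-a-
    single-lifelog model per lifelog — each on its own complete-case sample.
    """
    unknown = [v for v in list(drop_one) + list(lifelogs) if v not in table.columns]
    if unknown:
        raise KeyError(f"unknown variables: {unknown}")

    def _hier(subset: Sequence[str]) -> HierarchicalRegressionResult:
        cols = [outcome, *covariates, *subset]
        rows, _, _ = assemble_complete_cases(table, cols)
        return hierarchical_fit(rows[outcome], rows[list(covariates)], rows[list(subset)])

    out: dict[str, HierarchicalRegressionResult | ModelFit] = {}
    out["full"] = _hier(lifelogs)
    for name in drop_one:
        subset = [v for v in lifelogs if v != name]
        out[f"drop_{name}"] = _hier(subset)
    for name in lifelogs:
        out[f"only_{name}"] = _hier([name])
    return out
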