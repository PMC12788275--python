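"""Human-readable rendering of the analysis result tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import HierarchicalRegressionResult, ModelFit

__all__ = ["significance_stars", "render_tables"]


def significance_stars(p: float) -> str:
    """Conventional significance marks: * <0.05, ** <0.01, *** <0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _fmt(x: float, nd: int = 3) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "-"
    return f"{x:.{nd}f}"


def _model_block(fit: ModelFit, title: str) -> list[str]:
    lines = [title, "-" * len(title)]
    lines.append(f"{'predictor':<22}{'B':>10}{'SE':>10}{'beta':>8}{'p':>10}{'VIF':>8}")
    for name in fit.params.index:
        beta = fit.beta.get(name, np.nan) if name != "const" else np.nan
        vif = fit.vif.get(name, np.nan) if name != "const" else np.nan
        p = fit.p[name]
        lines.append(
            f"{name:<22}{fit.params[name]:>10.4f}{fit.se[name]:>10.4f}"
            f"{_fmt(beta):>8}{_fmt(p):>8} {significance_stars(p):<3}{_fmt(vif, 2):>6}"
        )
    if fit.kind == "huber":
        lines.append(
            f"robust R^2 = {fit.r2:.3f}; Wald chi2({int(fit.f_df[0])}) = {fit.f_stat:.2f}, "
            f"p = {fit.f_p:.4f}; n = {fit.n}"
        )
    else:
        lines.append(
            f"R^2 = {fit.r2:.3f}; F({int(fit.f_df[0])}, {int(fit.f_df[1])}) = {fit.f_stat:.2f}, "
            f"p = {fit.f_p:.4f}; n = {fit.n}"
        )
    lines.append("")
    return lines


def _hier_block(res: HierarchicalRegressionResult, title: str) -> list[str]:
    lines = _model_block(res.step1, f"{title} - step 1 (clinical covariates)")
    lines += _model_block(res.step2, f"{title} - step 2 (+ digital lifelogs)")
    lines.append(
        f"delta R^2 = {res.delta_r2:.3f}; F-change({res.df_change[0]}, {res.df_change[1]}) "
        f"= {res.f_change:.2f}, p = {res.p_change:.4f} {significance_stars(res.p_change)}"
    )
    lines.append("")
    return lines


def render_tables(results) -> str:
    """Render correlations, regressions, sensitivity fits and CV as text."""
    lines: list[str] = []
    lines.append("Pearson correlations: FI vs digital lifelogs")
    lines.append("--------------------------------------------")
    lines.append(f"{'feature':<22}{'n':>5}{'r':>9}{'p':>10}{'95% CI':>20}")
    corr = results.correlations if results.correlations is not None else pd.DataFrame()
    for _, row in corr.iterrows():
        ci = f"[{row.ci_lo:.3f}, {row.ci_hi:.3f}]"
        lines.append(
            f"{row.feature:<22}{int(row.n):>5}{row.r:>9.3f}{row.p:>10.4f}"
            f" {significance_stars(row.p):<4}{ci:>16}"
        )
    lines.append("* p < 0.05, ** p < 0.01, *** p < 0.001")
    lines.append("")

    if getattr(results, "hierarchical", None) is not None:
        lines += _hier_block(results.hierarchical, "Hierarchical regression (FI outcome)")
    if getattr(results, "lifelog_only", None) is not None:
        lines += _model_block(results.lifelog_only, "Lifelog-only regression")
    if getattr(results, "kfold", None) is not None:
        mean, sd, scores = results.kfold
        lines.append(
            f"5-fold cross-validated out-of-fold R^2 = {mean:.4f} (SD = {sd:.3f}); "
            f"folds: {np.array2string(np.asarray(scores), precision=3)}"
        )
        lines.append("")
    if getattr(results, "huber", None) is not None:
        lines += _model_block(results.huber, "Huber robust regression (full design)")
    for name, fit in getattr(results, "sensitivity", {}).items():
        if name == "full":
            continue
        if isinstance(fit, HierarchicalRegressionResult):
            lines.append(
                f"sensitivity [{name}]: step-2 R^2 = {fit.step2.r2:.3f}, "
                f"F-change p = {fit.p_change:.4f}, n = {fit.step2.n}"
            )
        else:
            lines.append(f"sensitivity [{name}]: R^2 = {fit.r2:.3f}, n = {fit.n}")
    lines.append("")
    return "\n".join(lines)
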