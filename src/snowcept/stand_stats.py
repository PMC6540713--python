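"""Correlation, curve-fit and stepwise-regression surface for stand data.

These are the conventional stand-structure statistics: Pearson correlations
of throughfall/interception against canopy metrics, simple linear fits,
power-law and exponential-decay fits for event-scale relationships, forward
stepwise multiple regression with backward elimination, and class-binned
interception-efficiency summaries.

Curve fits are estimated by ordinary least squares after log transformation
(the standard log-linearisation); R2 is reported on the transformed scale.
An optional nonlinear least-squares refinement is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .errors import FitError, InputError
from .observations import MAGNITUDE_CLASSES, classify_magnitude

__all__ = [
    "FitResult",
    "CorrelationResult",
    "pearson",
    "significance_stars",
    "fit_linear",
    "fit_power",
    "fit_exp_decay",
    "stepwise_regression",
    "efficiency_by_class",
    "per_event_density_regression",
]


@dataclass(frozen=True)
class FitResult:
    """One fitted model: form label, named coefficients, R2, S_YX, p, n."""

    form: str
    coefficients: Mapping[str, float]
    r_squared: float
    s_yx: float
    p_value: float
    n: int


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation for one variable pair with star coding."""

    pair: tuple[str, str]
    r: float
    p_value: float
    stars: str
    n: int


def significance_stars(p: float) -> str:
    """Star coding: ** below 1%, * below 5%, 'n.s.' otherwise."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


def _as_xy(x: Sequence[float], y: Sequence[float], min_n: int) -> tuple[np.ndarray, np.ndarray]:
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.ndim != 1 or ya.ndim != 1 or xa.size != ya.size:
        raise InputError("x and y must be 1-d and of equal length")
    if xa.size < min_n:
        raise InputError(f"need at least {min_n} points, got {xa.size}")
    return xa, ya


def pearson(
    x: Sequence[float],
    y: Sequence[float],
    names: tuple[str, str] = ("x", "y"),
) -> CorrelationResult:
    """Sample Pearson correlation with two-sided t-test p-value."""
    xa, ya = _as_xy(x, y, 3)
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise InputError("correlation undefined for a constant vector")
    res = stats.pearsonr(xa, ya)
    r = float(res.statistic)
    p = float(res.pvalue)
    return CorrelationResult(pair=names, r=r, p_value=p, stars=significance_stars(p), n=xa.size)


def _ols_simple(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, float]:
    """OLS of y on [1, x]: (intercept, slope, r2, s_yx, slope p-value)."""
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    n = x.size
    s_yx = math.sqrt(float(fit.ssr) / (n - 2)) if n > 2 else float("nan")
    return (
        float(fit.params[0]),
        float(fit.params[1]),
        float(fit.rsquared),
        s_yx,
        float(fit.pvalues[1]),
    )


def fit_linear(x: Sequence[float], y: Sequence[float]) -> FitResult:
    """Ordinary least squares line y = intercept + slope * x."""
    xa, ya = _as_xy(x, y, 3)
    if np.ptp(xa) == 0:
        raise InputError("regression undefined for constant x")
    b0, b1, r2, s_yx, p = _ols_simple(xa, ya)
    return FitResult(
        form="linear",
        coefficients={"intercept": b0, "slope": b1},
        r_squared=r2,
        s_yx=s_yx,
        p_value=p,
        n=xa.size,
    )


def fit_power(x: Sequence[float], y: Sequence[float], refine: bool = False) -> FitResult:
    """Power law y = a * x**b, estimated by OLS on log x vs log y.

    R2 and S_YX are reported on the log scale.  With ``refine=True`` the
    log-scale estimate seeds a nonlinear least-squares fit on the original
    scale (R2 then reported on the original scale).
    """
    xa, ya = _as_xy(x, y, 3)
    if np.any(xa <= 0) or np.any(ya <= 0):
        raise InputError("power fit requires strictly positive x and y")
    lx, ly = np.log(xa), np.log(ya)
    if np.ptp(lx) == 0:
        raise InputError("regression undefined for constant x")
    b0, b1, r2, s_yx, p = _ols_simple(lx, ly)
    a, b = math.exp(b0), b1
    if refine:
        (a, b), _ = optimize.curve_fit(lambda t, a_, b_: a_ * t**b_, xa, ya, p0=(a, b))
        resid = ya - a * xa**b
        ss_tot = float(np.sum((ya - ya.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot else 1.0
        s_yx = math.sqrt(float(np.sum(resid**2)) / (xa.size - 2))
    return FitResult(
        form="power",
        coefficients={"a": float(a), "b": float(b)},
        r_squared=r2,
        s_yx=s_yx,
        p_value=p,
        n=xa.size,
    )


def fit_exp_decay(x: Sequence[float], y: Sequence[float], refine: bool = False) -> FitResult:
    """Exponential decay y = a * exp(-b * x), via OLS on x vs log y.

    b > 0 indicates decay; a constant y gives b = 0 exactly.  R2 on the
    log scale unless refined.
    """
    xa, ya = _as_xy(x, y, 3)
    if np.any(ya <= 0):
        raise InputError("exponential fit requires strictly positive y")
    if np.ptp(xa) == 0:
        raise InputError("regression undefined for constant x")
    ly = np.log(ya)
    if np.ptp(ly) == 0:
        # constant y: slope exactly 0, intercept log(y); statsmodels would
        # report an indeterminate R2
        a = float(ya[0])
        return FitResult(
            form="exp_decay",
            coefficients={"a": a, "b": 0.0},
            r_squared=1.0,
            s_yx=0.0,
            p_value=1.0,
            n=xa.size,
        )
    b0, b1, r2, s_yx, p = _ols_simple(xa, ly)
    a, b = math.exp(b0), -b1
    if refine:
        (a, b), _ = optimize.curve_fit(lambda t, a_, b_: a_ * np.exp(-b_ * t), xa, ya, p0=(a, b))
        resid = ya - a * np.exp(-b * xa)
        ss_tot = float(np.sum((ya - ya.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot else 1.0
        s_yx = math.sqrt(float(np.sum(resid**2)) / (xa.size - 2))
    return FitResult(
        form="exp_decay",
        coefficients={"a": float(a), "b": float(b)},
        r_squared=r2,
        s_yx=s_yx,
        p_value=p,
        n=xa.size,
    )


def _multi_fit(y: np.ndarray, X: pd.DataFrame) -> FitResult:
    design = sm.add_constant(X)
    fit = sm.OLS(y, design).fit()
    k = X.shape[1]
    n = y.size
    dof = n - k - 1
    s_yx = math.sqrt(float(fit.ssr) / dof) if dof > 0 else float("nan")
    coeffs = {"intercept": float(fit.params.iloc[0])}
    coeffs.update({name: float(fit.params[name]) for name in X.columns})
    p = float(fit.f_pvalue) if k > 0 and not math.isnan(fit.f_pvalue) else 1.0
    return FitResult(
        form="multiple_linear",
        coefficients=coeffs,
        r_squared=float(fit.rsquared) if k > 0 else 0.0,
        s_yx=s_yx,
        p_value=p,
        n=n,
    )


def stepwise_regression(
    y: Sequence[float],
    candidates: pd.DataFrame,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
    condition_threshold: float = 1e8,
) -> list[FitResult]:
    """Forward stepwise multiple regression with backward elimination.

    At each step the candidate with the smallest partial-F p-value below
    ``alpha_enter`` enters; any included variable whose p-value rises above
    ``alpha_remove`` is then dropped.  Returns the fitted model after every
    step, mirroring the per-step rows of a stepwise table.  With
    ``alpha_enter = 1`` every candidate eventually enters (full-model OLS);
    with ``alpha_enter = 0`` nothing enters and the intercept-only model is
    returned.  Near-collinear candidates (design condition number above
    ``condition_threshold``) are skipped with a warning.
    """
    import warnings

    if alpha_enter > alpha_remove:
        raise InputError("alpha_enter must be <= alpha_remove")
    ya = np.asarray(y, dtype=float)
    if not isinstance(candidates, pd.DataFrame):
        raise InputError("candidates must be a DataFrame with named columns")
    if ya.size != len(candidates):
        raise InputError("y and candidates must have equal length")
    if ya.size <= candidates.shape[1] + 2:
        raise InputError("need n > number of candidates + 2")

    included: list[str] = []
    remaining = list(candidates.columns)
    steps: list[FitResult] = []

    while True:
        # forward: best admissible candidate by partial-F p-value
        best_name, best_p = None, None
        for name in remaining:
            trial = included + [name]
            X = candidates[trial]
            cond = np.linalg.cond(sm.add_constant(X.to_numpy()))
            if cond > condition_threshold:
                warnings.warn(
                    f"candidate {name!r} skipped: near-collinear design "
                    f"(condition number {cond:.2g})",
                    stacklevel=2,
                )
                continue
            fit = sm.OLS(ya, sm.add_constant(X)).fit()
            p = float(fit.pvalues[name])
            if math.isnan(p):
                continue
            if best_p is None or p < best_p:
                best_name, best_p = name, p
        if best_name is None or best_p >= alpha_enter:
            break
        included.append(best_name)
        remaining.remove(best_name)

        # backward: drop anything that lost significance
        while len(included) > 1:
            fit = sm.OLS(ya, sm.add_constant(candidates[included])).fit()
            pvals = {name: float(fit.pvalues[name]) for name in included}
            worst = max(pvals, key=pvals.get)
            if pvals[worst] > alpha_remove:
                included.remove(worst)
                remaining.append(worst)
            else:
                break

        steps.append(_multi_fit(ya, candidates[included]))

    if not steps:
        steps.append(_multi_fit(ya, candidates[[]]))
    return steps


def efficiency_by_class(
    event_swe: Sequence[float],
    efficiency_pct: Sequence[float],
) -> dict[str, float]:
    """Mean stand interception efficiency per snowfall-magnitude class.

    Empty classes are absent from the result, not reported as zero.
    """
    swe, eff = _as_xy(event_swe, efficiency_pct, 1)
    out: dict[str, list[float]] = {}
    for s, e in zip(swe, eff):
        out.setdefault(classify_magnitude(float(s)), []).append(float(e))
    return {cls: float(np.mean(v)) for cls in MAGNITUDE_CLASSES if (v := out.get(cls))}


def per_event_density_regression(
    panel: pd.DataFrame,
    event_col: str = "event_id",
    density_col: str = "canopy_density_pct",
    interception_col: str = "interception_mm",
    min_troughs: int = 3,
) -> dict[str, FitResult]:
    """Per-event simple regression of trough interception on canopy density.

    One :func:`fit_linear` per event over its troughs.  Events with fewer
    than ``min_troughs`` troughs or with constant canopy density raise.
    """
    out: dict[str, FitResult] = {}
    for event_id, grp in panel.groupby(event_col, sort=False):
        if len(grp) < min_troughs:
            raise InputError(
                f"event {event_id}: {len(grp)} troughs < required {min_troughs}"
            )
        try:
            out[str(event_id)] = fit_linear(grp[density_col], grp[interception_col])
        except InputError as err:
            raise InputError(f"event {event_id}: {err}") from err
    return out
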