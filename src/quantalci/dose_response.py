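"""Sigmoid dose-response fitting and Fano-factor noise quantification.

Two sigmoid forms are used, matching how mean descriptor values are
summarized against ligand dose:

* the Hill form ``y = y_max / (1 + (ka / x)**n)`` on linear dose ``x``,
  used for experimental-style descriptor tables (EC50 = ``ka``);
* the logistic form ``y = y_max / (1 + exp(-ka * (x - x0)))`` on
  ``x = log10(dose)``, used for stochastic-simulation summaries
  (EC50 = ``10**x0``).

Cell-to-cell variability of a descriptor within a (species, dose) group is
quantified by the Fano factor, variance / mean, with groups excluded when
their mean is zero or undefined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "HillFit",
    "LogisticFit",
    "FanoResult",
    "hill",
    "logistic",
    "fit_hill",
    "fit_logistic",
    "ec50",
    "group_fano",
]


@dataclass
class HillFit:
    """Hill-equation fit ``y = y_max / (1 + (ka/x)**n)``; EC50 = ka (ng/mL)."""

    y_max: float
    ka: float
    n: float
    r2: float
    converged: bool = True
    message: str = ""

    def predict(self, x):
        return hill(np.asarray(x, dtype=float), self.y_max, self.ka, self.n)


@dataclass
class LogisticFit:
    """Logistic fit on log10 dose ``y = y_max / (1 + e^{-ka (x - x0)})``.

    ``x0`` is the log10 dose of half-maximal response, so EC50 = 10**x0.
    """

    y_max: float
    ka: float
    x0: float
    r2: float
    converged: bool = True
    message: str = ""

    def predict(self, x):
        return logistic(np.asarray(x, dtype=float), self.y_max, self.ka, self.x0)


@dataclass
class FanoResult:
    """Variance-to-mean noise of one descriptor within one group."""

    group: dict
    feature: str
    n: int
    mean: float
    variance: float
    fano: float
    excluded: bool


def hill(x, y_max, ka, n):
    return y_max / (1.0 + (ka / x) ** n)


def logistic(x, y_max, ka, x0):
    return y_max / (1.0 + np.exp(-ka * (x - x0)))


def _r2(y, yhat) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else -np.inf
    return 1.0 - ss_res / ss_tot


def fit_hill(
    doses: Sequence[float],
    mean_responses: Sequence[float],
    fix_n: float | None = None,
) -> HillFit:
    """Least-squares Hill fit to mean response vs dose.

    Parameters are bounded positive; starting points are data-driven
    (``y_max`` from the largest response, ``ka`` from the dose nearest
    half-max) with a small multi-start grid over the Hill exponent for
    robustness. ``fix_n`` pins the exponent (e.g. 1 for a hyperbolic fit).
    Non-convergence or degenerate input yields a flagged result instead of
    an exception.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(mean_responses, dtype=float)
    if x.size < 4:
        raise ValueError("at least 4 dose points are required")
    if np.any(x <= 0):
        raise ValueError("doses must be positive")
    if np.all(y == y[0]):
        return HillFit(np.nan, np.nan, np.nan, np.nan, converged=False,
                       message="constant responses: sigmoid underdetermined")

    y_max0 = float(y.max())
    if y_max0 <= 0:
        return HillFit(np.nan, np.nan, np.nan, np.nan, converged=False,
                       message="non-positive responses")
    ka0 = float(x[np.argmin(np.abs(y - y_max0 / 2.0))])

    best = None
    n_starts = [fix_n] if fix_n is not None else [0.5, 1.0, 2.0, 4.0]
    for n0 in n_starts:
        try:
            if fix_n is not None:
                popt, _ = curve_fit(
                    lambda xx, ym, ka: hill(xx, ym, ka, fix_n),
                    x, y, p0=[y_max0, ka0],
                    bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=20000,
                )
                params = (popt[0], popt[1], fix_n)
            else:
                popt, _ = curve_fit(
                    hill, x, y, p0=[y_max0, ka0, n0],
                    bounds=([1e-12, 1e-12, 1e-12], [np.inf, np.inf, np.inf]),
                    maxfev=20000,
                )
                params = tuple(popt)
        except RuntimeError:
            continue
        r2 = _r2(y, hill(x, *params))
        if best is None or r2 > best[1]:
            best = (params, r2)
    if best is None:
        return HillFit(np.nan, np.nan, np.nan, np.nan, converged=False,
                       message="curve_fit failed to converge from all starts")
    (y_max, ka, n), r2 = best
    return HillFit(float(y_max), float(ka), float(n), float(r2))


def fit_logistic(
    log10_doses: Sequence[float], mean_responses: Sequence[float]
) -> LogisticFit:
    """Least-squares logistic fit to mean response vs log10 dose."""
    x = np.asarray(log10_doses, dtype=float)
    y = np.asarray(mean_responses, dtype=float)
    if x.size < 4:
        raise ValueError("at least 4 points are required")
    if np.all(y == y[0]):
        return LogisticFit(np.nan, np.nan, np.nan, np.nan, converged=False,
                           message="constant responses: sigmoid underdetermined")
    y_max0 = float(y.max())
    if y_max0 <= 0:
        return LogisticFit(np.nan, np.nan, np.nan, np.nan, converged=False,
                           message="non-positive responses")
    x00 = float(x[np.argmin(np.abs(y - y_max0 / 2.0))])
    span = max(x.max() - x.min(), 1e-6)
    best = None
    for ka0 in (0.5 / span, 2.0 / span, 2.0, 8.0):
        try:
            popt, _ = curve_fit(
                logistic, x, y, p0=[y_max0, ka0, x00],
                bounds=([1e-12, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        r2 = _r2(y, logistic(x, *popt))
        if best is None or r2 > best[1]:
            best = (tuple(popt), r2)
    if best is None:
        return LogisticFit(np.nan, np.nan, np.nan, np.nan, converged=False,
                           message="curve_fit failed to converge from all starts")
    (y_max, ka, x0), r2 = best
    return LogisticFit(float(y_max), float(ka), float(x0), float(r2))


def ec50(fit: HillFit | LogisticFit) -> float:
    """Half-maximal dose in ng/mL: ``ka`` (Hill) or ``10**x0`` (logistic)."""
    if not fit.converged:
        raise ValueError(f"cannot extract EC50 from an unconverged fit: {fit.message}")
    if isinstance(fit, HillFit):
        return fit.ka
    return float(10.0 ** fit.x0)


def group_fano(
    descriptor_table: pd.DataFrame,
    group_keys: Sequence[str],
    feature: str,
) -> list[FanoResult]:
    """Fano factor (sample variance / mean, ddof=1) per group.

    Groups whose mean is zero or undefined (empty, or all-NaN feature
    values) are reported with ``excluded=True`` and NaN fano.
    """
    if feature not in descriptor_table.columns:
        raise KeyError(f"feature column {feature!r} not in table")
    results = []
    for key, sub in descriptor_table.groupby(list(group_keys), sort=True, dropna=False):
        if not isinstance(key, tuple):
            key = (key,)
        vals = sub[feature].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        n = vals.size
        if n == 0:
            results.append(FanoResult(dict(zip(group_keys, key)), feature,
                                      0, np.nan, np.nan, np.nan, True))
            continue
        mean = float(vals.mean())
        var = float(vals.var(ddof=1)) if n > 1 else 0.0
        excluded = (mean == 0.0) or not np.isfinite(mean)
        fano = var / mean if not excluded else np.nan
        results.append(FanoResult(dict(zip(group_keys, key)), feature,
                                  n, mean, var, fano, excluded))
    return results
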