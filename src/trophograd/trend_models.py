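"""Gradient trend fitting (linear vs quadratic, AIC-selected) and
standardized multiple OLS with AIC-based subset selection.

AIC uses the full Gaussian form n*ln(RSS/n) + n*ln(2*pi) + n + 2k
(statsmodels' convention, k counting the mean parameters), so values are
comparable across modules; selection depends only on AIC differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class TrendFit:
    model: str                      # 'linear' or 'quadratic'
    coefficients: np.ndarray        # intercept first, then gradient powers
    R2: float
    AIC: float
    p_overall: float
    significant: bool
    aic_linear: float
    aic_quadratic: float
    predict: Callable[[np.ndarray], pd.DataFrame] = field(repr=False, default=None)

    @property
    def vertex(self) -> float | None:
        """Stationary point of the quadratic fit (None for linear)."""
        if self.model != "quadratic" or self.coefficients[2] == 0:
            return None
        return float(-self.coefficients[1] / (2.0 * self.coefficients[2]))


@dataclass
class RegressionFit:
    response: str
    terms: list[str]
    beta: pd.Series                 # standardized coefficients, no intercept
    R2: float
    AIC: float
    pvalues: pd.Series


def _design(g: np.ndarray, order: int) -> np.ndarray:
    cols = [np.ones_like(g)] + [g**p for p in range(1, order + 1)]
    return np.column_stack(cols)


def fit_gradient_trend(y, g) -> TrendFit:
    """Fit y ~ g and y ~ g + g^2 by OLS; return the lower-AIC model with a
    95% prediction-interval function."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    if len(y) != len(g):
        raise ValueError("y and g must have equal length")
    if len(y) < 5:
        raise ValueError("need at least 5 observations")
    if np.ptp(g) == 0:
        raise ValueError("constant gradient")
    if np.ptp(y) == 0:
        # flat response: both candidates reduce to the intercept-only model
        mean = float(y[0])

        def predict_flat(g_new: np.ndarray) -> pd.DataFrame:
            g_new = np.atleast_1d(np.asarray(g_new, dtype=float))
            return pd.DataFrame({"gradient": g_new, "fit": mean,
                                 "pi_low": mean, "pi_high": mean})

        return TrendFit(model="linear", coefficients=np.array([mean, 0.0]),
                        R2=0.0, AIC=-np.inf, p_overall=1.0, significant=False,
                        aic_linear=-np.inf, aic_quadratic=-np.inf,
                        predict=predict_flat)

    fits = {}
    for name, order in (("linear", 1), ("quadratic", 2)):
        fits[name] = sm.OLS(y, _design(g, order)).fit()
    chosen = "linear" if fits["linear"].aic <= fits["quadratic"].aic else "quadratic"
    fit = fits[chosen]
    order = 1 if chosen == "linear" else 2

    def predict(g_new: np.ndarray) -> pd.DataFrame:
        g_new = np.atleast_1d(np.asarray(g_new, dtype=float))
        pred = fit.get_prediction(_design(g_new, order))
        frame = pred.summary_frame(alpha=0.05)
        return pd.DataFrame({
            "gradient": g_new, "fit": frame["mean"].to_numpy(),
            "pi_low": frame["obs_ci_lower"].to_numpy(),
            "pi_high": frame["obs_ci_upper"].to_numpy()})

    p_overall = float(fit.f_pvalue) if np.isfinite(fit.f_pvalue) else 1.0
    return TrendFit(
        model=chosen, coefficients=np.asarray(fit.params),
        R2=float(fit.rsquared), AIC=float(fit.aic), p_overall=p_overall,
        significant=p_overall <= 0.05,
        aic_linear=float(fits["linear"].aic),
        aic_quadratic=float(fits["quadratic"].aic),
        predict=predict)


def standardize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant column cannot be standardized")
    return (x - x.mean()) / sd


def _fit_subset(yz: np.ndarray, xz: pd.DataFrame, cols: Sequence[str]):
    design = sm.add_constant(xz[list(cols)].to_numpy())
    return sm.OLS(yz, design).fit()


def ols_best_subset(y, X: pd.DataFrame, response: str = "y",
                    max_exhaustive: int = 10) -> RegressionFit:
    """AIC-minimizing OLS over predictor subsets on standardized variables.

    Exhaustive search for p <= ``max_exhaustive`` predictors, otherwise
    backward elimination.  Standardized coefficients are beta weights.
    """
    y = np.asarray(y, dtype=float)
    p = X.shape[1]
    if len(y) <= p + 2:
        raise ValueError("need n > p + 2 observations")
    xz = X.apply(lambda c: standardize(c.to_numpy()))
    cond = np.linalg.cond(xz.to_numpy())
    if cond > 1e10:
        raise ValueError(
            f"collinear candidate predictors (condition number {cond:.2e}); "
            "prune with VIF first")
    yz = standardize(y)

    names = list(X.columns)
    if p <= max_exhaustive:
        best_cols, best_fit, best_aic = None, None, np.inf
        for k in range(1, p + 1):
            for cols in combinations(names, k):
                fit = _fit_subset(yz, xz, cols)
                if fit.aic < best_aic:
                    best_cols, best_fit, best_aic = list(cols), fit, fit.aic
    else:
        cols = list(names)
        best_fit = _fit_subset(yz, xz, cols)
        improved = True
        while improved and len(cols) > 1:
            improved = False
            for c in list(cols):
                trial = [x for x in cols if x != c]
                fit = _fit_subset(yz, xz, trial)
                if fit.aic < best_fit.aic:
                    cols, best_fit, improved = trial, fit, True
                    break
        best_cols = cols

    beta = pd.Series(best_fit.params[1:], index=best_cols)
    pvals = pd.Series(best_fit.pvalues[1:], index=best_cols)
    return RegressionFit(response=response, terms=best_cols, beta=beta,
                         R2=float(best_fit.rsquared), AIC=float(best_fit.aic),
                         pvalues=pvals)
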