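"""Closed-form simple linear regression, prediction and prediction errors.

All models in this package are univariate (trait on PRS, or Y on X), so the
fit uses the textbook normal equations rather than a general design-matrix
solver:

    beta1 = Cov(x, y) / Var(x),      beta0 = mean(y) - beta1 * mean(x),

with the slope standard error, t statistic and two-sided p-value from the
t distribution on n - 2 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["FitResult", "fit_simple_ols", "predict", "prediction_errors", "format_pvalue"]

#: Below this, reports print the conventional "< 2.00E-16" floor.
PVALUE_FLOOR = 2.0e-16


@dataclass
class FitResult:
    """Simple-regression fit: coefficients, inference and residuals."""

    beta0: float
    beta1: float
    se_beta1: float
    t_stat: float
    pvalue: float
    r_squared: float
    residuals: np.ndarray
    fitted: np.ndarray
    n: int

    def summary_row(self) -> dict:
        """Effect size / SE / p-value / R-squared, as reported in tables."""
        return {
            "effect_size": self.beta1,
            "standard_error": self.se_beta1,
            "p_value": format_pvalue(self.pvalue),
            "r_squared": self.r_squared,
        }


def format_pvalue(p: float, floor: float = PVALUE_FLOOR) -> str:
    """Report-style p-value: values below the floor print as '< 2.00E-16'."""
    if p < floor:
        return f"<{floor:.2E}"
    return f"{p:.2E}"


def fit_simple_ols(x: np.ndarray, y: np.ndarray) -> FitResult:
    """Fit ``y = beta0 + beta1 * x`` by ordinary least squares.

    Raises
    ------
    ValueError
        If fewer than 3 observations, if ``x`` is constant, or if either
        input contains NaN (the message names the first offending index).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of identical length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    for name, v in (("x", x), ("y", y)):
        nan = np.flatnonzero(np.isnan(v))
        if nan.size:
            raise ValueError(f"NaN in {name} at index {nan[0]}")

    xbar = x.mean()
    ybar = y.mean()
    dx = x - xbar
    sxx = float(dx @ dx)
    if sxx == 0.0:
        raise ValueError("x is constant; slope is undefined")
    sxy = float(dx @ (y - ybar))

    beta1 = sxy / sxx
    beta0 = ybar - beta1 * xbar
    fitted = beta0 + beta1 * x
    residuals = y - fitted
    rss = float(residuals @ residuals)
    tss = float((y - ybar) @ (y - ybar))
    r_squared = 1.0 - rss / tss if tss > 0 else 1.0

    df = n - 2
    sigma2 = rss / df
    se_beta1 = float(np.sqrt(sigma2 / sxx))
    if se_beta1 > 0:
        t_stat = beta1 / se_beta1
        pvalue = float(2.0 * stats.t.sf(abs(t_stat), df))
    else:  # perfect fit
        t_stat = np.inf if beta1 != 0 else 0.0
        pvalue = 0.0 if beta1 != 0 else 1.0

    return FitResult(
        beta0=beta0,
        beta1=beta1,
        se_beta1=se_beta1,
        t_stat=t_stat,
        pvalue=pvalue,
        r_squared=r_squared,
        residuals=residuals,
        fitted=fitted,
        n=n,
    )


def predict(fit: FitResult, x_new: np.ndarray) -> np.ndarray:
    """Predicted response ``beta0 + beta1 * x_new``, elementwise."""
    return fit.beta0 + fit.beta1 * np.asarray(x_new, dtype=float)


def prediction_errors(y: np.ndarray, y_hat: np.ndarray) -> np.ndarray:
    """Per-observation prediction error ``y - y_hat``."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError(f"length mismatch: y has {y.shape}, y_hat has {y_hat.shape}")
    return y - y_hat
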