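"""Heteroscedasticity tests for a simple-regression fit.

All three tests share one auxiliary regression: the squared residuals of the
fit (suitably scaled) regressed, with intercept, on the fitted values.  For a
univariate model the fitted values are an affine function of the predictor,
and every statistic below depends on the auxiliary regressor only through its
R-squared, which is affine-invariant — so regressing on x gives identical
results.

breusch_pagan
    The original Breusch–Pagan Lagrange-multiplier statistic.  With
    ``g_i = e_i^2 / (RSS/n)``, the statistic is half the explained sum of
    squares of the auxiliary regression of g; chi-squared on 1 df.  Exact
    under normal errors; over-rejects when the error kurtosis exceeds 3.
score_test
    Koenker's studentized score statistic ``n * R2_aux`` from the auxiliary
    regression of the raw squared residuals; chi-squared on 1 df.  Robust to
    non-normal errors.
f_test
    The F form of the same auxiliary regression:
    ``F = R2_aux / ((1 - R2_aux)/(n - 2))`` on (1, n-2) df.

All p-values are upper-tail.  On homoscedastic data with normal errors the
score and F p-values agree closely; the Breusch–Pagan statistic is at least
as large as the score statistic whenever the sample kurtosis of the
residuals exceeds 3, which is why severely heteroscedastic data show
BP >= score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .ols import FitResult

__all__ = [
    "HeteroTestResult",
    "breusch_pagan",
    "score_test",
    "f_test",
    "all_tests",
    "bonferroni_threshold",
]


@dataclass
class HeteroTestResult:
    """Outcome of one heteroscedasticity test."""

    test: str  # breusch_pagan | score | f
    statistic: float
    df: tuple[int, Optional[int]]  # (numerator df, denominator df or None)
    pvalue: float

    def as_row(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "df": self.df[0] if self.df[1] is None else list(self.df),
            "p_value": self.pvalue,
        }


def _aux_r2_and_tss(fit: FitResult) -> tuple[float, float, float]:
    """R-squared, total SS and n of the auxiliary regression of e^2 on fitted.

    Returns (r2_aux, tss_e2, n).  A perfect primary fit (all residuals zero)
    yields r2_aux = 0 with a warning: there is no residual variation to test.
    """
    e2 = fit.residuals**2
    n = fit.n
    if float(e2.sum()) == 0.0:
        warnings.warn(
            "perfect fit: residual sum of squares is zero, "
            "heteroscedasticity statistic defined as 0",
            RuntimeWarning,
            stacklevel=3,
        )
        return 0.0, 0.0, n
    z = fit.fitted
    dz = z - z.mean()
    szz = float(dz @ dz)
    de2 = e2 - e2.mean()
    tss = float(de2 @ de2)
    if szz == 0.0 or tss == 0.0:
        # constant regressor or constant squared residuals: no association
        return 0.0, tss, n
    slope = float(dz @ de2) / szz
    ess = slope * slope * szz
    return ess / tss, tss, n


def breusch_pagan(fit: FitResult, x: Optional[np.ndarray] = None) -> HeteroTestResult:
    """Original Breusch–Pagan LM test: half the explained sum of squares of
    the auxiliary regression of ``e^2 / (RSS/n)`` on the fitted values.

    ``x`` is accepted for interface symmetry; the statistic is identical for
    any affine transform of the auxiliary regressor, so it is unused.
    """
    if fit.n < 4:
        raise ValueError(f"need at least 4 observations, got {fit.n}")
    r2_aux, tss_e2, n = _aux_r2_and_tss(fit)
    sigma2_hat = float(fit.residuals @ fit.residuals) / n
    if sigma2_hat == 0.0:
        stat = 0.0
    else:
        # ESS of the regression of g = e^2/sigma2_hat is ESS(e^2)/sigma2_hat^2
        stat = r2_aux * tss_e2 / (sigma2_hat**2) / 2.0
    return HeteroTestResult("breusch_pagan", stat, (1, None), float(stats.chi2.sf(stat, 1)))


def score_test(fit: FitResult, x: Optional[np.ndarray] = None) -> HeteroTestResult:
    """Koenker's studentized score test: ``n * R2`` of the auxiliary regression."""
    if fit.n < 4:
        raise ValueError(f"need at least 4 observations, got {fit.n}")
    r2_aux, _, n = _aux_r2_and_tss(fit)
    stat = n * r2_aux
    return HeteroTestResult("score", stat, (1, None), float(stats.chi2.sf(stat, 1)))


def f_test(fit: FitResult, x: Optional[np.ndarray] = None) -> HeteroTestResult:
    """F form of the auxiliary regression, on (1, n-2) degrees of freedom."""
    if fit.n < 4:
        raise ValueError(f"need at least 4 observations, got {fit.n}")
    r2_aux, _, n = _aux_r2_and_tss(fit)
    df_den = n - 2
    if r2_aux >= 1.0:
        stat = np.inf
    else:
        stat = (r2_aux / 1.0) / ((1.0 - r2_aux) / df_den)
    return HeteroTestResult("f", float(stat), (1, df_den), float(stats.f.sf(stat, 1, df_den)))


def all_tests(fit: FitResult) -> dict[str, HeteroTestResult]:
    """All three tests on one fit, keyed by test name."""
    return {
        "breusch_pagan": breusch_pagan(fit),
        "score": score_test(fit),
        "f": f_test(fit),
    }


def bonferroni_threshold(alpha: float, k: int) -> float:
    """Family-wise error threshold ``alpha / k`` for k hypotheses."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1); got {alpha}")
    if k < 1:
        raise ValueError(f"k must be a positive integer; got {k}")
    return alpha / k
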