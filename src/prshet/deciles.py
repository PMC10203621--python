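"""Decile stratification by predictor and decile-based diagnostics.

Observations are ranked by the predictor (PRS or X) and cut into ten
contiguous groups G1 (smallest) .. G10 (largest).  Heteroscedasticity of a
fitted model is then summarised by two scalars:

* the G10/G1 ratio of mean absolute residuals, computed on the modeling set
  (close to 1 under homoscedasticity, and growing with the severity of the
  variance trend), and
* the G10/G1 ratio of validation-set error rates, where the error rate of a
  decile is the fraction of prediction errors lying more than one pooled
  standard deviation from the pooled mean error.

The pooled mean and SD are taken over the whole validation set, not per
decile: centering and scaling within deciles would mechanically flatten
exactly the signal these diagnostics are meant to expose.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "DecileProfile",
    "decile_groups",
    "residual_variance_by_decile",
    "mean_abs_residual_by_decile",
    "mean_abs_residual_ratio",
    "error_rate_by_decile",
    "error_rate_ratio",
    "profile",
]

N_GROUPS = 10


def decile_groups(x: np.ndarray) -> np.ndarray:
    """Assign each observation to a decile group of ``x``.

    Returns integer labels 1..10 aligned to the input order.  Observations
    are sorted ascending (stable, so ties keep input order) and cut into 10
    contiguous groups; when n is not a multiple of 10 the larger groups come
    first, so sizes are ``ceil(n/10)`` for the first ``n mod 10`` groups and
    ``floor(n/10)`` for the rest.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < N_GROUPS:
        raise ValueError(f"need at least {N_GROUPS} observations, got {n}")
    order = np.argsort(x, kind="stable")
    base, rem = divmod(n, N_GROUPS)
    sizes = np.full(N_GROUPS, base, dtype=int)
    sizes[:rem] += 1
    labels = np.empty(n, dtype=int)
    labels[order] = np.repeat(np.arange(1, N_GROUPS + 1), sizes)
    return labels


def _per_decile(values: np.ndarray, labels: np.ndarray, func, min_size: int = 1) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have identical length")
    out = np.full(N_GROUPS, np.nan)
    for g in range(1, N_GROUPS + 1):
        v = values[labels == g]
        if v.size >= min_size:
            out[g - 1] = func(v)
    return out


def decile_counts(labels: np.ndarray) -> np.ndarray:
    """Group sizes of G1..G10."""
    labels = np.asarray(labels)
    return np.array([(labels == g).sum() for g in range(1, N_GROUPS + 1)])


def residual_variance_by_decile(residuals: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Sample variance (denominator n_g - 1) of residuals within each decile.

    A decile with fewer than 2 members has undefined variance, reported NaN.
    """
    return _per_decile(residuals, labels, lambda v: float(np.var(v, ddof=1)), min_size=2)


def mean_abs_residual_by_decile(residuals: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Mean absolute residual within each decile."""
    return _per_decile(residuals, labels, lambda v: float(np.mean(np.abs(v))))


def mean_abs_residual_ratio(residuals: np.ndarray, labels: np.ndarray) -> float:
    """G10/G1 ratio of mean absolute residuals.

    Scale-invariant (multiplying all residuals by c > 0 leaves it unchanged)
    and approximately 1 for a homoscedastic fit.
    """
    m = mean_abs_residual_by_decile(residuals, labels)
    if not m[0] > 0:
        raise ValueError(
            "mean absolute residual in G1 is zero: degenerate fit, ratio undefined"
        )
    return float(m[-1] / m[0])


def error_rate_by_decile(errors: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-decile fraction of errors more than 1 pooled SD from the pooled mean.

    The mean and SD pool over *all* supplied errors (the whole validation
    set).  If the pooled SD is zero every rate is 0, with a warning.
    """
    errors = np.asarray(errors, dtype=float)
    mu = errors.mean()
    s = errors.std(ddof=1) if errors.size > 1 else 0.0
    if s == 0.0:
        warnings.warn(
            "pooled SD of errors is zero; all error rates reported as 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.zeros(N_GROUPS)
    outside = (np.abs(errors - mu) > s).astype(float)
    return _per_decile(outside, labels, lambda v: float(np.mean(v)))


def error_rate_ratio(rates: np.ndarray) -> float:
    """G10/G1 ratio of error rates; NaN when the G1 rate is zero."""
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (N_GROUPS,):
        raise ValueError(f"expected {N_GROUPS} per-decile rates")
    if not rates[0] > 0:
        return float("nan")
    return float(rates[-1] / rates[0])


@dataclass
class DecileProfile:
    """Per-decile diagnostics plus the two G10/G1 summary ratios."""

    labels: np.ndarray
    counts: np.ndarray
    resid_variance: np.ndarray
    mean_abs_resid: np.ndarray
    ratio_abs_resid: float
    error_rate: Optional[np.ndarray] = None
    ratio_error_rate: Optional[float] = None

    def table(self) -> "object":
        """Per-decile table (pandas DataFrame): decile, n, variance, |resid|, rate."""
        import pandas as pd

        d = {
            "decile": [f"G{g}" for g in range(1, N_GROUPS + 1)],
            "n": self.counts,
            "resid_variance": self.resid_variance,
            "mean_abs_resid": self.mean_abs_resid,
        }
        if self.error_rate is not None:
            d["error_rate"] = self.error_rate
        return pd.DataFrame(d)

    def summary(self) -> dict:
        out = {"ratio_abs_resid": self.ratio_abs_resid}
        if self.ratio_error_rate is not None:
            out["ratio_error_rate"] = self.ratio_error_rate
        return out


def profile(
    x: np.ndarray,
    residuals: np.ndarray,
    errors: Optional[np.ndarray] = None,
    error_x: Optional[np.ndarray] = None,
) -> DecileProfile:
    """Full decile profile of a fit.

    Residual diagnostics (variance, mean |residual|, their G10/G1 ratio) are
    computed on ``(x, residuals)`` — the modeling set.  If validation-set
    prediction errors are supplied, per-decile error rates use decile
    boundaries recomputed from ``error_x`` (the validation predictor).
    """
    labels = decile_groups(x)
    rates = None
    rate_ratio = None
    if errors is not None:
        if error_x is None:
            raise ValueError("error_x is required when errors are supplied")
        err_labels = decile_groups(error_x)
        rates = error_rate_by_decile(errors, err_labels)
        rate_ratio = error_rate_ratio(rates)
    return DecileProfile(
        labels=labels,
        counts=decile_counts(labels),
        resid_variance=residual_variance_by_decile(residuals, labels),
        mean_abs_resid=mean_abs_residual_by_decile(residuals, labels),
        ratio_abs_resid=mean_abs_residual_ratio(residuals, labels),
        error_rate=rates,
        ratio_error_rate=rate_ratio,
    )
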