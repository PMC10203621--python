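"""Heteroscedastic simulation scenarios for a simple linear regression.

Twelve canonical scenarios cross four variance regimes with three signal
strengths.  Each scenario generates

    Y_i = beta0 + beta1 * X_i + e_i,     e_i ~ Normal(0, sigma_i^2),
    sigma_i = a * X_i + b,               X_i = 1, 2, ..., n,

so the residual standard deviation is an affine function of the predictor.
The four regimes are:

HS0
    homoscedastic, ``a = 0``: constant residual SD ``b``.
HS1 / HS2
    mild / moderate heteroscedasticity: ``a > 0`` and ``b > 0``.
HS3
    severe heteroscedasticity, ``b = 0``: SD proportional to X.

Within each regime, three (a, b) pairs place the ordinary-least-squares
R-squared near 0.9, 0.5 and 0.1 at n = 2000.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "LEVELS",
    "ScenarioSpec",
    "LabeledDataset",
    "scenario_table",
    "generate",
    "split",
]

LEVELS = ("HS0", "HS1", "HS2", "HS3")

MODELING = "modeling"
VALIDATION = "validation"


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation scenario: variance regime plus generative coefficients.

    Parameters
    ----------
    level
        Variance regime, one of ``HS0``–``HS3``.
    r2_target
        Nominal R-squared the (a, b) pair was chosen for (0.9, 0.5 or 0.1).
        Informational: the realised R-squared is a function of (a, b, n).
    n
        Number of observations; the predictor is the sequence ``1..n``.
    beta0, beta1
        Intercept and slope of the mean model.
    a, b
        Slope and intercept of the residual-SD function ``sigma_i = a*X_i + b``.
    """

    level: str
    r2_target: float
    a: float
    b: float
    n: int = 2000
    beta0: float = 0.5
    beta1: float = 0.5

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}; expected one of {LEVELS}")
        if self.n < 1:
            raise ValueError("n must be a positive integer")
        if self.a < 0 or self.b < 0:
            raise ValueError("sigma coefficients a, b must be non-negative")
        if self.level == "HS0" and self.a != 0:
            raise ValueError("HS0 requires a = 0 (constant residual SD)")
        if self.level == "HS3" and self.b != 0:
            raise ValueError("HS3 requires b = 0 (SD proportional to X)")

    def sigma(self, x: np.ndarray) -> np.ndarray:
        """Residual SD at each predictor value: ``a*x + b``."""
        return self.a * np.asarray(x, dtype=float) + self.b

    def with_n(self, n: int) -> "ScenarioSpec":
        """Same variance regime and coefficients at a different sample size."""
        return replace(self, n=n)

    @property
    def name(self) -> str:
        return f"{self.level}/{self.r2_target:g}"


@dataclass
class LabeledDataset:
    """Paired predictor/response vectors with an optional modeling/validation split."""

    x: np.ndarray
    y: np.ndarray
    partition: Optional[np.ndarray] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of identical length")
        if self.x.size < 2:
            raise ValueError("need at least 2 observations")
        if self.partition is not None:
            self.partition = np.asarray(self.partition, dtype=object)
            if self.partition.shape != self.x.shape:
                raise ValueError("partition length must match x")
            labels = set(self.partition.tolist())
            if labels != {MODELING, VALIDATION}:
                raise ValueError(
                    f"partition must contain both labels "
                    f"{{{MODELING!r}, {VALIDATION!r}}}; got {sorted(map(str, labels))}"
                )

    @property
    def n(self) -> int:
        return self.x.size

    def subset(self, label: str) -> "LabeledDataset":
        """Rows carrying the given partition label, as an unpartitioned dataset."""
        if self.partition is None:
            raise ValueError("dataset has no partition")
        mask = self.partition == label
        return LabeledDataset(self.x[mask], self.y[mask], seed=self.seed)

    @property
    def modeling(self) -> "LabeledDataset":
        return self.subset(MODELING)

    @property
    def validation(self) -> "LabeledDataset":
        return self.subset(VALIDATION)


# The 12 canonical (a, b) pairs, by regime and nominal R-squared.
_CANONICAL = {
    "HS0": {0.9: (0.0, 55.0), 0.5: (0.0, 285.0), 0.1: (0.0, 800.0)},
    "HS1": {0.9: (0.04, 60.0), 0.5: (0.09, 190.0), 0.1: (0.3, 500.0)},
    "HS2": {0.9: (0.05, 40.0), 0.5: (0.15, 130.0), 0.1: (0.5, 300.0)},
    "HS3": {0.9: (0.08, 0.0), 0.5: (0.25, 0.0), 0.1: (0.8, 0.0)},
}


def scenario_table() -> list[ScenarioSpec]:
    """The 12 canonical scenarios, ordered HS0..HS3 and, within a regime,
    by decreasing nominal R-squared (0.9, 0.5, 0.1)."""
    return [
        ScenarioSpec(level, r2, a=a, b=b)
        for level in LEVELS
        for r2, (a, b) in _CANONICAL[level].items()
    ]


def get_scenario(level: str, r2_target: float) -> ScenarioSpec:
    """Look up one canonical scenario by regime and nominal R-squared."""
    try:
        a, b = _CANONICAL[level][r2_target]
    except KeyError:
        raise KeyError(
            f"no canonical scenario {level}/{r2_target}; levels are {LEVELS} "
            "and r2 targets are 0.9, 0.5, 0.1"
        ) from None
    return ScenarioSpec(level, r2_target, a=a, b=b)


def generate(spec: ScenarioSpec, seed: int) -> LabeledDataset:
    """Draw one dataset from a scenario.

    The predictor is the fixed integer sequence ``1..n`` (each value once);
    only the residuals are random.  Identical ``(spec, seed)`` always yields
    the identical dataset.
    """
    x = np.arange(1, spec.n + 1, dtype=float)
    sigma = spec.sigma(x)
    bad = np.flatnonzero(sigma <= 0)
    if bad.size:
        raise ValueError(
            f"residual SD a*X+b is non-positive at index {bad[0]} "
            f"(X={x[bad[0]]:g}, sigma={sigma[bad[0]]:g}); "
            "a degenerate zero-variance scenario cannot be generated"
        )
    rng = np.random.default_rng(seed)
    e = rng.normal(0.0, sigma)
    y = spec.beta0 + spec.beta1 * x + e
    return LabeledDataset(x, y, seed=seed)


def split(ds: LabeledDataset, modeling_fraction: float, seed: int) -> LabeledDataset:
    """Randomly assign each row to the modeling or validation set.

    The modeling set gets ``round(fraction * n)`` rows chosen by a seeded
    uniform permutation; the split is disjoint and exhaustive, and identical
    ``(ds, fraction, seed)`` always reproduces the same partition.
    """
    if not 0.0 < modeling_fraction < 1.0:
        raise ValueError(f"modeling_fraction must be in (0, 1); got {modeling_fraction}")
    if ds.partition is not None:
        raise ValueError("dataset is already partitioned")
    n = ds.n
    # both labels must occur, so clamp the rounded size away from 0 and n
    n_model = min(max(int(round(modeling_fraction * n)), 1), n - 1)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    partition = np.empty(n, dtype=object)
    partition[order[:n_model]] = MODELING
    partition[order[n_model:]] = VALIDATION
    return LabeledDataset(ds.x, ds.y, partition=partition, seed=ds.seed)
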