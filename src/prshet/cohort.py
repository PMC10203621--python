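"""Synthetic PRS-cohort generation: genotypes -> weighted-sum PRS -> trait.

The generator emulates a biobank-style polygenic-score analysis without any
real data: independent biallelic variants are drawn binomially from random
allele frequencies, a polygenic risk score is the weighted sum of effect
allele counts

    PRS_j = sum_i  b_i * x_ij ,

and a quantitative trait is linear in the standardized score z with a
residual standard deviation that itself rises linearly in z:

    Y_j = beta0 + beta1 * z_j + eps_j,   eps_j ~ Normal(0, sigma(z_j)^2),
    sigma(z) = max(b + a * z, sigma_floor).

With a = 0 the cohort is homoscedastic.  With a > 0 the top PRS decile has
larger prediction errors than the bottom decile, which is the phenomenon the
diagnostics in this package quantify.  ``calibrate_variance`` inverts the
closed-form normal-decile moments so a requested model R-squared and
G10/G1 mean-absolute-residual ratio are hit by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats

__all__ = [
    "WeightTable",
    "GenotypeMatrix",
    "CohortSpec",
    "simulate_genotypes",
    "simulate_weights",
    "score_prs",
    "harmonize_direction",
    "standardize",
    "simulate_trait",
    "calibrate_variance",
    "filter_outliers",
    "generate_cohort",
]

logger = logging.getLogger(__name__)

_ALLELES = frozenset("ACGT")
#: |E[Z | Z in extreme decile]| for Z ~ Normal(0,1): phi(z_0.9)/0.1
NORMAL_DECILE_MEAN = float(stats.norm.pdf(stats.norm.ppf(0.9)) / 0.1)
#: E|Z| for Z ~ Normal(0,1)
HALF_NORMAL_MEAN = float(np.sqrt(2.0 / np.pi))


@dataclass
class WeightTable:
    """Per-variant scoring weights: id, effect allele, other allele, weight."""

    variant_id: np.ndarray
    effect_allele: np.ndarray
    other_allele: np.ndarray
    effect_weight: np.ndarray

    def __post_init__(self) -> None:
        self.variant_id = np.asarray(self.variant_id, dtype=object)
        self.effect_allele = np.asarray(self.effect_allele, dtype=object)
        self.other_allele = np.asarray(self.other_allele, dtype=object)
        self.effect_weight = np.asarray(self.effect_weight, dtype=float)
        m = self.variant_id.size
        if not (self.effect_allele.size == self.other_allele.size == self.effect_weight.size == m):
            raise ValueError("all weight-table columns must have equal length")
        if len(set(self.variant_id.tolist())) != m:
            raise ValueError("variant ids must be unique")
        for i in range(m):
            ea, oa = self.effect_allele[i], self.other_allele[i]
            if ea == oa:
                raise ValueError(
                    f"variant {self.variant_id[i]}: effect and other allele are both {ea!r}"
                )

    @property
    def m(self) -> int:
        return self.variant_id.size

    def is_strand_ambiguous(self) -> np.ndarray:
        """A/T and C/G variants, whose strand cannot be resolved from alleles."""
        pairs = {frozenset(("A", "T")), frozenset(("C", "G"))}
        return np.array(
            [frozenset((e, o)) in pairs for e, o in zip(self.effect_allele, self.other_allele)]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rsID": self.variant_id,
                "effect_allele": self.effect_allele,
                "other_allele": self.other_allele,
                "effect_weight": self.effect_weight,
            }
        )


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix of counted-allele copies in [0, 2].

    ``counted_allele`` names the allele each column's dosages count; NaN
    entries are missing calls.
    """

    dosages: np.ndarray
    variant_id: np.ndarray
    counted_allele: Optional[np.ndarray] = None
    other_allele: Optional[np.ndarray] = None
    sample_id: Optional[np.ndarray] = None
    freq: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D samples x variants array")
        self.variant_id = np.asarray(self.variant_id, dtype=object)
        if self.variant_id.size != self.dosages.shape[1]:
            raise ValueError("variant ids must match the number of columns")
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("dosages must lie within [0, 2]")
        if self.sample_id is None:
            self.sample_id = np.array(
                [f"S{j + 1}" for j in range(self.dosages.shape[0])], dtype=object
            )

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]


@dataclass(frozen=True)
class CohortSpec:
    """Design of one synthetic PRS cohort.

    ``a``, ``b`` and ``beta1`` may be left None, in which case they are
    calibrated from ``r2_target`` and ``ratio_target`` (see
    :func:`calibrate_variance`).  ``outlier_rate`` injects gross trait
    outliers to exercise the quartile fence filter.
    """

    n: int = 100_000
    m: int = 200
    freq_range: tuple[float, float] = (0.05, 0.95)
    beta0: float = 0.0
    beta1: Optional[float] = None
    a: Optional[float] = None
    b: Optional[float] = None
    sigma_floor: float = 0.05
    r2_target: float = 0.05
    ratio_target: float = 1.5
    outlier_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_floor <= 0:
            raise ValueError("sigma_floor must be positive")
        if not 0.0 < self.r2_target < 1.0:
            raise ValueError(f"target R-squared must be in (0, 1); got {self.r2_target}")
        if self.ratio_target < 1.0:
            raise ValueError(f"target G10/G1 ratio must be >= 1; got {self.ratio_target}")
        if not 0.0 <= self.outlier_rate < 1.0:
            raise ValueError("outlier_rate must be in [0, 1)")

    def sigma(self, z: np.ndarray) -> np.ndarray:
        if self.a is None or self.b is None:
            raise ValueError("variance coefficients not set; calibrate first")
        return np.maximum(self.b + self.a * np.asarray(z, dtype=float), self.sigma_floor)

    def calibrated(self) -> "CohortSpec":
        """Fill in (a, b, beta1) from the targets if not already set."""
        if self.a is not None and self.b is not None and self.beta1 is not None:
            return self
        a, b, beta1 = calibrate_variance(self)
        return replace(self, a=a, b=b, beta1=beta1)


# -- genotype and weight simulation ------------------------------------------

_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("C", "T"), ("G", "T")]  # non-ambiguous


def simulate_genotypes(spec: CohortSpec, seed: int) -> GenotypeMatrix:
    """Independent biallelic variants: per-variant frequency p_i drawn
    uniformly from ``spec.freq_range``, dosages Binomial(2, p_i)."""
    if spec.m < 1:
        raise ValueError(f"need at least 1 variant; got m={spec.m}")
    if spec.n < 2:
        raise ValueError(f"need at least 2 samples; got n={spec.n}")
    lo, hi = spec.freq_range
    if not (0.01 <= lo < hi <= 0.99):
        raise ValueError(
            f"allele-frequency range must satisfy 0.01 <= low < high <= 0.99; got ({lo}, {hi})"
        )
    rng = np.random.default_rng(seed)
    p = rng.uniform(lo, hi, size=spec.m)
    dosages = rng.binomial(2, p, size=(spec.n, spec.m)).astype(float)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=spec.m)
    counted = np.array([_ALLELE_PAIRS[k][0] for k in pair_idx], dtype=object)
    other = np.array([_ALLELE_PAIRS[k][1] for k in pair_idx], dtype=object)
    ids = np.array([f"rs{100000 + i}" for i in range(spec.m)], dtype=object)
    return GenotypeMatrix(dosages, ids, counted_allele=counted, other_allele=other, freq=p)


def simulate_weights(g: GenotypeMatrix, seed: int, scale: Optional[float] = None) -> WeightTable:
    """Random effect weights aligned to a genotype matrix.

    Weights are Normal(0, scale^2) with scale defaulting to 1/sqrt(m), so the
    raw PRS has variance of order one; the effect allele is the matrix's
    counted allele, making the pair directly scorable.
    """
    rng = np.random.default_rng(seed)
    if scale is None:
        scale = 1.0 / np.sqrt(g.m)
    w = rng.normal(0.0, scale, size=g.m)
    counted = g.counted_allele if g.counted_allele is not None else np.array(["A"] * g.m, dtype=object)
    other = g.other_allele if g.other_allele is not None else np.array(["G"] * g.m, dtype=object)
    return WeightTable(g.variant_id.copy(), counted.copy(), other.copy(), w)


# -- scoring ------------------------------------------------------------------


def score_prs(
    g: GenotypeMatrix,
    w: WeightTable,
    missing: str = "drop",
    require_effect_orientation: bool = False,
) -> np.ndarray:
    """Weighted-sum polygenic score ``PRS_j = sum_i b_i x_ij`` per sample.

    Every weight-table variant must be present in the matrix, and the
    matrix's allele pair must match the weight's pair (same two alleles);
    violations raise with the offending ids.  Orientation (which of the two
    alleles the matrix counts) does not change the arithmetic — direction is
    carried by the sign of the weight, which is what
    :func:`harmonize_direction` manipulates; pass
    ``require_effect_orientation=True`` to insist that the counted allele be
    the effect allele exactly.  Strand-ambiguous (A/T, C/G) variants score
    normally but are counted in a log message.

    Missing dosages (NaN): ``missing="drop"`` omits that variant's term for
    that sample (logged); ``missing="mean"`` imputes the variant's mean
    dosage over non-missing samples.
    """
    if missing not in ("drop", "mean"):
        raise ValueError(f"missing policy must be 'drop' or 'mean'; got {missing!r}")
    col = {vid: j for j, vid in enumerate(g.variant_id)}
    absent = [vid for vid in w.variant_id if vid not in col]
    if absent:
        raise KeyError(f"variants absent from genotype matrix: {absent}")
    idx = np.array([col[vid] for vid in w.variant_id])

    if g.counted_allele is not None:
        counted = g.counted_allele[idx]
        other = g.other_allele[idx] if g.other_allele is not None else None
        for k in range(w.m):
            pair_w = {w.effect_allele[k], w.other_allele[k]}
            pair_g = {counted[k]} if other is None else {counted[k], other[k]}
            if not pair_g <= pair_w:
                raise ValueError(
                    f"allele mismatch for variant {w.variant_id[k]}: matrix counts "
                    f"{counted[k]!r} but the weight table has "
                    f"{w.effect_allele[k]}/{w.other_allele[k]}"
                )
            if require_effect_orientation and counted[k] != w.effect_allele[k]:
                raise ValueError(
                    f"variant {w.variant_id[k]}: matrix counts {counted[k]!r}, "
                    f"not the effect allele {w.effect_allele[k]!r}"
                )

    n_ambig = int(w.is_strand_ambiguous().sum())
    if n_ambig:
        logger.info("scoring includes %d strand-ambiguous (A/T or C/G) variants", n_ambig)

    x = g.dosages[:, idx]
    mask = np.isnan(x)
    if mask.any():
        n_miss = int(mask.sum())
        if missing == "mean":
            col_mean = np.nanmean(x, axis=0)
            x = np.where(mask, col_mean[None, :], x)
            logger.info("mean-imputed %d missing genotype calls", n_miss)
        else:
            x = np.where(mask, 0.0, x)
            logger.info("dropped %d missing genotype calls from the score", n_miss)
    return x @ w.effect_weight


def harmonize_direction(w: WeightTable) -> WeightTable:
    """Swap effect/other alleles and negate every weight.

    Scoring with the result is the elementwise negation of scoring with the
    input; applying it twice returns the original table.  Used to unify the
    direction of effect for traits where lower values indicate risk (in the
    source design, the FEV1/FVC ratio).
    """
    return WeightTable(
        w.variant_id.copy(),
        w.other_allele.copy(),
        w.effect_allele.copy(),
        -w.effect_weight,
    )


def standardize(prs: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Z-score ``prs`` by the mean and SD (ddof=1) of ``reference``.

    Standardizing a vector by itself yields mean 0 and SD 1.  In the
    split-sample pipeline the reference is always the modeling set, so
    validation scores are standardized without leakage.
    """
    reference = np.asarray(reference, dtype=float)
    mu = reference.mean()
    sd = reference.std(ddof=1) if reference.size > 1 else 0.0
    if sd == 0.0:
        raise ValueError("reference PRS has zero variance; cannot standardize")
    return (np.asarray(prs, dtype=float) - mu) / sd


# -- trait simulation and calibration ----------------------------------------


def simulate_trait(z: np.ndarray, spec: CohortSpec, seed: int) -> np.ndarray:
    """Trait values ``Y = beta0 + beta1*z + eps`` with SD(eps) = sigma(z).

    With ``spec.outlier_rate > 0`` a random fraction of samples is displaced
    by 8-12 pooled SDs (random sign) to mimic gross phenotype outliers.
    """
    spec = spec.calibrated()
    z = np.asarray(z, dtype=float)
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, spec.sigma(z))
    y = spec.beta0 + spec.beta1 * z + eps
    if spec.outlier_rate > 0:
        k = int(round(spec.outlier_rate * z.size))
        if k:
            idx = rng.choice(z.size, size=k, replace=False)
            scale = y.std(ddof=1)
            shift = rng.uniform(8.0, 12.0, size=k) * rng.choice([-1.0, 1.0], size=k)
            y[idx] = y.mean() + shift * scale
    return y


def _decile_mean_sigma(a: float, b: float, floor: float, decile: int) -> float:
    """E[max(b + a Z, floor) | Z in decile g] for Z ~ Normal(0,1), by quadrature."""
    lo = stats.norm.ppf((decile - 1) / 10.0) if decile > 1 else -np.inf
    hi = stats.norm.ppf(decile / 10.0) if decile < 10 else np.inf
    val, _ = integrate.quad(
        lambda t: max(b + a * t, floor) * stats.norm.pdf(t), lo, hi, limit=200
    )
    return val / 0.1


def _expected_sigma2(a: float, b: float, floor: float) -> float:
    """E[sigma(Z)^2] for Z ~ Normal(0,1)."""
    val, _ = integrate.quad(
        lambda t: max(b + a * t, floor) ** 2 * stats.norm.pdf(t), -np.inf, np.inf, limit=200
    )
    return val


def expected_abs_resid_ratio(a: float, b: float, floor: float) -> float:
    """Large-n expectation of the G10/G1 mean-absolute-residual ratio.

    Within a decile the residual is Normal(0, sigma(z)^2) given z, so the
    mean absolute residual is sqrt(2/pi) * E[sigma(Z) | decile]; the constant
    cancels in the ratio.
    """
    return _decile_mean_sigma(a, b, floor, 10) / _decile_mean_sigma(a, b, floor, 1)


def calibrate_variance(spec: CohortSpec) -> tuple[float, float, float]:
    """Solve (a, b, beta1) hitting ``spec.r2_target`` and ``spec.ratio_target``.

    The residual-SD intercept is fixed at b = 1 (the trait's residual scale
    at the mean PRS; the two targets are scale-free).  The SD slope ``a`` is
    found by root-finding the closed-form decile expectation of the ratio,
    and ``beta1`` then sets the signal so that
    ``R2 = beta1^2 / (beta1^2 + E[sigma(Z)^2])`` equals the target exactly.

    Raises
    ------
    ValueError
        If the requested ratio is infeasible: attaining it would push the
        bottom-decile SD at or below ``sigma_floor``, where the floor—not
        the linear trend—controls the ratio.
    """
    b = 1.0
    floor = spec.sigma_floor
    if floor >= b:
        raise ValueError(
            f"sigma_floor={floor} must be below the SD intercept b={b}"
        )
    target = spec.ratio_target
    if target == 1.0:
        a = 0.0
    else:
        # beyond a_max the G1 decile-mean SD dips to the floor and the linear
        # variance trend no longer controls the ratio
        a_max = (b - floor) / NORMAL_DECILE_MEAN
        attainable = expected_abs_resid_ratio(a_max, b, floor)
        if target > attainable:
            raise ValueError(
                f"G10/G1 ratio {target} is infeasible with sigma_floor={floor}: "
                f"the largest attainable ratio before the bottom decile hits the "
                f"floor is {attainable:.3f}"
            )
        a = optimize.brentq(
            lambda aa: expected_abs_resid_ratio(aa, b, floor) - target, 0.0, a_max
        )
    r2 = spec.r2_target
    beta1 = float(np.sqrt(r2 / (1.0 - r2) * _expected_sigma2(a, b, floor)))
    return float(a), b, beta1


# -- phenotype outlier filter --------------------------------------------------


def filter_outliers(y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, float, float]:
    """Quartile-fence phenotype filter.

    Removes values strictly below ``Q1 - 3*IQR`` or strictly above
    ``Q3 + 3*IQR``, with quartiles by linear interpolation between order
    statistics.  Returns ``(kept_idx, removed_idx, q1, q3, iqr)``; kept and
    removed indices partition the input.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 4:
        raise ValueError(f"need at least 4 values to form quartile fences; got {y.size}")
    q1, q3 = np.percentile(y, [25.0, 75.0])
    iqr = q3 - q1
    lo, hi = q1 - 3.0 * iqr, q3 + 3.0 * iqr
    removed = np.flatnonzero((y < lo) | (y > hi))
    kept = np.flatnonzero((y >= lo) & (y <= hi))
    return kept, removed, float(q1), float(q3), float(iqr)


# -- end-to-end cohort ---------------------------------------------------------


def generate_cohort(spec: CohortSpec, seed: int) -> pd.DataFrame:
    """Genotypes -> weights -> PRS -> standardized PRS -> trait, as a table.

    Columns: ``id``, ``prs`` (raw weighted sum), ``z`` (PRS standardized by
    the whole cohort, for generation only) and ``trait``.  Downstream
    analyses re-standardize on the modeling set.
    """
    spec = spec.calibrated()
    root = np.random.SeedSequence(seed)
    s_geno, s_w, s_trait = (int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(3))
    g = simulate_genotypes(spec, s_geno)
    w = simulate_weights(g, s_w)
    prs = score_prs(g, w)
    z = standardize(prs, prs)
    y = simulate_trait(z, spec, s_trait)
    return pd.DataFrame({"id": g.sample_id, "prs": prs, "z": z, "trait": y})
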