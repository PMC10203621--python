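# Methods

## The problem and the model

A polygenic risk score for individual *j* is the weighted sum of effect
allele counts over *m* variants, PRSⱼ = Σᵢ b̂ᵢ·xᵢⱼ, and trait prediction uses
the univariate linear model Ŷ = β₀ + β₁·PRS fitted by ordinary least
squares.  OLS point estimates stay unbiased under heteroscedasticity, but
prediction *accuracy* does not: when the residual standard deviation rises
with the score, individuals in the top score decile have systematically
larger prediction errors than the model's average error suggests.  This
package simulates that regime, tests for it, and quantifies it.

## Simulation scenarios

Each scenario draws

    Yᵢ = β₀ + β₁·Xᵢ + eᵢ,   eᵢ ~ Normal(0, σᵢ²),   σᵢ = a·Xᵢ + b,

with β₀ = β₁ = 0.5 and Xᵢ the fixed integer grid 1..n (n = 2000 by
default; each value occurs exactly once, no resampling of X).  The twelve
canonical (a, b) pairs are, per regime and nominal R²:

| regime | R²≈0.9 | R²≈0.5 | R²≈0.1 |
|---|---|---|---|
| HS0 (a=0) | (0, 55) | (0, 285) | (0, 800) |
| HS1 | (0.04, 60) | (0.09, 190) | (0.3, 500) |
| HS2 | (0.05, 40) | (0.15, 130) | (0.5, 300) |
| HS3 (b=0) | (0.08, 0) | (0.25, 0) | (0.8, 0) |

The notation N(0, (a·Xᵢ+b)²) is read as normal with *standard deviation*
a·Xᵢ+b, consistent with the homoscedastic rows.  The nominal R² labels are
design targets, not guarantees: analytically
R² = β₁²·Var(X)/(β₁²·Var(X)+E[σ²]) with Var(X) = (n²−1)/12, which gives
≈0.506 for HS0/(0, 285) but ≈0.965 for HS0/(0, 55) — the high-signal
homoscedastic label of 0.9 is approximate, and we deliberately do not
adjust the coefficients to force it.

Generation is deterministic given (spec, seed): one `numpy` Generator per
`generate`/`split` call, seeds recorded in outputs.  The simulation study
splits 50/50 (modeling/validation); the cohort pipeline defaults to 80/20.
Both are flags.

## Heteroscedasticity tests

All three tests derive from one auxiliary regression of the squared
residuals on the fitted values (with intercept).  For a univariate model
the fitted values are affine in x, and each statistic depends on the
auxiliary regressor only through the auxiliary R², which is
affine-invariant — so regressing on x or on Ŷ is equivalent (asserted
numerically in the tests).

- **Breusch–Pagan (original LM)**: with gᵢ = eᵢ²/(RSS/n), the statistic is
  ESS_aux(g)/2, χ² on 1 df.  Exact under normal errors; inflates when the
  error kurtosis exceeds 3 — which variance-mixing by x produces by
  construction, hence BP ≥ score on heteroscedastic data.
- **Score (Koenker's studentized form)**: n·R²_aux from the regression of
  raw e², χ² on 1 df.  Robust to non-normal errors.  Some descriptions
  label this a likelihood-ratio comparison of a variance-augmented model;
  the implemented statistic is the standard studentized score form, which
  reproduces the score ≈ F ≤ BP pattern seen in practice.
- **F test**: R²_aux/((1−R²_aux)/(n−2)) on (1, n−2) df; asymptotically
  equivalent to the score test (their p-values agree to <0.02 on null data
  at n = 1000, tested).

Degenerate inputs: a perfect primary fit (RSS = 0) returns statistic 0,
p = 1 with a warning rather than an error.  All p-values are upper-tail.
Multiple testing across traits uses plain Bonferroni α/k (0.05/15 in the
15-trait design); a study is flagged heteroscedastic only when **all
three** tests fall below the threshold (a config option relaxes to "any").

## Decile diagnostics

Observations are ranked by predictor and cut into ten contiguous groups,
larger groups first when n is not a multiple of 10, ties stable in input
order.  Reported per decile: count, sample residual variance (ddof 1,
missing when a decile has <2 members), mean |residual|, and on the
validation set the fraction of prediction errors more than one pooled SD
from the pooled mean error.  Two scalars summarise a model:
ratio_abs_resid = mean|resid|(G10)/mean|resid|(G1), computed on modeling
residuals, and ratio_error_rate = rate(G10)/rate(G1) on validation errors.

Two deliberate choices: the error-rate mean and SD pool over the whole
validation set (per-decile centering would mechanically erase the signal),
and validation decile boundaries are recomputed from validation predictor
values (a flag allows reusing modeling-set boundaries).  Under severe
heteroscedasticity the bottom decile's error rate can be exactly zero — its
σ is a small fraction of the pooled SD — in which case the error-rate ratio
is honestly reported as missing rather than infinite.

For a homoscedastic model the per-decile error rate converges to
2·Φ(−1) ≈ 31.7%, the normal mass outside ±1 SD; this is the calibration
check the test suite enforces at n = 10⁵ (±2%).  Note that simulated
error-rate *ranges* under heteroscedasticity are sensitive to which SD is
used in the rule; figures quoted elsewhere that pool differently can
disagree with the normal-tail expectation, so this package documents its
pooling convention and tests against the analytic oracle only.

## Synthetic PRS cohort

Genotypes are independent biallelic variants, dosages Binomial(2, pᵢ) with
pᵢ uniform on (0.05, 0.95) by default (respecting a MAF ≥ 0.01 floor); a
weighted sum over m = 200 variants is approximately normal (|skewness| <
0.1 at n = 10⁴, tested), matching the empirical normality of real PRS
distributions.  The trait model on the standardized score z is

    Yⱼ = β₀ + β₁·zⱼ + εⱼ,   εⱼ ~ Normal(0, σ(z)²),   σ(z) = max(b + a·z, σ_floor).

The linear-in-z SD is a modelling choice: real-data analyses establish only
that residual spread rises monotonically with the score, and the affine
form mirrors the simulation module's σ = a·X + b.  The floor σ_floor > 0
(default 0.05·b) keeps the variance positive in the far-left tail.

**Calibration.**  With b fixed at 1 (the residual scale at the mean score;
both targets are scale-free), the expected G10/G1 mean-absolute-residual
ratio is E[σ(Z)|top decile]/E[σ(Z)|bottom decile] for Z ~ N(0,1) — within a
decile the residual is centred normal, so mean|ε| = √(2/π)·E[σ] and the
constant cancels.  The decile-conditional expectations are computed by
quadrature (the unfloored closed form uses the decile mean
φ(z₀.₉)/0.1 ≈ 1.755), and `a` is found by Brent root-finding.  A requested
ratio is rejected as infeasible when reaching it would push the
bottom-decile SD to the floor, where the floor rather than the linear trend
controls the ratio.  Then β₁ = √(R²/(1−R²)·E[σ(Z)²]) hits the target R²
exactly in expectation.  Parameter recovery at n = 10⁵ is within ±0.01 (R²)
and ±5% (ratio), tested.

**What the generator does and does not emulate.**  It reproduces the
features the diagnostics depend on: normally distributed standardized
scores, trait linear in the score with R² in the 0.02–0.13 range observed
for real PRS-trait fits, residual SD rising linearly so the G10/G1 ratio
spans ≈1.0–1.6, and gross phenotype outliers (optional injection) for the
quartile-fence filter.  It does not model linkage disequilibrium, GWAS
estimation noise in the weights, covariates (age, sex, ancestry), or
non-normal trait scales — so passing tests demonstrate correctness of the
diagnostics under the stated generative model, not robustness to every
real-data pathology.  The default 15-trait panel pairs ten heteroscedastic
traits (ratios 1.07–1.53) with five homoscedastic ones, providing a known
truth for end-to-end discovery tests.

**Scoring conventions.**  Scoring requires every weight-table variant in
the matrix and the matrix's allele pair to match the weight's pair; foreign
alleles are hard errors naming the variant.  Direction is carried by the
sign of the weight: `harmonize_direction` swaps effect/other alleles and
negates the weights, so scoring the harmonized table is the exact negation
of the original — the mechanism for unifying effect direction across traits
where lower values indicate risk.  A strict flag additionally requires the
counted allele to *be* the effect allele.  Strand-ambiguous (A/T, C/G)
variants are accepted but logged.  Missing calls drop that variant's term
for that sample (logged); mean imputation is available behind a flag.

**Phenotype filter.**  Values strictly outside [Q1 − 3·IQR, Q3 + 3·IQR] are
removed, with quartiles by linear interpolation between order statistics
(the default convention in mainstream statistical environments; the rule's
source names no method).  On normal data the fences remove <10⁻³ of the
sample and a second pass is effectively idempotent.

## Standardization and leakage

PRS standardization moments (mean, SD with ddof 1) come from the modeling
set only and are reused for the validation set, so validation z-scores do
not have exactly zero mean — the deliberate no-leakage convention.

## Problem sizes and tolerances

The default test run uses the study's own sizes where the checks are about
reported numbers (n = 2000 scenarios; 100–200 Monte-Carlo seeds for ratio
and slope summaries; 2000 null seeds for test size; 500 seeds per scenario
for power; n = 10⁵ for the error-rate law and calibration recovery) and a
scaled-down cohort panel (n = 4×10⁴, m = 50 variants) for the routine
end-to-end discovery test, whose power margins are large (score statistic
≈ n·2δ², two orders of magnitude above the χ²₁ threshold at both sizes).
OLS agrees with the normal-equation reference to 10⁻⁸ relative error and
the three tests with an independent reference implementation to 10⁻⁶, on
random inputs.

## Known limitations

- Only univariate (single-predictor) fits: the PRS prediction models under
  study are univariate, and no covariate adjustment is offered.
- Only the affine variance shapes σ = a·X + b and σ(z) = max(b+a·z, floor);
  no quadratic or step alternatives, no White or Goldfeld–Quandt tests, and
  no heteroscedasticity-consistent standard errors — the package diagnoses,
  it does not remedy.
- The single-seed slope band 0.47–0.55 quoted for the 12-scenario table is
  a property of one particular draw: for the low-signal scenarios the
  slope's sampling SD is ≈0.05 (the printed standard errors), so ~40% of
  fresh draws fall outside that band; only the Monte-Carlo mean (0.50 ±
  0.01) is a stable reproduction target.
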