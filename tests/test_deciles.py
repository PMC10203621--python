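"""Decile stratification and the G10/G1 residual and error-rate diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import prshet as ph
from prshet.deciles import decile_counts
from tests.conftest import run_scenario


def test_even_split_labels():
    labels = ph.decile_groups(np.arange(1.0, 21.0))
    np.testing.assert_array_equal(labels, np.repeat(np.arange(1, 11), 2))


def test_remainder_goes_to_lower_deciles():
    labels = ph.decile_groups(np.arange(25.0))
    np.testing.assert_array_equal(decile_counts(labels), [3, 3, 3, 3, 3, 2, 2, 2, 2, 2])


def test_ties_are_stable_and_small_n_rejected():
    labels = ph.decile_groups(np.zeros(10))
    np.testing.assert_array_equal(labels, np.arange(1, 11))  # input order kept
    with pytest.raises(ValueError):
        ph.decile_groups(np.arange(9.0))


@settings(derandomize=True, max_examples=30, deadline=None)
@given(n=st.integers(min_value=10, max_value=500), seed=st.integers(0, 2**31 - 1))
def test_decile_groups_partition_every_input(n, seed):
    x = np.random.default_rng(seed).normal(size=n)
    labels = ph.decile_groups(x)
    counts = decile_counts(labels)
    assert counts.sum() == n and counts.max() - counts.min() <= 1
    # groups are contiguous in x: every value in G10 >= every value in G1
    assert x[labels == 10].min() >= x[labels == 1].max()


def test_variance_by_decile_zero_within_groups():
    x = np.arange(1.0, 21.0)
    labels = ph.decile_groups(x)
    v = ph.residual_variance_by_decile(labels.astype(float), labels)
    np.testing.assert_allclose(v, 0.0)


def test_homoscedastic_variance_flat_at_large_n(rng):
    e = rng.normal(size=100_000)
    v = ph.residual_variance_by_decile(e, ph.decile_groups(rng.normal(size=100_000)))
    assert v.max() / v.min() < 1.1


def test_hs3_variance_strictly_increasing():
    """sigma^2 grows as X^2, so decile variances rise in all 9 steps."""
    spec = ph.get_scenario("HS3", 0.5).with_n(10_000)
    d = ph.generate(spec, 3)
    e = d.y - 0.5 - 0.5 * d.x
    v = ph.residual_variance_by_decile(e, ph.decile_groups(d.x))
    assert bool(np.all(np.diff(v) > 0))


def test_abs_residual_ratio_unit_and_degenerate():
    labels = ph.decile_groups(np.arange(20.0))
    assert ph.mean_abs_residual_ratio(np.ones(20), labels) == pytest.approx(1.0)
    with pytest.raises(ValueError, match="G1"):
        bad = np.ones(20)
        bad[labels == 1] = 0.0
        ph.mean_abs_residual_ratio(bad, labels)


@settings(derandomize=True, max_examples=20, deadline=None)
@given(c=st.floats(min_value=1e-3, max_value=1e3), seed=st.integers(0, 2**31 - 1))
def test_abs_residual_ratio_scale_invariant(c, seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=100)
    e = rng.normal(size=100) * (1 + np.abs(x))
    labels = ph.decile_groups(x)
    r1 = ph.mean_abs_residual_ratio(e, labels)
    r2 = ph.mean_abs_residual_ratio(c * e, labels)
    assert r2 == pytest.approx(r1, rel=1e-9)


def test_hs0_ratio_near_one():
    """Homoscedastic scenarios: ratio in [0.85, 1.15] across seeds."""
    hits = 0
    for seed in range(20):
        for r2 in (0.9, 0.5, 0.1):
            d, fit = run_scenario(ph.get_scenario("HS0", r2), 700 + seed)
            labels = ph.decile_groups(d.modeling.x)
            if 0.85 <= ph.mean_abs_residual_ratio(fit.residuals, labels) <= 1.15:
                hits += 1
    assert hits >= 0.9 * 60


def test_hs1_ratio_matches_analytic_expectation():
    """MC mean ~ (a*xbar_G10 + b)/(a*xbar_G1 + b) = 361/199 for HS1 medium."""
    spec = ph.get_scenario("HS1", 0.5)
    vals = []
    for seed in range(60):
        d, fit = run_scenario(spec, 1500 + seed)
        vals.append(ph.mean_abs_residual_ratio(fit.residuals, ph.decile_groups(d.modeling.x)))
    assert np.mean(vals) == pytest.approx(361.0 / 199.0, rel=0.05)


def test_error_rate_normal_tail_mass(rng):
    """Pooled +-1 SD rule on standard normal errors: rate ~ 2*Phi(-1)."""
    e = rng.normal(size=200_000)
    rates = ph.error_rate_by_decile(e, ph.decile_groups(rng.normal(size=200_000)))
    np.testing.assert_allclose(rates, 2 * stats.norm.cdf(-1), atol=0.01)


def test_error_rate_degenerate_zero_sd():
    labels = ph.decile_groups(np.arange(20.0))
    with pytest.warns(RuntimeWarning, match="zero"):
        rates = ph.error_rate_by_decile(np.full(20, 3.0), labels)
    np.testing.assert_array_equal(rates, 0.0)


def test_error_rate_rises_with_decile_under_heteroscedasticity(hs3_medium):
    d = ph.split(ph.generate(hs3_medium.with_n(20_000), 11), 0.5, 12)
    fit = ph.fit_simple_ols(d.modeling.x, d.modeling.y)
    err = ph.prediction_errors(d.validation.y, ph.predict(fit, d.validation.x))
    rates = ph.error_rate_by_decile(err, ph.decile_groups(d.validation.x))
    assert rates[-1] > rates[0]
    assert stats.spearmanr(np.arange(10), rates).statistic > 0.8


def test_error_rate_ratio_arithmetic():
    rates = np.full(10, 0.1)
    rates[-1] = 0.4
    assert ph.error_rate_ratio(rates) == pytest.approx(4.0)
    rates[0] = 0.0
    assert np.isnan(ph.error_rate_ratio(rates))


def test_profile_combines_modeling_and_validation(rng):
    # moderate heteroscedasticity so every decile's error rate is nonzero
    # and the error-rate ratio is defined
    spec = ph.CohortSpec(ratio_target=1.5, r2_target=0.05).calibrated()
    z = rng.standard_normal(40_000)
    y = ph.simulate_trait(z, spec, 13)
    d = ph.split(ph.LabeledDataset(z, y), 0.5, 14)
    fit = ph.fit_simple_ols(d.modeling.x, d.modeling.y)
    err = ph.prediction_errors(d.validation.y, ph.predict(fit, d.validation.x))
    prof = ph.profile(d.modeling.x, fit.residuals, errors=err, error_x=d.validation.x)
    assert prof.counts.sum() == d.modeling.n
    assert prof.ratio_abs_resid == pytest.approx(1.5, rel=0.15)
    assert prof.ratio_error_rate is not None and prof.ratio_error_rate > 1
    tab = prof.table()
    assert list(tab["decile"]) == [f"G{g}" for g in range(1, 11)]


def test_severe_heteroscedasticity_error_ratio_undefined(hs3_medium):
    """When the bottom decile's sigma is tiny relative to the pooled SD its
    error rate is zero, and the G10/G1 error-rate ratio reports NaN."""
    d = ph.split(ph.generate(hs3_medium, 9), 0.5, 10)
    fit = ph.fit_simple_ols(d.modeling.x, d.modeling.y)
    err = ph.prediction_errors(d.validation.y, ph.predict(fit, d.validation.x))
    prof = ph.profile(d.modeling.x, fit.residuals, errors=err, error_x=d.validation.x)
    assert prof.error_rate[0] == 0.0
    assert np.isnan(prof.ratio_error_rate)
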