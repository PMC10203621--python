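import numpy as np
import pytest

import prshet as ph


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def hs0_medium():
    """Canonical homoscedastic scenario with medium signal (sigma = 285)."""
    return ph.get_scenario("HS0", 0.5)


@pytest.fixture
def hs3_medium():
    """Canonical severe-heteroscedasticity scenario (sigma_i = 0.25 X_i)."""
    return ph.get_scenario("HS3", 0.5)


def run_scenario(spec, seed, fraction=0.5):
    """generate -> split -> fit on the modeling half; returns (data, fit)."""
    data = ph.split(ph.generate(spec, seed), fraction, seed + 1_000_003)
    fit = ph.fit_simple_ols(data.modeling.x, data.modeling.y)
    return data, fit
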