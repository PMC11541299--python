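import numpy as np
import pytest

from micsim.grm import default_item_parameters
from micsim.simulate import DesignPoint, simulate_sample


@pytest.fixture(scope="session")
def params():
    return default_item_parameters()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def baseline_design():
    """Middle-of-the-road design cell without present-state bias."""
    return DesignPoint(theta1_mean=0.0, delta_sd=1.0, cor_theta1_delta=0.0,
                       prop_improved=0.5, tr_reliability=0.5, psb_mean=0.0)


@pytest.fixture(scope="session")
def baseline_sample(params, baseline_design):
    return simulate_sample(baseline_design, params, rng=42, conversion_n=100_000)


@pytest.fixture(scope="session")
def psb_sample(params):
    """A complete-PSB sample from the same seed family."""
    design = DesignPoint(theta1_mean=0.0, delta_sd=1.0, cor_theta1_delta=0.0,
                         prop_improved=0.5, tr_reliability=0.5, psb_mean=1.0)
    return simulate_sample(design, params, rng=43, conversion_n=100_000)
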