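import numpy as np
import pytest

from gutphage import DEFAULT_PARAMETERS, PopulationState
from gutphage.synthetic import generate_calibration_bundle


@pytest.fixture(scope="session")
def params():
    """Calibrated gut parameter set (package default)."""
    return DEFAULT_PARAMETERS


@pytest.fixture(scope="session")
def equal_start():
    """1:1 gavage state: L0 = S0 = 1e6 cfu/g, no phage."""
    return PopulationState(S=1e6, L=1e6)


@pytest.fixture(scope="session")
def noiseless_bundle(params):
    """Noiseless mono + LamB- + wt-competition datasets from the default set."""
    return generate_calibration_bundle(params, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
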