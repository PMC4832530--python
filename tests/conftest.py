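import numpy as np
import pytest

from gazeprior import GazeObserver, default_model


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def spec_observer():
    """Observer used in the worked examples: prior 10 deg, clean noise 2 deg,
    noisy sensory sd 8 deg at contrast 0.6 (gain 10)."""
    return GazeObserver(prior_sd_deg=10.0, clean_sensory_sd_deg=2.0, noise_gain=10.0)


@pytest.fixture(scope="session")
def psi_model():
    return default_model()
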