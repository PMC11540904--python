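import numpy as np
import pytest

from flimfret import DecayParams, ScenarioConfig


@pytest.fixture
def truth_params() -> DecayParams:
    """Canonical two-state sensor parameters used across tests."""
    return DecayParams.two_state(0.3, tau_d=2.6, tau_ad=1.1, tau_g=0.2, t0=2.0)


@pytest.fixture
def default_config() -> ScenarioConfig:
    return ScenarioConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20241009)
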