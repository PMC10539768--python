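import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dosyres as dr

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def quinine_design():
    """The experiment design of the quinine demonstration: quadratic ramp,
    N=12 gradients from 12.5 to 52.8 G/cm, deepest exponent 0.76."""
    kappa = 12.5 / 52.8
    return dr.epsilon_schedule("quadratic", 12, kappa, 0.76)


@pytest.fixture(scope="session")
def quinine_seq():
    """Rectangular encoding, 1 ms net gradient pulse, 0.16 s diffusion delay."""
    return dr.PulseSequence(delta=1e-3, Delta=0.16)


@pytest.fixture(scope="session")
def linear_params():
    return dr.shape_params("linear")


@pytest.fixture(scope="session")
def quadratic_params():
    return dr.shape_params("quadratic")
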