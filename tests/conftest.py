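import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import bsmap
from bsmap import pulses

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def optimized_pulse():
    """The published 3.5 ms Fermi sensitizing pulse at 1 us sampling."""
    return bsmap.optimized_fermi_pulse()


@pytest.fixture(scope="session")
def btilde(optimized_pulse):
    return pulses.normalized_squared_integral(optimized_pulse)


@pytest.fixture(scope="session")
def model_2khz(btilde):
    return bsmap.BSPhaseModel(b_tilde=btilde, omega_rf=2000.0)


@pytest.fixture(scope="session")
def loop_coil():
    from bsmap import phantom

    return phantom.LoopCoil(radius=0.05, reference_point=(0.0, 0.0, 0.10),
                            reference_gamma_b1=1000.0)
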