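import numpy as np
import pytest

from rimdyn.io_core import Anthropometry
from rimdyn.synthetic import SimParams, simulate_propulsion
from rimdyn.upperlimb_model import SegmentInertia


@pytest.fixture(scope="session")
def clean_params():
    return SimParams(noise_sd_marker=0.0, noise_sd_force=0.0)


@pytest.fixture(scope="session")
def clean_trial(clean_params):
    """Noise-free trial: 5.2 s at cadence 1.25 -> six pushes, five cycles."""
    return simulate_propulsion(clean_params, 5.2)


@pytest.fixture(scope="session")
def clean_trial_240():
    """Noise-free trial with markers already on the kinetic clock."""
    p = SimParams(noise_sd_marker=0.0, noise_sd_force=0.0, marker_rate=240.0)
    return simulate_propulsion(p, 5.2)


@pytest.fixture(scope="session")
def noisy_trial():
    return simulate_propulsion(SimParams(seed=7), 5.2)


@pytest.fixture(scope="session")
def inertia(clean_params):
    return SegmentInertia.from_anthropometry(clean_params.anthropometry)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
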