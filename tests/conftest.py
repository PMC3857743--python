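import numpy as np
import pytest
from hypothesis import settings

from spikestab.network import GainFunction, NetworkSpec
from spikestab.synth import make_trial_table

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def gain_through(value, slope, at=0.5, theta=0.5):
    """Naka-Rushton gain with prescribed value and slope at ``at``."""
    c = slope * (theta + at) ** 2 / theta
    return GainFunction(c=c, B=value - c * at / (theta + at), theta=theta)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def trial_table():
    """200 balanced trials on the standard event timeline."""
    return make_trial_table(200, np.random.default_rng(7))


@pytest.fixture
def mutual_excitation_net():
    """Two mutually excitatory populations, attractor pinned at (0.5, 0.5)."""
    def make(eta1=0.3, eta2=0.3, sigma=0.0):
        return NetworkSpec(
            weights=np.array([[0, 1], [1, 0]]),
            gains={(0, 1): gain_through(0.5, eta1), (1, 0): gain_through(0.5, eta2)},
            sigma=sigma,
        )
    return make


@pytest.fixture
def exc_inh_net():
    """Excitation-inhibition loop with attractor at (0.5, 0.5)."""
    def make(slope=0.7, sigma=0.0):
        return NetworkSpec(
            weights=np.array([[0, 1], [-1, 0]]),
            gains={(0, 1): gain_through(0.5, slope), (1, 0): gain_through(0.5, slope)},
            sigma=sigma,
            bias=np.array([0.0, 1.0]),
        )
    return make
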