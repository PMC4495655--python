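import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")

from rodcone.ln import LNModel
from rodcone.synthetic import (NoiseStimulusSpec, cone_filter,
                               default_shared_nonlinearity, rod_filter)


@pytest.fixture(scope="session")
def rod():
    return rod_filter()


@pytest.fixture(scope="session")
def cone():
    return cone_filter()


@pytest.fixture(scope="session")
def noise_spec():
    return NoiseStimulusSpec()


@pytest.fixture(scope="session")
def shared_nl(rod, noise_spec):
    """Default threshold-linear rectifier used across interaction tests."""
    return default_shared_nonlinearity(rod, noise_spec)


@pytest.fixture(scope="session")
def rod_model(rod, shared_nl):
    return LNModel(rod, shared_nl, rod.dt)


@pytest.fixture(scope="session")
def cone_model(cone, shared_nl):
    return LNModel(cone, shared_nl, cone.dt)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
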