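import numpy as np
import pytest

from fmbsim import ModelParameters, find_steady_states


@pytest.fixture(scope="session")
def defaults() -> ModelParameters:
    """The symmetric bistable reference parameter set."""
    return ModelParameters()


@pytest.fixture(scope="session")
def default_steady_states(defaults):
    return find_steady_states(defaults)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20130814)
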