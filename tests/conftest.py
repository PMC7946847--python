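import numpy as np
import pytest

from awtsim.design import DesignConfig, generate_session, session_to_frame
from awtsim.observer import ObserverParams


@pytest.fixture(scope="session")
def default_config():
    return DesignConfig()


@pytest.fixture(scope="session")
def modified_config():
    return DesignConfig(cue_valid_fraction=0.8)


@pytest.fixture(scope="session")
def default_observer():
    return ObserverParams()


@pytest.fixture(scope="session")
def default_session_frame(default_config):
    return session_to_frame(generate_session(default_config, seed=123))


@pytest.fixture()
def rng():
    return np.random.default_rng(987)
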