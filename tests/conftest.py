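import numpy as np
import pytest

from phosdyn.fixtures import load_fixture
from phosdyn.params import load_parameter_set


@pytest.fixture(scope="session")
def hps():
    return load_parameter_set("hps")


@pytest.fixture(scope="session")
def modified_hps():
    return load_parameter_set("modified_hps")


@pytest.fixture(scope="session")
def lcd():
    return load_fixture("tdp43_lcd")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
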