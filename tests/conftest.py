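import numpy as np
import pytest

from paranmr.pre import PREConditions
from paranmr.synthetic import make_helix, make_two_lobe_toy, two_helix_scenario


@pytest.fixture(scope="session")
def conditions():
    return PREConditions()


@pytest.fixture(scope="session")
def helix10():
    return make_helix(10)


@pytest.fixture(scope="session")
def two_lobe():
    structure, ss = make_two_lobe_toy()
    return structure, ss


@pytest.fixture(scope="session")
def scenario():
    return two_helix_scenario(seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
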