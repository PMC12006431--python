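import numpy as np
import pytest

from thermoclamp.model import available_presets, load_preset


@pytest.fixture(scope="session")
def presets():
    return {name: load_preset(name) for name in available_presets()}


@pytest.fixture(scope="session")
def ph74(presets):
    return presets["pH7.4"]


@pytest.fixture(scope="session")
def ba(presets):
    return presets["ba_divalent"]


@pytest.fixture(scope="session")
def null(presets):
    return presets["catsper_null"]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
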