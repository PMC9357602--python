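import numpy as np
import pytest

from turingdelay.reaction_models import Kinetics, ModelSpec


@pytest.fixture
def li_model():
    return ModelSpec(Kinetics.LI, 0.1, 0.9)


@pytest.fixture
def gm1_model():
    return ModelSpec(Kinetics.GM1, 0.75, 0.5)


@pytest.fixture
def gm2_model():
    return ModelSpec(Kinetics.GM2, 0.75, 0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
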