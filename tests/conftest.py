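import numpy as np
import pytest

from diveo2.oxy_dissociation import BohrModel, emperor_bohr_model, fulmar_curve


@pytest.fixture(scope="session")
def bohr():
    return emperor_bohr_model()


@pytest.fixture(scope="session")
def fulmar():
    return fulmar_curve()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_bohr():
    # small hand-built model, independent of the shipped anchors
    return BohrModel(anchors=((7.2, 40.0), (7.4, 30.0)))
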