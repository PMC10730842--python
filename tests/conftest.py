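import numpy as np
import pytest

from gradcap import EffectConfig, make_parcellation
from gradcap.synth import make_ground_truth


@pytest.fixture(scope="session")
def parc70():
    return make_parcellation(70, seed=0)


@pytest.fixture(scope="session")
def parc350():
    return make_parcellation(350, seed=0)


@pytest.fixture(scope="session")
def truth70(parc70):
    return make_ground_truth(parc70, EffectConfig(), seed=1)


@pytest.fixture(scope="session")
def truth350(parc350):
    return make_ground_truth(parc350, EffectConfig(), seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
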