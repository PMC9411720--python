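import numpy as np
import pytest

import srflow as sf
from srflow.models import TINY_PRESET


@pytest.fixture(scope="session")
def abc_field():
    return sf.abc_flow(sf.FlowRecipe(kind="abc", shape=(16, 16, 16)))


@pytest.fixture(scope="session")
def solenoidal_field():
    return sf.solenoidal_random_field(
        sf.FlowRecipe(shape=(32, 32, 32), smoothness_sigma=2.0, seed=7)
    )


@pytest.fixture(scope="session")
def poiseuille_field():
    return sf.poiseuille_tube(sf.FlowRecipe(kind="poiseuille", shape=(16, 16, 16)))


@pytest.fixture(scope="session")
def tiny_net():
    """Randomly initialized desk-scale network, scale 2."""
    cfg = sf.ModelConfig(scale=2, **TINY_PRESET)
    return sf.build_model(cfg, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
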