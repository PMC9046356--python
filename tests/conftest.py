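import math

import numpy as np
import pytest

from cytolaminar.synthetic import GroupEffect, LayerParams

#: Two thin, sparse layers — fast to generate, used wherever the laminar
#: structure itself is not under test.
SMALL_LAYERS = (
    LayerParams("L1", 200.0, 150.0, math.log(50.0), 0.30),
    LayerParams("L2", 200.0, 250.0, math.log(70.0), 0.30),
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_layers():
    return SMALL_LAYERS


@pytest.fixture
def identity_effect():
    return GroupEffect("g")
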