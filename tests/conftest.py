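import numpy as np
import pytest

from adafnn import (
    BasisLayerSpec,
    MicroNetworkSpec,
    ModelSpec,
    make_time_grid,
)
from adafnn.synthetic import SyntheticSpec, generate_trials


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_trials():
    """A small, quickly generated trial set with clear class structure."""
    spec = SyntheticSpec(n_per_class=(14, 10, 8), J=64, F=3,
                         informative_channels=(0, 1), noise_sd=0.3,
                         pad_prob=0.0, seed=7)
    ts, truth = generate_trials(spec)
    return ts, truth


@pytest.fixture
def small_model_spec():
    return ModelSpec(BasisLayerSpec(K=2, F=3, micro=MicroNetworkSpec((8, 4))))


@pytest.fixture
def grid64():
    return make_time_grid(64)
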