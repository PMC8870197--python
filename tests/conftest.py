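import numpy as np
import pytest

from cgbg import ModelParams, NetworkWeights


@pytest.fixture
def default_params() -> ModelParams:
    return ModelParams()


@pytest.fixture
def absolute_params() -> ModelParams:
    """Parameters using the absolute dopamine coding (dip/tonic/burst = 0/0.5/1)."""
    return ModelParams().with_absolute_da()


def make_zero_weights(n: int) -> NetworkWeights:
    return NetworkWeights(n, np.zeros((n, 2 * n)), np.zeros((n, n)))


@pytest.fixture
def zero_weights():
    return make_zero_weights


def random_weights(rng: np.random.Generator, n: int, scale: float = 1.5) -> NetworkWeights:
    return NetworkWeights(
        n,
        rng.uniform(0.0, scale, size=(n, 2 * n)),
        rng.uniform(0.0, scale, size=(n, n)),
    )
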