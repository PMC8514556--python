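import numpy as np
import pytest

from crosssort import EmbeddingParams, NetworkSpec, simulate_logistic_map


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def lm_trace():
    """A single chaotic logistic-map trace of length 400."""
    spec = NetworkSpec(1, np.zeros((1, 1)), "lm", {"r": [3.8], "x0": [0.37]})
    return simulate_logistic_map(spec, 400, seed=3).series.values


@pytest.fixture
def p21():
    return EmbeddingParams(dim=2, lag=1)
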