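import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_zero_inflated(rng, n, p, zero_fraction):
    """Random nonnegative samples-by-metabolites matrix with a given zero rate."""
    X = rng.gamma(shape=2.0, scale=1.5, size=(n, p))
    X[rng.random((n, p)) < zero_fraction] = 0.0
    return X


@pytest.fixture
def toy_separation():
    """n=20 (10/10), p=1: controls all absent, cases present near 5."""
    rng = np.random.default_rng(7)
    x = np.concatenate([np.zeros(10), rng.normal(5.0, 0.1, 10)])[:, None]
    y = np.concatenate([np.zeros(10, dtype=int), np.ones(10, dtype=int)])
    return x, y
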