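import numpy as np
import pytest

from uqpath import Patch, SampleMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_patch(rng):
    def make(h=16, w=16, seed=None):
        r = rng if seed is None else np.random.default_rng(seed)
        return Patch(r.uniform(0, 1, (h, w, 3)), identifier=f"p{h}x{w}")
    return make


@pytest.fixture
def random_matrix(rng):
    """Random sample matrix with scores strictly inside (0, 1)."""
    def make(n=100, T=10, seed=None, method="ensemble"):
        r = rng if seed is None else np.random.default_rng(seed)
        samples = r.uniform(1e-3, 1 - 1e-3, (n, T))
        labels = r.integers(0, 2, n)
        return SampleMatrix(samples, labels, method=method)
    return make
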