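import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_similarity_matrix(rng):
    """Factory for valid random similarity matrices (symmetric, unit diag)."""

    def make(n: int, low: float = -1.0, high: float = 1.0) -> np.ndarray:
        q = rng.uniform(low, high, size=(n, n))
        q = (q + q.T) / 2.0
        np.fill_diagonal(q, 1.0)
        return q

    return make
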