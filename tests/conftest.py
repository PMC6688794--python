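import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_null(rng):
    """A small null dataset: traits independent of genotypes."""
    n, K, M = 60, 3, 6
    Y = rng.standard_normal((n, K))
    X = rng.binomial(2, 0.3, size=(n, M)).astype(float)
    Z = np.column_stack([rng.standard_normal(n), rng.binomial(1, 0.5, n).astype(float)])
    return Y, X, Z


@pytest.fixture
def associated(rng):
    """A dataset with a strong genuine trait-genotype association."""
    n, K, M = 200, 3, 5
    X = rng.binomial(2, 0.3, size=(n, M)).astype(float)
    Y = rng.standard_normal((n, K))
    Y[:, 0] += 0.8 * X[:, 0] + 0.5 * X[:, 1]
    Y[:, 1] += 0.6 * X[:, 0]
    return Y, X
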