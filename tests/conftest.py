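import numpy as np
import pytest

from cosmoda import CompositionDataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_dataset(rng):
    """Random strictly-positive composition data with a binary covariate."""
    n, p = 24, 4
    X = rng.dirichlet(np.ones(p) * 3.0, size=n)
    y = rng.integers(0, 2, size=n).astype(float)
    return CompositionDataset(X, y)


@pytest.fixture
def continuous_covariate_dataset(rng):
    n, p = 20, 5
    X = rng.dirichlet(np.ones(p) * 2.0, size=n)
    y = rng.normal(size=n)
    return CompositionDataset(X, y)
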