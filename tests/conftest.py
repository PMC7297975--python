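import numpy as np
import pytest

from robitsel import Dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_data(rng):
    """n=20, p=10 random dataset with intercept column."""
    n, p = 20, 10
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p))])
    y = rng.integers(0, 2, n)
    y[0], y[1] = 0, 1  # both classes present
    return Dataset(X=X, y=y)


@pytest.fixture
def separated_1d():
    """p=1 dataset where the feature separates the classes strongly."""
    x = np.concatenate([np.linspace(-3, -1, 10), np.linspace(1, 3, 10)])
    y = np.concatenate([np.zeros(10, int), np.ones(10, int)])
    X = np.column_stack([np.ones(20), x])
    return Dataset(X=X, y=y)
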