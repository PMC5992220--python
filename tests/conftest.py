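import numpy as np
import pytest

from dsmm import PointSet


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_pair(rng):
    """A small random 2-D target/template pair (M=7, N=5)."""
    X = PointSet(rng.normal(size=(7, 2)))
    Y = PointSet(rng.normal(size=(5, 2)))
    return X, Y


def random_simplex_rows(rng, m, n):
    """Random (m, n) matrix with rows on the open probability simplex."""
    A = rng.gamma(2.0, size=(m, n)) + 1e-3
    return A / A.sum(axis=1, keepdims=True)
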