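import numpy as np
import pytest

from precision_lasso import DesignMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def orthonormal_design(rng):
    """64 x 8 design with exactly orthonormal columns."""
    Q, _ = np.linalg.qr(rng.standard_normal((64, 8)))
    return DesignMatrix(Q)


@pytest.fixture
def random_design(rng):
    return DesignMatrix(rng.standard_normal((20, 6)))


def make_duplicated_design(rng, n=120, p=10):
    """Random design whose column 1 is an exact copy of column 0."""
    X = rng.standard_normal((n, p))
    X[:, 1] = X[:, 0]
    return DesignMatrix(X)
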