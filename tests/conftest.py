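import numpy as np
import pytest

from mplnmix.model import ComponentParams, CountMatrix, NormalizationOffsets


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_counts(rng):
    """50 x 3 matrix of MPLN-ish counts with moderate magnitudes."""
    theta = rng.normal(3.0, 0.5, size=(50, 3))
    return CountMatrix(rng.poisson(np.exp(theta)))


@pytest.fixture
def comp2():
    return ComponentParams(np.array([1.0, -0.5]),
                           np.array([[0.5, 0.2], [0.2, 0.8]]))


@pytest.fixture
def unit_offsets():
    return NormalizationOffsets(np.ones(2))
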