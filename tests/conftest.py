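import numpy as np
import pytest

from propbayes.counts import (
    BinaryConditionalCounts,
    CountVector,
    MultiplicityHistogram,
)
from propbayes.core import SolverConfig


@pytest.fixture(scope="session")
def cfg():
    return SolverConfig()


@pytest.fixture(scope="session")
def bivariate_fixtures():
    """Small bivariate datasets exercising singletons and coincidences."""
    return [
        BinaryConditionalCounts([(0, 1)], 1),
        BinaryConditionalCounts([(1, 0), (0, 1), (0, 1)], 10),
        BinaryConditionalCounts([(2, 1), (0, 3), (1, 1), (0, 1), (1, 0)], 20),
        BinaryConditionalCounts([(1, 1)] * 4 + [(0, 2)] * 2 + [(1, 0)] * 5, 50),
    ]


@pytest.fixture(scope="session")
def multiplicity_fixtures():
    """Small entropy datasets: (partition, k) pairs as histograms."""
    return [
        MultiplicityHistogram.from_partition(p, k)
        for p, k in [
            ((1,), 2),
            ((2, 1), 3),
            ((3, 1, 1), 5),
            ((2, 1, 1, 1, 1), 30),
            ((4, 2), 30),
        ]
    ]


@pytest.fixture(scope="session")
def count_vector_fixtures():
    return [
        CountVector((1, 0), 2),
        CountVector((2, 1, 0), 3),
        CountVector((3, 1, 1), 5),
        CountVector((4, 4, 2, 1, 1), 10),
        CountVector((2, 1, 1, 1, 1), 30),
    ]


@pytest.fixture(scope="session")
def beta_grid_41():
    return np.linspace(-20.0, 20.0, 41)
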