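import numpy as np
import pytest

from funconn import ConnectivityMatrix, rectify_negatives
from funconn.synthetic import CohortSpec, make_cohort


def random_symmetric(n: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.uniform(-1, 1, size=(n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    return v


def random_rectified(n: int, rng: np.random.Generator) -> ConnectivityMatrix:
    return rectify_negatives(ConnectivityMatrix(random_symmetric(n, rng)))


def random_adjacency(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    a = rng.random((n, n)) < p
    a = np.triu(a, 1)
    a = a | a.T
    return a


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny null cohort shared across tests (12 subjects, 20 regions)."""
    spec = CohortSpec(
        n_patients=5, n_controls=7, n_rois=20, n_timepoints=80,
        modules=[list(range(10)), list(range(10, 20))], seed=7,
    )
    return make_cohort(spec)
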