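import numpy as np
import pytest

from connstim import FunctionalConnectome, default_parcellation
from connstim.synthetic import synthetic_parcellation


def random_admissible_matrix(rng, n, radius=0.4):
    """Symmetric zero-diagonal matrix rescaled to the given spectral radius."""
    m = rng.normal(size=(n, n))
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    current = np.max(np.abs(np.linalg.eigvalsh(m)))
    return m * (radius / current)


@pytest.fixture(scope="session")
def parcellation92():
    return default_parcellation()


@pytest.fixture
def parcellation6():
    return synthetic_parcellation(6)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def connectome_factory(rng):
    def make(n=6, radius=0.4, regions=None):
        m = random_admissible_matrix(rng, n, radius)
        return FunctionalConnectome.from_measurement(
            m, regions or tuple(f"r{i+1}" for i in range(n))
        )

    return make
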