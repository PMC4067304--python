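import numpy as np
import pytest

from ramaweight import ChainTopology, ForceFieldParams, MaxEntDensity, enumerate_basis
from ramaweight.experiments import make_toy_density


@pytest.fixture(scope="session")
def toy_density() -> MaxEntDensity:
    """The canonical order-5 bimodal (centro-symmetric) torsion density."""
    return make_toy_density()


@pytest.fixture(scope="session")
def order2_density() -> MaxEntDensity:
    """A small hand-set order-2 density for cheap exact checks."""
    coeffs = np.array([1.0, -0.5, 0.3, 0.2, -0.4, 0.1, 0.0, 0.6])
    assert coeffs.size == len(enumerate_basis(2))
    return MaxEntDensity(order=2, coeffs=coeffs)


@pytest.fixture
def topo5() -> ChainTopology:
    return ChainTopology(5)


@pytest.fixture
def ff() -> ForceFieldParams:
    return ForceFieldParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
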