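import numpy as np
import pytest

from aimpot.core import ModelConfig
from aimpot.potential import NeuralPotential
from aimpot.synthdata import ToyPotential
from aimpot.system import MolecularSystem

ORGANIC_Z = np.array([1, 6, 7, 8, 9, 16, 17])


def random_system(rng, n_atoms=None, charge=0, box=4.0, min_dist=0.8,
                  z_choices=ORGANIC_Z):
    """Random non-clashing isolated system (no bond graph)."""
    n = n_atoms or int(rng.integers(3, 9))
    for _ in range(200):
        coords = rng.uniform(0, box, size=(n, 3))
        d = np.linalg.norm(coords[None] - coords[:, None], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() >= min_dist:
            break
    z = rng.choice(z_choices, size=n)
    return MolecularSystem(coords=coords, atomic_numbers=z, charge=charge)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def toypot():
    return ToyPotential()


@pytest.fixture(scope="session")
def small_model():
    """Compact untrained model (random weights) with full physics."""
    return NeuralPotential(config=ModelConfig(hidden=(48, 24), n_passes=2,
                                              seed=11))


@pytest.fixture(scope="session")
def default_model():
    """Default-architecture model (random weights)."""
    return NeuralPotential(config=ModelConfig(seed=3))
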