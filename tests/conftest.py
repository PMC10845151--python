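import warnings

import numpy as np
import pytest

from deltabh.geometry import Geometry
from deltabh.molgraph import MolecularGraph
from deltabh.synthetic import GeneratorConfig, gen_dataset

warnings.filterwarnings("ignore", message="negative barrier height")


@pytest.fixture(scope="session")
def methane():
    # C at origin, 4 H tetrahedral at 1.09 A
    a = 1.09 / np.sqrt(3)
    coords = np.array(
        [[0, 0, 0], [a, a, a], [a, -a, -a], [-a, a, -a], [-a, -a, a]], dtype=float
    )
    return Geometry(("C", "H", "H", "H", "H"), coords)


@pytest.fixture(scope="session")
def formaldehyde():
    return Geometry(
        ("C", "O", "H", "H"),
        np.array(
            [
                [0.0, 0.0, 0.0],
                [0.0, 0.0, 1.21],
                [0.94, 0.0, -0.54],
                [-0.94, 0.0, -0.54],
            ]
        ),
    )


def random_molgraph(rng, n_max=8):
    """Random small graph with CHNO labels (no valence constraint needed)."""
    n = int(rng.integers(2, n_max + 1))
    adj = np.triu((rng.random((n, n)) < 0.4).astype(int), 1)
    adj = adj + adj.T
    z = rng.choice([1, 6, 7, 8], size=n)
    return MolecularGraph(adj, z)


@pytest.fixture(scope="session")
def dataset_2000():
    """Shared synthetic study set: n=2000, sd 2 kcal/mol correction noise."""
    cfg = GeneratorConfig(n_reactions=2000, seed=123, noise_sd=2.0)
    return gen_dataset(cfg)


@pytest.fixture(scope="session")
def small_dataset():
    cfg = GeneratorConfig(n_reactions=60, seed=42, noise_sd=1.0)
    return gen_dataset(cfg)
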