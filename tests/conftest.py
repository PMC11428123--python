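import numpy as np
import pytest

from xtalloy.crystal_model import Molecule, UnitCell, CrystalStructure
from xtalloy.synthetic_data import (
    WATER,
    VACUUM,
    make_interaction_table,
    make_toy_structure,
)


@pytest.fixture(scope="session")
def toy_beta():
    return make_toy_structure("beta")


@pytest.fixture(scope="session")
def toy_beta4():
    return make_toy_structure("beta4")


@pytest.fixture(scope="session")
def toy_cubic():
    return make_toy_structure("cubic")


@pytest.fixture(scope="session")
def vacuum_table(toy_beta):
    return make_interaction_table(toy_beta, VACUUM)


@pytest.fixture(scope="session")
def water_table(toy_beta):
    return make_interaction_table(toy_beta, WATER)


def random_structure(rng: np.random.Generator, max_molecules: int = 3,
                     max_atoms: int = 4) -> CrystalStructure:
    """Random small triclinic P1 cell for oracle-equivalence tests."""
    cell = UnitCell(
        float(rng.uniform(4.5, 8.0)),
        float(rng.uniform(4.5, 8.0)),
        float(rng.uniform(4.5, 8.0)),
        float(rng.uniform(80.0, 100.0)),
        float(rng.uniform(80.0, 100.0)),
        float(rng.uniform(80.0, 100.0)),
    )
    n_mol = int(rng.integers(1, max_molecules + 1))
    mols = []
    for _ in range(n_mol):
        n_at = int(rng.integers(1, max_atoms + 1))
        center = rng.uniform(0, 1, 3)
        spread = rng.uniform(-0.9, 0.9, (n_at, 3))
        inv = np.linalg.inv(cell.matrix)
        frac = center + spread @ inv.T
        mols.append(Molecule("host", tuple(["C"] * n_at), frac))
    return CrystalStructure(cell, mols, ["x,y,z"], n_mol, "random")
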