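import io

import numpy as np
import pytest

from confens import (
    Conformer,
    MoleculeGraph,
    build_template,
    perceive,
)


ETHANE_SDF = """ethane
  test

  8  7  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.5400    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.3600    1.0300    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.3600   -0.5100    0.8900 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.3600   -0.5100   -0.8900 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.9000    1.0300    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.9000   -0.5100    0.8900 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.9000   -0.5100   -0.8900 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  1  3  1  0
  1  4  1  0
  1  5  1  0
  2  6  1  0
  2  7  1  0
  2  8  1  0
M  END
$$$$
"""


@pytest.fixture
def ethane_sdf():
    return io.StringIO(ETHANE_SDF)


@pytest.fixture
def benzene():
    mol, conf = build_template("phenyl_chain(0)")
    return mol, conf, perceive(mol)


@pytest.fixture
def cyclohexane():
    mol, conf = build_template("ring(6)")
    return mol, conf, perceive(mol)


def chain_mol(n, elements=None, name="chain"):
    """Simple heavy-atom chain molecule with given elements."""
    elements = elements or ["C"] * n
    atoms = tuple((e, 0) for e in elements)
    bonds = tuple((k, k + 1, 1) for k in range(n - 1))
    return MoleculeGraph(atoms=atoms, bonds=bonds, name=name)


def random_molecule(rng, n_atoms):
    """Random connected heavy-atom molecule (tree plus optional extra edge)."""
    elements = rng.choice(["C", "C", "N", "O"], size=n_atoms)
    atoms = tuple((str(e), 0) for e in elements)
    bonds = []
    for k in range(1, n_atoms):
        parent = int(rng.integers(0, k))
        bonds.append((parent, k, 1))
    if n_atoms >= 4 and rng.random() < 0.4:
        existing = {(min(i, j), max(i, j)) for i, j, _ in bonds}
        i, j = sorted(rng.choice(n_atoms, size=2, replace=False).tolist())
        if (i, j) not in existing:
            bonds.append((i, j, 1))
    return MoleculeGraph(atoms=atoms, bonds=tuple(bonds), name="random")


def random_conformer(rng, mol, scale=1.5):
    """Random (non-physical) coordinates for a molecule's atoms."""
    return Conformer(coords=rng.normal(0.0, scale, size=(len(mol.atoms), 3)))
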