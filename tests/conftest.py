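import numpy as np
import pytest

from mfccpocket.structure_model import Atom, Residue, Role, Structure
from mfccpocket.synthetic_data import ToySpec, make_toy_complex, toy_ligand_id


@pytest.fixture(scope="session")
def toy_structure():
    """Default 8-residue complex (ASP3/LYS7, 2 waters), fixed seed."""
    return make_toy_complex(ToySpec(seed=11))


@pytest.fixture(scope="session")
def ligand_id():
    return toy_ligand_id()


@pytest.fixture
def make_complex():
    """Factory: toy complex with overridable spec fields."""

    def _make(seed=0, **fields):
        return make_toy_complex(ToySpec(seed=seed, **fields))

    return _make


def single_atom_residue(chain, seq, name, role, element, position, charge=0.0):
    """Minimal one-atom residue for hand-built geometric scenarios."""
    atom = Atom("CA" if role == Role.PROTEIN else element, element,
                np.asarray(position, dtype=float), partial_charge=charge)
    return Residue(chain, seq, name, [atom], role)


@pytest.fixture
def point_structure():
    """Factory: structure of single-atom residues at given distances from a
    single-atom ligand at the origin (for distance/shell scenarios)."""

    def _make(distances, ligand_pos=(0.0, 0.0, 0.0)):
        residues = [
            single_atom_residue("A", i + 1, "GLY", Role.PROTEIN, "C",
                                (d, 0.0, 0.0))
            for i, d in enumerate(distances)
        ]
        lig = single_atom_residue("L", 900, "LIG", Role.LIGAND, "C", ligand_pos)
        return Structure(residues + [lig]), lig.id

    return _make
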