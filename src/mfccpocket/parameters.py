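"""Minimal embedded non-bonded parameter set for the classical backend.

The classical pairwise backend is a desk-scale stand-in for the DFT total
energies, so the parameter set is deliberately small: common backbone
partial charges, element-based side-chain defaults, TIP3P water, and
element-keyed Lennard-Jones parameters.  Per-residue charges are normalised
so that each residue's partial charges sum exactly to its formal charge —
the classical energetics then respect the charge bookkeeping that the
fragment combination relies on.

External parameter files are accepted as TSV with columns
``residue  atom_name  charge  sigma  epsilon`` (sigma/epsilon may be empty
to inherit the element defaults).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .errors import ParameterizationError
from .structure_model import Atom, Residue, Role, Structure

# Lennard-Jones parameters by element: (sigma [A], epsilon [kcal/mol])
ELEMENT_LJ: dict[str, tuple[float, float]] = {
    "H": (1.20, 0.0157),
    "C": (3.40, 0.0860),
    "N": (3.25, 0.1700),
    "O": (3.00, 0.2100),
    "S": (3.60, 0.2500),
    "P": (3.74, 0.2000),
    "F": (3.00, 0.0610),
    "CL": (3.47, 0.2650),
    "BR": (3.60, 0.3200),
    "ZN": (1.95, 0.2500),
    "MG": (1.64, 0.8750),
    "NA": (2.43, 0.0028),
    "K": (3.04, 0.0003),
    "CA": (2.65, 0.4500),
}
DEFAULT_LJ: tuple[float, float] = (3.30, 0.1000)

# Reduced backbone charge set (amide dipole dominant, CHARMM-like signs).
BACKBONE_CHARGES: dict[str, float] = {
    "N": -0.47, "H": 0.31, "H1": 0.33, "H2": 0.33, "H3": 0.33,
    "CA": 0.07, "HA": 0.09, "HA2": 0.09, "HA3": 0.09,
    "C": 0.51, "O": -0.51, "OXT": -0.67,
}

# Element fallbacks for side-chain / ligand atoms lacking explicit entries.
ELEMENT_CHARGES: dict[str, float] = {
    "C": 0.0, "H": 0.06, "O": -0.40, "N": -0.35, "S": -0.20,
}

WATER_CHARGES: dict[str, float] = {"O": -0.834, "H": 0.417}  # TIP3P


@dataclass
class ParameterTable:
    """Charge and LJ lookup with optional per-(residue, atom) overrides."""

    charge_overrides: dict[tuple[str, str], float] = field(default_factory=dict)
    lj_overrides: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ParameterTable":
        table = cls()
        lines = Path(path).read_text().splitlines()
        start = 1 if lines and lines[0].lower().startswith("residue") else 0
        for line in lines[start:]:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            resname, atom = parts[0].upper(), parts[1]
            if parts[2]:
                table.charge_overrides[(resname, atom)] = float(parts[2])
            if len(parts) >= 5 and parts[3] and parts[4]:
                table.lj_overrides[(resname, atom)] = (float(parts[3]), float(parts[4]))
        return table

    def raw_charge(self, residue: Residue, atom: Atom) -> float:
        key = (residue.name.upper(), atom.name)
        if key in self.charge_overrides:
            return self.charge_overrides[key]
        if residue.role == Role.WATER:
            return WATER_CHARGES.get(atom.element, 0.0)
        if residue.role == Role.ION:
            return float(residue.formal_charge)
        if residue.role == Role.PROTEIN and atom.name in BACKBONE_CHARGES:
            return BACKBONE_CHARGES[atom.name]
        return ELEMENT_CHARGES.get(atom.element, 0.0)

    def lj(self, residue_name: str, atom: Atom) -> tuple[float, float]:
        if atom.is_cap_hydrogen:
            return (0.0, 0.0)
        key = (residue_name.upper(), atom.name)
        if key in self.lj_overrides:
            return self.lj_overrides[key]
        return ELEMENT_LJ.get(atom.element, DEFAULT_LJ)

    def assign_charges(self, structure: Structure, overwrite: bool = False) -> Structure:
        """Set ``partial_charge`` on every atom.

        Raw per-atom values come from the override table, backbone/water/ion
        tables, or element defaults; each residue's charges are then shifted
        uniformly so they sum exactly to the residue's formal charge.  Atoms
        that already carry a charge are kept unless `overwrite` is set (the
        whole residue is then re-derived).
        """
        for res in structure.residues:
            if not overwrite and all(a.partial_charge is not None for a in res.atoms):
                continue
            raw = [self.raw_charge(res, a) for a in res.atoms]
            if res.atoms:
                shift = (res.formal_charge - sum(raw)) / len(res.atoms)
                for a, q in zip(res.atoms, raw):
                    a.partial_charge = q + shift
        return structure


DEFAULT_TABLE = ParameterTable()


def resolve_charge(atom: Atom, context: str = "") -> float:
    """The charge used by the classical backend for an atom in a fragment.

    Saturating cap hydrogens are spectators (zero charge); any other atom
    must carry an assigned partial charge.
    """
    if atom.is_cap_hydrogen:
        return 0.0
    if atom.partial_charge is None:
        raise ParameterizationError(
            f"atom {atom.name}{' of ' + context if context else ''} has no "
            "partial charge; run charge assignment first")
    return atom.partial_charge
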