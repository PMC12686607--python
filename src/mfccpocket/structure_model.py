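"""Molecular structure domain model and standard-format I/O.

The pipeline works on a light-weight residue/atom model rather than on a
parser's object tree: every downstream stage (shell selection, conjugated-cap
fragmentation, classical energies, deck generation) needs only names,
elements, coordinates, roles and charges.  PDB files are read through
Biopython's parser and mapped onto this model; writing uses the fixed-column
PDB v3 layout directly.

Roles follow the usual crystallographic conventions: ``ATOM`` records are
protein, ``HETATM`` waters are detected by residue name (HOH/WAT/...),
single-atom HETATM species are ions, and every remaining HETATM residue is a
ligand candidate.
"""
from __future__ import annotations

import copy as _copy
import io
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, NamedTuple

import numpy as np

from . import constants, topology
from ._geometry import complete_substituents, unit
from .errors import ContentError, MfccError, PDBParseError, UnparameterizedResidueError


class Role(str, Enum):
    PROTEIN = "protein"
    LIGAND = "ligand"
    WATER = "water"
    ION = "ion"


class ResidueId(NamedTuple):
    chain_id: str
    seq_number: int
    insertion_code: str = ""

    def __str__(self) -> str:
        return f"{self.chain_id}:{self.seq_number}{self.insertion_code}"


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray
    partial_charge: float | None = None
    occupancy: float = 1.0
    altloc: str = ""
    is_added_hydrogen: bool = False
    # hydrogen introduced to saturate a cut peptide bond during fragment
    # construction (spectator in the classical backend; real H in QM decks)
    is_cap_hydrogen: bool = False

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"atom {self.name}: position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: non-finite coordinates")
        self.element = self.element.strip().upper()
        if self.element not in constants.ELEMENTS:
            raise ValueError(f"atom {self.name}: unknown element {self.element!r}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.position.copy(),
                    self.partial_charge, self.occupancy, self.altloc,
                    self.is_added_hydrogen, self.is_cap_hydrogen)


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    role: Role = Role.PROTEIN
    insertion_code: str = ""
    formal_charge: int = 0

    @property
    def id(self) -> ResidueId:
        return ResidueId(self.chain_id, self.seq_number, self.insertion_code)

    def get_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self, heavy_only: bool = False) -> np.ndarray:
        atoms = [a for a in self.atoms if not (heavy_only and a.is_hydrogen)]
        if not atoms:
            return np.empty((0, 3))
        return np.array([a.position for a in atoms])

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def copy(self) -> "Residue":
        return Residue(self.chain_id, self.seq_number, self.name,
                       [a.copy() for a in self.atoms], self.role,
                       self.insertion_code, self.formal_charge)


@dataclass
class Structure:
    residues: list[Residue] = field(default_factory=list)
    title: str = ""
    source: str = ""

    def __post_init__(self):
        self._check_unique_ids()

    def _check_unique_ids(self):
        seen: set[ResidueId] = set()
        for r in self.residues:
            if r.id in seen:
                raise ContentError(f"duplicate residue id {r.id}")
            seen.add(r.id)

    def get(self, rid: ResidueId) -> Residue:
        for r in self.residues:
            if r.id == ResidueId(*rid):
                return r
        raise KeyError(f"no residue {rid}")

    def by_role(self, role: Role) -> list[Residue]:
        return [r for r in self.residues if r.role == role]

    @property
    def protein_residues(self) -> list[Residue]:
        return self.by_role(Role.PROTEIN)

    @property
    def ligands(self) -> list[Residue]:
        return self.by_role(Role.LIGAND)

    @property
    def waters(self) -> list[Residue]:
        return self.by_role(Role.WATER)

    def chain(self, chain_id: str) -> list[Residue]:
        return [r for r in self.protein_residues if r.chain_id == chain_id]

    def neighbors_in_chain(self, rid: ResidueId) -> tuple[Residue | None, Residue | None]:
        """The chain-adjacent previous/next protein residues (by order)."""
        chain = self.chain(ResidueId(*rid).chain_id)
        for i, r in enumerate(chain):
            if r.id == ResidueId(*rid):
                prev_r = chain[i - 1] if i > 0 else None
                next_r = chain[i + 1] if i + 1 < len(chain) else None
                return prev_r, next_r
        raise KeyError(f"no protein residue {rid}")

    def copy(self) -> "Structure":
        return Structure([r.copy() for r in self.residues], self.title, self.source)


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

_COORD_SLICES = ((30, 38), (38, 46), (46, 54))


def _prescan_pdb(text: str) -> None:
    """Validate coordinate fields so parse failures carry a line number."""
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        if len(line) < 54:
            raise PDBParseError("truncated coordinate record", lineno)
        for lo, hi in _COORD_SLICES:
            try:
                float(line[lo:hi])
            except ValueError:
                raise PDBParseError(
                    f"malformed coordinate field {line[lo:hi]!r}", lineno
                ) from None


def _pick_altloc(instances, policy: str):
    """Resolve a disordered atom to one conformer per the altloc policy."""
    if policy == "label_A":
        for a in instances:
            if (a.get_altloc() or " ").strip() in ("A", ""):
                return a
        return instances[0]
    # highest_occupancy, ties broken by altloc label (A first)
    return sorted(
        instances,
        key=lambda a: (-(a.get_occupancy() or 0.0), (a.get_altloc() or "~")),
    )[0]


def _guess_element(bio_atom) -> str:
    el = (bio_atom.element or "").strip().upper()
    if el in constants.ELEMENTS:
        return el
    name = bio_atom.get_name().strip()
    lead = name.lstrip("0123456789")
    if lead[:2].upper() in constants.ELEMENTS and lead[:2].upper() in topology.ION_CHARGES:
        return lead[:2].upper()
    return lead[:1].upper()


def read_pdb(path: str | Path, altloc_policy: str = "highest_occupancy") -> Structure:
    """Read a PDB file into a :class:`Structure`.

    `altloc_policy` is one of ``highest_occupancy`` (default; ties broken by
    label A) or ``label_A``.  Waters are recognised by residue name, ions as
    single-atom HETATM species, and the remaining HETATM residues become
    ligands.  Raises :class:`PDBParseError` (with a line number) on malformed
    coordinate records and :class:`ContentError` if no protein residue is
    found.
    """
    if altloc_policy not in ("highest_occupancy", "label_A"):
        raise ValueError(f"unknown altloc policy {altloc_policy!r}")
    path = Path(path)
    text = path.read_text()
    _prescan_pdb(text)

    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        parser = PDBParser(QUIET=True)
        model = parser.get_structure(path.stem, io.StringIO(text))[0]

    residues: list[Residue] = []
    for bio_chain in model:
        for bio_res in bio_chain:
            hetflag, seq, icode = bio_res.get_id()
            resname = bio_res.get_resname().strip()
            atoms: list[Atom] = []
            for bio_atom in bio_res:
                if bio_atom.is_disordered():
                    chosen = _pick_altloc(bio_atom.disordered_get_list(), altloc_policy)
                else:
                    chosen = bio_atom
                atoms.append(Atom(
                    name=chosen.get_name().strip(),
                    element=_guess_element(chosen),
                    position=np.array(chosen.get_coord(), dtype=float),
                    occupancy=min(max(chosen.get_occupancy() or 1.0, 0.0), 1.0),
                    altloc=(chosen.get_altloc() or "").strip(),
                ))
            heavy = [a for a in atoms if not a.is_hydrogen]
            if topology.is_water_name(resname) or hetflag == "W":
                role = Role.WATER
            elif hetflag.startswith("H"):
                role = Role.ION if len(heavy) == 1 else Role.LIGAND
            else:
                role = Role.PROTEIN
            formal = topology.ION_CHARGES.get(resname.upper(), 0) if role == Role.ION else 0
            residues.append(Residue(
                chain_id=bio_chain.id.strip() or "A",
                seq_number=int(seq),
                name=resname,
                atoms=atoms,
                role=role,
                insertion_code=(icode or "").strip(),
                formal_charge=formal,
            ))

    structure = Structure(residues, title=path.stem, source=str(path))
    if not structure.protein_residues:
        raise ContentError(f"{path}: no protein residues found")
    return structure


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write the structure in PDB v3 fixed-column format (ATOM/HETATM/TER/END)."""
    path = Path(path)
    lines: list[str] = []
    if structure.title:
        lines.append(f"TITLE     {structure.title[:60]}")
    serial = 1
    last_protein_chain: str | None = None

    def _ter():
        nonlocal serial
        lines.append(f"TER   {serial:5d}")
        serial += 1

    for res in structure.residues:
        if (last_protein_chain is not None
                and (res.role != Role.PROTEIN or res.chain_id != last_protein_chain)):
            _ter()
            last_protein_chain = None
        record = "ATOM  " if res.role == Role.PROTEIN else "HETATM"
        for atom in res.atoms:
            name = atom.name
            # column-13 alignment rule: 1-letter elements start in column 14
            padded = f" {name:<3s}" if len(atom.element) == 1 and len(name) < 4 else f"{name:<4s}"
            x, y, z = atom.position
            lines.append(
                f"{record}{serial:5d} {padded}{atom.altloc or ' ':1s}"
                f"{res.name:<3s} {res.chain_id[:1]}{res.seq_number:4d}"
                f"{res.insertion_code or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                f"          {atom.element:>2s}"
            )
            serial += 1
        if res.role == Role.PROTEIN:
            last_protein_chain = res.chain_id
    if last_protein_chain is not None:
        _ter()
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def write_charges_tsv(structure: Structure, path: str | Path) -> None:
    """Persist per-atom partial charges keyed by residue id and atom name."""
    rows = ["chain\tseq\ticode\tresname\tatom\tcharge"]
    for res in structure.residues:
        for atom in res.atoms:
            q = atom.partial_charge
            rows.append(
                f"{res.chain_id}\t{res.seq_number}\t{res.insertion_code}"
                f"\t{res.name}\t{atom.name}\t{'' if q is None else repr(q)}"
            )
    Path(path).write_text("\n".join(rows) + "\n")


def apply_charges_tsv(structure: Structure, path: str | Path) -> Structure:
    """Load charges written by :func:`write_charges_tsv` onto `structure`."""
    table: dict[tuple, float] = {}
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        chain, seq, icode, _resname, atom, q = line.split("\t")
        if q:
            table[(chain, int(seq), icode, atom)] = float(q)
    for res in structure.residues:
        for atom in res.atoms:
            key = (res.chain_id, res.seq_number, res.insertion_code, atom.name)
            if key in table:
                atom.partial_charge = table[key]
    return structure


# ---------------------------------------------------------------------------
# Protonation
# ---------------------------------------------------------------------------

def _neighbor_positions(res: Residue, names: Iterable[str],
                        prev_res: Residue | None, next_res: Residue | None):
    out = []
    for n in names:
        a = res.get_atom(n)
        if a is None:
            raise UnparameterizedResidueError(
                f"{res.name} {res.id}: missing heavy atom {n}"
            )
        out.append(a.position)
    return out


def _add_hydrogens_on(res: Residue, heavy_name: str, element: str,
                      bonded: list[np.ndarray], n_h: int, geometry: str,
                      reference: np.ndarray | None = None) -> None:
    center_atom = res.get_atom(heavy_name)
    if center_atom is None:
        raise UnparameterizedResidueError(f"{res.name} {res.id}: missing {heavy_name}")
    positions = complete_substituents(
        center_atom.position, bonded, n_h,
        constants.x_h_bond_length(element), geometry, reference,
    )
    for hname, pos in zip(topology.hydrogen_names(heavy_name, n_h), positions):
        res.atoms.append(Atom(hname, "H", pos, is_added_hydrogen=True))


def _protonate_protein_residue(res: Residue, prev_res: Residue | None,
                               next_res: Residue | None,
                               his_state: str) -> None:
    tmpl = topology.template_for(res.name)
    if tmpl is None:
        raise UnparameterizedResidueError(
            f"no protonation template for residue {res.name} at {res.id}"
        )
    n_h_overrides: dict[str, int] = {}
    formal = tmpl.formal_charge
    if res.name.upper() in ("HIS", "HIE", "HID", "HIP"):
        key = his_state if his_state in topology.HIS_VARIANTS else "HIE"
        n_h_overrides, formal = topology.HIS_VARIANTS[key]

    res.atoms = [a for a in res.atoms if not a.is_hydrogen]

    n = res.get_atom("N")
    ca = res.get_atom("CA")
    c = res.get_atom("C")
    o = res.get_atom("O")
    if n is None or ca is None or c is None or o is None:
        raise UnparameterizedResidueError(f"{res.name} {res.id}: incomplete backbone")

    is_nterm = prev_res is None
    is_cterm = next_res is None

    # backbone amide / ammonium hydrogens
    if is_nterm:
        if tmpl.backbone_n_h == 0:  # proline: secondary amine, 2 H -> +1
            cd = res.get_atom("CD")
            _add_hydrogens_on(res, "N", "N", [ca.position, cd.position], 2, "sp3")
        else:
            _add_hydrogens_on(res, "N", "N", [ca.position], 3, "sp3",
                              reference=c.position)
        formal += 1  # ammonium terminus (zwitterionic convention)
    elif tmpl.backbone_n_h > 0:
        prev_c = prev_res.get_atom("C")
        nbrs = [ca.position] + ([prev_c.position] if prev_c is not None else [])
        _add_hydrogens_on(res, "N", "N", nbrs, 1, "sp2")

    if is_cterm:
        if res.get_atom("OXT") is None:
            # complete the carboxylate: sp2 position opposite O around C
            pos = complete_substituents(c.position, [ca.position, o.position], 1,
                                        1.25, "sp2")[0]
            res.atoms.append(Atom("OXT", "O", pos, is_added_hydrogen=False))
        formal -= 1  # deprotonated carboxylate terminus

    # CA hydrogens (2 for GLY)
    ca_nbrs = [n.position, c.position]
    cb = res.get_atom("CB")
    if cb is not None:
        ca_nbrs.append(cb.position)
        _add_hydrogens_on(res, "CA", "C", ca_nbrs, 1, "sp3")
    else:
        _add_hydrogens_on(res, "CA", "C", ca_nbrs, 2, "sp3")

    # side chain
    for name, element, bonds, n_h, geometry in tmpl.side_chain:
        n_h = n_h_overrides.get(name, n_h)
        if n_h == 0:
            if res.get_atom(name) is None:
                raise UnparameterizedResidueError(
                    f"{res.name} {res.id}: missing heavy atom {name}")
            continue
        bonded = _neighbor_positions(res, bonds, prev_res, next_res)
        reference = None
        if len(bonds) == 1:
            # torsion reference: a neighbour of the single bonded atom
            parent = bonds[0]
            parent_tmpl = next((t for t in tmpl.side_chain if t[0] == parent), None)
            grand = None
            if parent_tmpl is not None:
                grand = next((b for b in parent_tmpl[2] if b != name), None)
            elif parent == "CA":
                grand = "N"
            if grand is not None and res.get_atom(grand) is not None:
                reference = res.get_atom(grand).position
        _add_hydrogens_on(res, name, element, bonded, n_h, geometry, reference)

    res.formal_charge = formal


def _protonate_water(res: Residue) -> None:
    res.atoms = [a for a in res.atoms if not a.is_hydrogen]
    oxygens = [a for a in res.atoms if a.element == "O"]
    if len(oxygens) != 1:
        raise ContentError(f"water {res.id} must have exactly one oxygen")
    positions = complete_substituents(oxygens[0].position, [], 2, constants.WATER_O_H, "sp3")
    for hname, pos in zip(("H1", "H2"), positions):
        res.atoms.append(Atom(hname, "H", pos, is_added_hydrogen=True))
    res.formal_charge = 0


def assign_protonation(
    structure: Structure,
    pH: float = 7.4,
    his_states: dict[ResidueId, str] | None = None,
    rebuild_hook: Callable[[Structure, Residue, list[str]], None] | None = None,
) -> Structure:
    """Assign pH-7.4 protonation states and place idealised hydrogens.

    Standard rules: ASP/GLU side chains deprotonated (-1), LYS/ARG protonated
    (+1), HIS neutral N-epsilon tautomer unless overridden via `his_states`
    (values "HIE"/"HID"/"HIP"), termini zwitterionic.  Existing protein and
    water hydrogens are replaced; every placed hydrogen is flagged
    ``is_added_hydrogen``.  Ligand and ion residues are left untouched
    (ligand protonation is accepted as prepared upstream).

    Missing side-chain heavy atoms raise
    :class:`UnparameterizedResidueError` unless a `rebuild_hook` is supplied;
    the hook receives (structure, residue, missing-atom-names) and must add
    the atoms in place.
    """
    if pH != 7.4:
        raise NotImplementedError(
            "only the pH 7.4 rule set is implemented; supply explicit "
            "his_states / formal charges for other conditions")
    his_states = {ResidueId(*k): v for k, v in (his_states or {}).items()}

    for chain_id in dict.fromkeys(r.chain_id for r in structure.protein_residues):
        chain = structure.chain(chain_id)
        for i, res in enumerate(chain):
            prev_res = chain[i - 1] if i > 0 else None
            next_res = chain[i + 1] if i + 1 < len(chain) else None
            tmpl = topology.template_for(res.name)
            if tmpl is not None:
                missing = [t[0] for t in tmpl.side_chain if res.get_atom(t[0]) is None]
                if missing and rebuild_hook is not None:
                    rebuild_hook(structure, res, missing)
                    missing = [t[0] for t in tmpl.side_chain if res.get_atom(t[0]) is None]
                if missing:
                    raise UnparameterizedResidueError(
                        f"{res.name} {res.id}: missing side-chain atoms "
                        f"{', '.join(missing)} (no rebuild hook)")
            _protonate_protein_residue(res, prev_res, next_res,
                                       his_states.get(res.id, "HIE"))
    for res in structure.waters:
        _protonate_water(res)
    return structure


def total_formal_charge(structure: Structure, roles: tuple[Role, ...] = (Role.PROTEIN,)) -> int:
    return sum(r.formal_charge for r in structure.residues if r.role in roles)


# ---------------------------------------------------------------------------
# XYZ export for fragment systems
# ---------------------------------------------------------------------------

def write_fragment_xyz(system, path: str | Path) -> None:
    """Write a fragment system as a standard XYZ file.

    Line 1: atom count; line 2: term label and net charge; then one
    ``element x y z`` line per atom at 1e-6 Angstrom precision.
    """
    atoms = list(system.atoms)
    if not atoms:
        raise MfccError("refusing to write an empty fragment system")
    lines = [str(len(atoms)), f"{system.term} charge={system.net_charge}"]
    for a in atoms:
        x, y, z = a.position
        el = a.element.capitalize()
        lines.append(f"{el:<2s} {x:16.8f} {y:16.8f} {z:16.8f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path: str | Path) -> list[Atom]:
    """Read an XYZ file back into a flat atom list (names = element symbols)."""
    lines = Path(path).read_text().splitlines()
    try:
        count = int(lines[0])
    except (IndexError, ValueError) as exc:
        raise MfccError(f"{path}: not an XYZ file") from exc
    atoms = []
    for i, line in enumerate(lines[2:2 + count]):
        el, x, y, z = line.split()
        atoms.append(Atom(f"{el.upper()}{i + 1}", el, np.array([float(x), float(y), float(z)])))
    if len(atoms) != count:
        raise MfccError(f"{path}: expected {count} atoms, found {len(atoms)}")
    return atoms
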