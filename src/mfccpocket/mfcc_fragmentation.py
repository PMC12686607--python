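"""Conjugated-caps fragment construction.

Each pocket residue R_i is embedded in its chemical context by two caps:
the entire chain-adjacent residues i-1 and i+1.  Cutting the two outer
peptide bonds (cap_prev to residue i-2, cap_next to residue i+2) leaves
dangling valences that are saturated by hydrogens placed along the former
bond vector at standard bond lengths (1.01 A from an amide N, 1.09 A from a
carbonyl C).  Chain termini yield single-sided caps that retain their real
terminal groups.

From a capped residue and the ligand, four fragment systems are assembled:

=========  =========================================================
term       contents
=========  =========================================================
L_CRC      ligand + cap_prev + R_i (+ its waters) + cap_next
L_CC       ligand + caps only (R_i removed, new cuts H-saturated)
CRC        cap_prev + R_i (+ waters) + cap_next
CC         caps only
=========  =========================================================

The interaction energy is then E(L_CRC) - E(L_CC) - E(CRC) + E(CC); for any
pairwise-additive backend with inert saturating hydrogens this collapses
exactly to the direct ligand <-> (R_i + waters) interaction.

Crystallographic waters are attached to pocket residues beforehand: a water
goes to the residue with the smallest donor-acceptor heavy-atom (N/O)
distance to its oxygen among residues within the H-bond cutoff, each water
to at most one residue.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from . import constants
from ._geometry import unit
from .errors import ChainDiscontinuityError, FragmentIntegrityError
from .structure_model import Atom, Residue, ResidueId, Role, Structure

TERMS = ("L_CRC", "L_CC", "CRC", "CC")


@dataclass
class CapHydrogen:
    """A saturating hydrogen with the provenance of the bond it heals."""

    atom: Atom
    bonded_to: tuple[ResidueId, str]   # heavy atom it is attached to
    replaces: tuple[ResidueId, str]    # neighbour removed by the cut
    side: str                          # outer_prev / outer_next / inner_prev / inner_next


@dataclass
class CappedResidue:
    residue_id: ResidueId
    cap_prev: list[Residue] = field(default_factory=list)
    cap_next: list[Residue] = field(default_factory=list)
    cap_hydrogens: list[CapHydrogen] = field(default_factory=list)
    attached_waters: list[ResidueId] = field(default_factory=list)


@dataclass
class FragmentSystem:
    """The atom set of one four-term component, ready for a backend."""

    term: str
    atoms: list[Atom] = field(default_factory=list)
    net_charge: int = 0
    multiplicity: int = 1
    residue_names: list[str] = field(default_factory=list)  # parallel to atoms
    label: str = ""

    def __post_init__(self):
        if self.term not in TERMS:
            raise ValueError(f"unknown fragment term {self.term!r}")


def _saturating_hydrogen(keep_atom: Atom, removed_atom: Atom,
                         keep_res: Residue, removed_res: Residue,
                         side: str) -> CapHydrogen:
    """Hydrogen replacing `removed_atom` along the former bond vector."""
    length = constants.x_h_bond_length(keep_atom.element)
    direction = unit(removed_atom.position - keep_atom.position)
    h = Atom(
        name="H" + ("N" if keep_atom.element == "N" else "C") + "C",
        element="H",
        position=keep_atom.position + length * direction,
        partial_charge=0.0,
        is_added_hydrogen=True,
        is_cap_hydrogen=True,
    )
    return CapHydrogen(h, (keep_res.id, keep_atom.name),
                       (removed_res.id, removed_atom.name), side)


def _check_peptide_bond(c_res: Residue, n_res: Residue) -> None:
    c = c_res.get_atom("C")
    n = n_res.get_atom("N")
    if c is None or n is None:
        raise ChainDiscontinuityError(
            f"missing backbone atoms between {c_res.id} and {n_res.id}")
    d = float(np.linalg.norm(c.position - n.position))
    if d > constants.PEPTIDE_BOND_MAX:
        raise ChainDiscontinuityError(
            f"peptide C-N distance {d:.2f} A between {c_res.id} and "
            f"{n_res.id} exceeds {constants.PEPTIDE_BOND_MAX} A")


def build_caps(structure: Structure, residue_id: ResidueId) -> CappedResidue:
    """Build the conjugated-caps system for one protein residue.

    cap_prev / cap_next are the entire chain-adjacent residues; the outer
    peptide bonds to residues i-2 and i+2 are cut and hydrogen-saturated.
    At chain termini the corresponding cap is empty and the real terminal
    group of R_i is retained.  Raises :class:`ChainDiscontinuityError` when
    an expected peptide bond is broken (C-N above 2.0 A).
    """
    residue_id = ResidueId(*residue_id)
    res = structure.get(residue_id)
    if res.role != Role.PROTEIN:
        raise FragmentIntegrityError(f"{residue_id} is not a protein residue")
    for name in ("N", "CA", "C"):
        if res.get_atom(name) is None:
            raise FragmentIntegrityError(f"{residue_id}: incomplete backbone ({name})")

    chain = structure.chain(residue_id.chain_id)
    idx = next(i for i, r in enumerate(chain) if r.id == residue_id)
    capped = CappedResidue(residue_id)

    if idx > 0:
        prev_res = chain[idx - 1]
        _check_peptide_bond(prev_res, res)
        capped.cap_prev = [prev_res]
        if idx > 1:  # cut the bond to residue i-2, saturate prev's N
            outer = chain[idx - 2]
            _check_peptide_bond(outer, prev_res)
            capped.cap_hydrogens.append(_saturating_hydrogen(
                prev_res.get_atom("N"), outer.get_atom("C"),
                prev_res, outer, "outer_prev"))
    if idx + 1 < len(chain):
        next_res = chain[idx + 1]
        _check_peptide_bond(res, next_res)
        capped.cap_next = [next_res]
        if idx + 2 < len(chain):  # cut the bond to residue i+2, saturate next's C
            outer = chain[idx + 2]
            _check_peptide_bond(next_res, outer)
            capped.cap_hydrogens.append(_saturating_hydrogen(
                next_res.get_atom("C"), outer.get_atom("N"),
                next_res, outer, "outer_next"))
    return capped


@dataclass
class WaterAssignment:
    """Water-to-residue H-bond assignment with the leftovers listed."""

    assigned: dict[ResidueId, ResidueId] = field(default_factory=dict)
    unassigned: list[ResidueId] = field(default_factory=list)

    def __getitem__(self, water_id):
        return self.assigned[ResidueId(*water_id)]

    def get(self, water_id, default=None):
        return self.assigned.get(ResidueId(*water_id), default)

    def items(self):
        return self.assigned.items()

    def waters_of(self, residue_id: ResidueId) -> list[ResidueId]:
        rid = ResidueId(*residue_id)
        return [w for w, r in self.assigned.items() if r == rid]


def assign_waters(structure: Structure, pocket: Iterable[ResidueId],
                  hbond_dmax: float = constants.HBOND_DMAX_DEFAULT) -> WaterAssignment:
    """Assign each crystallographic water to at most one pocket residue.

    The geometric H-bond criterion is the donor-acceptor heavy-atom
    distance: the water oxygen against the residue's N/O atoms.  The
    residue with the smallest such distance wins, provided it is within
    `hbond_dmax` (default 3.5 A); ties go to pocket order.  Waters with no
    qualifying residue are listed as unassigned.
    """
    if hbond_dmax <= 0:
        raise ValueError("hbond_dmax must be positive")
    pocket_residues = [structure.get(rid) for rid in pocket]
    polar: list[tuple[ResidueId, np.ndarray]] = []
    for res in pocket_residues:
        coords = [a.position for a in res.atoms if a.element in ("N", "O")]
        if coords:
            polar.append((res.id, np.array(coords)))

    out = WaterAssignment()
    for water in structure.waters:
        oxy = next((a for a in water.atoms if a.element == "O"), None)
        if oxy is None:
            out.unassigned.append(water.id)
            continue
        best: tuple[float, ResidueId] | None = None
        for rid, coords in polar:
            d = float(np.min(np.linalg.norm(coords - oxy.position, axis=1)))
            if d <= hbond_dmax and (best is None or d < best[0]):
                best = (d, rid)
        if best is None:
            out.unassigned.append(water.id)
        else:
            out.assigned[water.id] = best[1]
    return out


def _extend(system: FragmentSystem, residues: Iterable[Residue]) -> None:
    for res in residues:
        for atom in res.atoms:
            system.atoms.append(atom.copy())
            system.residue_names.append(res.name)
        system.net_charge += res.formal_charge


def build_fragment_systems(capped: CappedResidue, ligand_id: ResidueId,
                           structure: Structure) -> dict[str, FragmentSystem]:
    """Assemble the four fragment systems for one capped residue.

    The ligand appears in L_CRC and L_CC; R_i (with its attached waters) in
    L_CRC and CRC.  Removing R_i exposes the two inner peptide bonds, which
    are hydrogen-saturated by the same former-bond-vector rule used for the
    outer cuts.  Net charges are the sums of the constituent formal charges.
    """
    ligand = structure.get(ligand_id)
    if ligand.role != Role.LIGAND:
        raise FragmentIntegrityError(f"{ligand_id} does not have the ligand role")
    res = structure.get(capped.residue_id)
    waters = [structure.get(w) for w in capped.attached_waters]

    # inner saturating hydrogens, created only where a cap actually abuts R_i
    inner_h: list[CapHydrogen] = []
    if capped.cap_prev:
        prev_res = capped.cap_prev[-1]
        inner_h.append(_saturating_hydrogen(
            prev_res.get_atom("C"), res.get_atom("N"), prev_res, res, "inner_prev"))
    if capped.cap_next:
        next_res = capped.cap_next[0]
        inner_h.append(_saturating_hydrogen(
            next_res.get_atom("N"), res.get_atom("C"), next_res, res, "inner_next"))

    label = str(capped.residue_id)
    systems: dict[str, FragmentSystem] = {}
    for term in TERMS:
        sys_ = FragmentSystem(term=term, label=label)
        if term.startswith("L_"):
            _extend(sys_, [ligand])
        _extend(sys_, capped.cap_prev)
        if term in ("L_CRC", "CRC"):
            _extend(sys_, [res])
            _extend(sys_, waters)
        _extend(sys_, capped.cap_next)
        for ch in capped.cap_hydrogens:
            sys_.atoms.append(ch.atom.copy())
            sys_.residue_names.append("CAP")
        if term in ("L_CC", "CC"):
            for ch in inner_h:
                sys_.atoms.append(ch.atom.copy())
                sys_.residue_names.append("CAP")
        systems[term] = sys_

    n_ligand = len(ligand.atoms)
    diff_lcrc = len(systems["L_CRC"].atoms) - len(systems["CRC"].atoms)
    if diff_lcrc != n_ligand:
        raise FragmentIntegrityError(
            f"{label}: ligand atom bookkeeping broken ({diff_lcrc} != {n_ligand})")
    return systems
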