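"""Amino-acid topology templates.

For each of the 20 standard residues we record the side-chain heavy atoms,
their within-residue bonds, how many hydrogens each heavy atom carries at
physiological pH (7.4), the local geometry used for idealised hydrogen
placement, and the side-chain formal charge.  The defaults follow the usual
pH-7.4 conventions: ASP/GLU carboxylates deprotonated (-1), LYS ammonium and
ARG guanidinium protonated (+1), HIS neutral in the N-epsilon tautomer, CYS
and TYR protonated.

Histidine tautomers/protonation are selectable: "HIE" (neutral, H on NE2,
the default), "HID" (neutral, H on ND1) and "HIP" (+1, both ring nitrogens
protonated).
"""
from __future__ import annotations

from dataclasses import dataclass, field

#: (name, element, bonded heavy-atom names within the residue, n_H, geometry)
AtomDef = tuple[str, str, tuple[str, ...], int, str]


@dataclass(frozen=True)
class ResidueTemplate:
    name: str
    side_chain: tuple[AtomDef, ...]
    formal_charge: int = 0
    # extra hydrogens on backbone N (PRO has none; others one)
    backbone_n_h: int = 1


def _t(name, side_chain, charge=0, n_h=1) -> ResidueTemplate:
    return ResidueTemplate(name, tuple(side_chain), charge, n_h)


RESIDUE_TEMPLATES: dict[str, ResidueTemplate] = {
    "ALA": _t("ALA", [("CB", "C", ("CA",), 3, "sp3")]),
    "ARG": _t("ARG", [
        ("CB", "C", ("CA", "CG"), 2, "sp3"),
        ("CG", "C", ("CB", "CD"), 2, "sp3"),
        ("CD", "C", ("CG", "NE"), 2, "sp3"),
        ("NE", "N", ("CD", "CZ"), 1, "sp2"),
        ("CZ", "C", ("NE", "NH1", "NH2"), 0, "sp2"),
        ("NH1", "N", ("CZ",), 2, "sp2"),
        ("NH2", "N", ("CZ",), 2, "sp2"),
    ], charge=+1),
    "ASN": _t("ASN", [
        ("CB", "C", ("CA", "CG"), 2, "sp3"),
        ("CG", "C", ("CB", "OD1", "ND2"), 0, "sp2"),
        ("OD1", "O", ("CG",), 0, "sp2"),
        ("ND2", "N", ("CG",), 2, "sp2"),
    ]),
    "ASP": _t("ASP", [
        ("CB", "C", ("CA", "CG"), 2, "sp3"),
        ("CG", "C", ("CB", "OD1", "OD2"), 0, "sp2"),
        ("OD1", "O", ("CG",), 0, "sp2"),
        ("OD2", "O", ("CG",), 0, "sp2"),
    ], charge=-1),
    "CYS": _t("CYS", [
        ("CB", "C", ("CA", "SG"), 2, "sp3"),
        ("SG", "S", ("CB",), 1, "sp3"),
    ]),
    "GLN": _t("GLN", [
        ("CB", "C", ("CA", "CG"), 2, "sp3"),
        ("CG", "C", ("CB", "CD"), 2, "sp3"),
        ("CD", "C", ("CG", "OE1", "NE2"), 0, "sp2"),
        ("OE1", "O", ("CD",), 0, "sp2"),
        ("NE2", "N", ("CD",), 2, "sp2"),
    ]),
    "GLU": _t("GLU", [
        ("CB", "C", ("CA", "CG"), 2, "sp3"),
        ("CG", "C", ("CB", "CD"), 2, "sp3"),
        ("CD", "C", ("CG", "OE1", "OE2"), 0, "sp2"),
        ("OE1", "O", ("CD",), 0, "sp2"),
        ("OE2", "O", ("CD",), 0, "sp2"),
    ], charge=-1),
    "GLY": _t("GLY", []),
    "HIS": _t("HIS", [  # neutral N-epsilon tautomer (HIE)
        ("CB", "C", ("CA", "CG"), 2, "sp3"),
        ("CG", "C", ("CB", "ND1", "CD2"), 0, "sp2"),
        ("ND1", "N", ("CG", "CE1"), 0, "sp2"),
        ("CD2", "C", ("CG", "NE2"), 1, "sp2"),
        ("CE1", "C", ("ND1", "NE2"), 1, "sp2"),
        ("NE2", "N", ("CD2", "CE1"), 1, "sp2"),
    ]),
    "ILE": _t("ILE", [
        ("CB", "C", ("CA", "CG1", "CG2"), 1, "sp3"),
        ("CG1", "C", ("CB", "CD1"), 2, "sp3"),
        ("CG2", "C", ("CB",), 3, "sp3"),
        ("CD1", "C", ("CG1",), 3, "sp3"),
    ]),
    "LEU": _t("LEU", [
        ("CB", "C", ("CA", "CG"), 2, "sp3"),
        ("CG", "C", ("CB", "CD1", "CD2"), 1, "sp3"),
        ("CD1", "C", ("CG",), 3, "sp3"),
        ("CD2", "C", ("CG",), 3, "sp3"),
    ]),
    "LYS": _t("LYS", [
        ("CB", "C", ("CA", "CG"), 2, "sp3"),
        ("CG", "C", ("CB", "CD"), 2, "sp3"),
        ("CD", "C", ("CG", "CE"), 2, "sp3"),
        ("CE", "C", ("CD", "NZ"), 2, "sp3"),
        ("NZ", "N", ("CE",), 3, "sp3"),
    ], charge=+1),
    "MET": _t("MET", [
        ("CB", "C", ("CA", "CG"), 2, "sp3"),
        ("CG", "C", ("CB", "SD"), 2, "sp3"),
        ("SD", "S", ("CG", "CE"), 0, "sp3"),
        ("CE", "C", ("SD",), 3, "sp3"),
    ]),
    "PHE": _t("PHE", [
        ("CB", "C", ("CA", "CG"), 2, "sp3"),
        ("CG", "C", ("CB", "CD1", "CD2"), 0, "sp2"),
        ("CD1", "C", ("CG", "CE1"), 1, "sp2"),
        ("CD2", "C", ("CG", "CE2"), 1, "sp2"),
        ("CE1", "C", ("CD1", "CZ"), 1, "sp2"),
        ("CE2", "C", ("CD2", "CZ"), 1, "sp2"),
        ("CZ", "C", ("CE1", "CE2"), 1, "sp2"),
    ]),
    "PRO": _t("PRO", [
        ("CB", "C", ("CA", "CG"), 2, "sp3"),
        ("CG", "C", ("CB", "CD"), 2, "sp3"),
        ("CD", "C", ("CG", "N"), 2, "sp3"),
    ], n_h=0),
    "SER": _t("SER", [
        ("CB", "C", ("CA", "OG"), 2, "sp3"),
        ("OG", "O", ("CB",), 1, "sp3"),
    ]),
    "THR": _t("THR", [
        ("CB", "C", ("CA", "OG1", "CG2"), 1, "sp3"),
        ("OG1", "O", ("CB",), 1, "sp3"),
        ("CG2", "C", ("CB",), 3, "sp3"),
    ]),
    "TRP": _t("TRP", [
        ("CB", "C", ("CA", "CG"), 2, "sp3"),
        ("CG", "C", ("CB", "CD1", "CD2"), 0, "sp2"),
        ("CD1", "C", ("CG", "NE1"), 1, "sp2"),
        ("CD2", "C", ("CG", "CE2", "CE3"), 0, "sp2"),
        ("NE1", "N", ("CD1", "CE2"), 1, "sp2"),
        ("CE2", "C", ("NE1", "CD2", "CZ2"), 0, "sp2"),
        ("CE3", "C", ("CD2", "CZ3"), 1, "sp2"),
        ("CZ2", "C", ("CE2", "CH2"), 1, "sp2"),
        ("CZ3", "C", ("CE3", "CH2"), 1, "sp2"),
        ("CH2", "C", ("CZ2", "CZ3"), 1, "sp2"),
    ]),
    "TYR": _t("TYR", [
        ("CB", "C", ("CA", "CG"), 2, "sp3"),
        ("CG", "C", ("CB", "CD1", "CD2"), 0, "sp2"),
        ("CD1", "C", ("CG", "CE1"), 1, "sp2"),
        ("CD2", "C", ("CG", "CE2"), 1, "sp2"),
        ("CE1", "C", ("CD1", "CZ"), 1, "sp2"),
        ("CE2", "C", ("CD2", "CZ"), 1, "sp2"),
        ("CZ", "C", ("CE1", "CE2", "OH"), 0, "sp2"),
        ("OH", "O", ("CZ",), 1, "sp3"),
    ]),
    "VAL": _t("VAL", [
        ("CB", "C", ("CA", "CG1", "CG2"), 1, "sp3"),
        ("CG1", "C", ("CB",), 3, "sp3"),
        ("CG2", "C", ("CB",), 3, "sp3"),
    ]),
}

# Histidine variants: (per-atom n_H overrides, formal charge)
HIS_VARIANTS: dict[str, tuple[dict[str, int], int]] = {
    "HIE": ({"ND1": 0, "NE2": 1}, 0),
    "HID": ({"ND1": 1, "NE2": 0}, 0),
    "HIP": ({"ND1": 1, "NE2": 1}, +1),
}

WATER_NAMES = {"HOH", "WAT", "H2O", "TIP", "TIP3", "SOL", "DOD"}

# Single-atom HETATM species treated as ions, with their formal charges.
ION_CHARGES = {
    "ZN": 2, "MG": 2, "CA": 2, "MN": 2, "FE": 2, "NA": 1, "K": 1,
    "CL": -1, "BR": -1, "I": -1, "CU": 2, "NI": 2, "CO": 2, "CD": 2,
}


def hydrogen_names(heavy_name: str, n_h: int) -> list[str]:
    """PDB-v3-style hydrogen names for `n_h` hydrogens on `heavy_name`.

    CB -> HB (HB1, HB2 ... when several), CG1 -> HG11/HG12/..., N -> H,
    CA -> HA.  Backbone amide hydrogens are named "H"; N-terminal ammonium
    hydrogens are H1/H2/H3.
    """
    suffix = heavy_name[1:] if len(heavy_name) > 1 else ""
    base = "H" + suffix
    if heavy_name == "N":
        return ["H"] if n_h == 1 else [f"H{i}" for i in range(1, n_h + 1)]
    if n_h == 1:
        return [base]
    return [f"{base}{i}" for i in range(1, n_h + 1)]


def is_water_name(resname: str) -> bool:
    return resname.strip().upper() in WATER_NAMES


def template_for(resname: str) -> ResidueTemplate | None:
    return RESIDUE_TEMPLATES.get(resname.strip().upper())
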