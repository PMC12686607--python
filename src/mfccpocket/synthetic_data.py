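"""Desk-scale synthetic complexes and independent oracles.

The generator emulates the class of inputs the pipeline assumes — a small
hydrogen-complete peptide in an extended conformation, a rigid polar
small-molecule ligand placed at a controlled distance, and waters parked in
H-bond range of chosen residues — with partial charges assigned so that the
classical backend has everything it needs.  It makes no attempt at
crystallographic realism: the point is that every energetic claim of the
fragment combination can be checked against a brute-force pairwise sum.

``oracle_pairwise`` is that check: a plain double loop over ligand and
residue atoms sharing only the pair potential with the main code path, no
fragment logic.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants
from ._geometry import complete_substituents, place_from_internal, unit
from .energy_backends import BackendSpec, coulomb_lj_pair
from .errors import GenerationError
from .mfcc_fragmentation import assign_waters
from .parameters import DEFAULT_TABLE
from .pocket_shells import ShellProfile
from .structure_model import (
    Atom, Residue, ResidueId, Role, Structure, assign_protonation,
)

GENERATOR_RESIDUES = ("GLY", "ALA", "ASP", "LYS", "SER", "HIS", "PRO")

# beta-strand backbone torsions: extended but non-degenerate frames
PHI, PSI, OMEGA = -135.0, 135.0, 180.0

# minimum allowed ligand-protein all-atom distance when placing the ligand
_MIN_CONTACT = 1.7


@dataclass(frozen=True)
class ToySpec:
    """Stated world of one synthetic complex; the seed fixes everything."""

    n_residues: int = 8
    sequence: tuple[str, ...] | None = None
    ligand_net_charge: int = 0
    ligand_distance: float = 5.0
    n_waters: int = 2
    seed: int = 0
    jitter: float = 0.0
    charge_noise: float = 0.05
    water_targets: tuple[int, ...] | None = None  # 1-based residue indices
    anchor_index: int | None = None               # 1-based; default middle

    def __post_init__(self):
        if self.n_residues < 3:
            raise ValueError("need at least 3 residues so one has both caps")
        if self.sequence is not None:
            if len(self.sequence) != self.n_residues:
                raise ValueError("sequence length must match n_residues")
            bad = set(self.sequence) - set(GENERATOR_RESIDUES)
            if bad:
                raise ValueError(
                    f"generator supports {GENERATOR_RESIDUES}, not {sorted(bad)}")


def default_sequence(n: int) -> tuple[str, ...]:
    """Poly-ALA with ASP/LYS alternating every fourth position (from #3)."""
    seq = ["ALA"] * n
    special = ("ASP", "LYS")
    for j, i in enumerate(range(2, n, 4)):
        seq[i] = special[j % 2]
    return tuple(seq)


# ---------------------------------------------------------------------------
# peptide construction
# ---------------------------------------------------------------------------

_BB = {  # bond lengths / angles of the peptide unit
    "n_ca": 1.458, "ca_c": 1.525, "c_n": 1.329, "c_o": 1.231,
    "ang_c_n_ca": 121.7, "ang_n_ca_c": 111.2, "ang_ca_c_n": 116.2,
}


def _build_backbone(n: int) -> list[dict[str, np.ndarray]]:
    res: list[dict[str, np.ndarray]] = []
    n0 = np.zeros(3)
    ca0 = np.array([_BB["n_ca"], 0.0, 0.0])
    ang = np.deg2rad(_BB["ang_n_ca_c"])
    c0 = ca0 + _BB["ca_c"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    res.append({"N": n0, "CA": ca0, "C": c0})
    for _ in range(1, n):
        p = res[-1]
        nn = place_from_internal(p["N"], p["CA"], p["C"],
                                 _BB["c_n"], _BB["ang_ca_c_n"], PSI)
        ca = place_from_internal(p["CA"], p["C"], nn,
                                 _BB["n_ca"], _BB["ang_c_n_ca"], OMEGA)
        c = place_from_internal(p["C"], nn, ca,
                                _BB["ca_c"], _BB["ang_n_ca_c"], PHI)
        res.append({"N": nn, "CA": ca, "C": c})
    # carbonyl oxygens: sp2 on C, anti to the next amide nitrogen
    for i, r in enumerate(res):
        if i + 1 < n:
            next_n = res[i + 1]["N"]
        else:  # virtual next N just to orient the terminal carbonyl
            next_n = place_from_internal(r["N"], r["CA"], r["C"],
                                         _BB["c_n"], _BB["ang_ca_c_n"], PSI)
        r["O"] = complete_substituents(r["C"], [r["CA"], next_n], 1, _BB["c_o"], "sp2")[0]
    return res


def _side_chain(name: str, bb: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    if name == "GLY":
        return {}
    n, ca, c = bb["N"], bb["CA"], bb["C"]
    cb = complete_substituents(ca, [n, c], 2, 1.53, "sp3")[0]
    out = {"CB": cb}
    if name == "ALA":
        return out
    if name == "SER":
        out["OG"] = place_from_internal(n, ca, cb, 1.42, 110.5, 180.0)
        return out
    if name == "ASP":
        cg = place_from_internal(n, ca, cb, 1.52, 112.6, 180.0)
        od = complete_substituents(cg, [cb], 2, 1.25, "sp2", reference=ca)
        out.update({"CG": cg, "OD1": od[0], "OD2": od[1]})
        return out
    if name == "LYS":
        cg = place_from_internal(n, ca, cb, 1.52, 111.0, 180.0)
        cd = place_from_internal(ca, cb, cg, 1.52, 111.0, 180.0)
        ce = place_from_internal(cb, cg, cd, 1.52, 111.0, 180.0)
        nz = place_from_internal(cg, cd, ce, 1.47, 111.0, 180.0)
        out.update({"CG": cg, "CD": cd, "CE": ce, "NZ": nz})
        return out
    if name == "HIS":
        # planar imidazole: regular pentagon in the plane spanned by the
        # CB->CG bond and the CA-CB-CG normal, centroid along CB->CG
        cg = place_from_internal(n, ca, cb, 1.50, 113.0, 180.0)
        u = unit(cg - cb)
        nrm = unit(np.cross(cg - cb, ca - cb))
        m = np.cross(nrm, u)
        radius = 1.37 / (2.0 * np.sin(np.deg2rad(36.0)))
        centroid = cg + radius * u
        ring = {}
        for atom_name, phi in (("ND1", 72.0), ("CE1", 144.0),
                               ("NE2", 216.0), ("CD2", 288.0)):
            a = np.deg2rad(phi)
            ring[atom_name] = centroid + radius * (-np.cos(a) * u + np.sin(a) * m)
        out["CG"] = cg
        out.update(ring)
        return out
    if name == "PRO":
        # approximate (planar-ish) pyrrolidine ring closing CB->CG->CD->N
        cg = place_from_internal(n, ca, cb, 1.52, 103.0, 35.0)
        cd = place_from_internal(ca, cb, cg, 1.52, 103.0, -35.0)
        out.update({"CG": cg, "CD": cd})
        return out
    raise GenerationError(f"no side-chain builder for {name}")


# ---------------------------------------------------------------------------
# ligand template: N-methyl glycolamide, HO-CH2-C(=O)-NH-CH3
# ---------------------------------------------------------------------------

#: heavy-atom -> ligand region (three labelled regions for contact tests)
LIGAND_REGIONS: dict[str, str] = {
    "C2": "i", "O2": "i",
    "C1": "ii", "O1": "ii",
    "N1": "iii", "C3": "iii",
}

_LIGAND_BASE_CHARGES: dict[str, float] = {
    "C1": 0.52, "O1": -0.50, "N1": -0.46, "HN": 0.32,
    "C3": -0.10, "H31": 0.08, "H32": 0.08, "H33": 0.08,
    "C2": 0.08, "H21": 0.05, "H22": 0.05, "O2": -0.62, "HO2": 0.40,
}


def ligand_region_map() -> dict[str, str]:
    return dict(LIGAND_REGIONS)


def _build_ligand_template() -> list[tuple[str, str, np.ndarray]]:
    c1 = np.zeros(3)
    o1 = np.array([0.0, 1.23, 0.0])
    n1 = 1.33 * np.array([np.cos(np.deg2rad(-30.0)), np.sin(np.deg2rad(-30.0)), 0.0])
    c2 = 1.52 * np.array([np.cos(np.deg2rad(210.0)), np.sin(np.deg2rad(210.0)), 0.0])
    o2 = place_from_internal(n1, c1, c2, 1.42, 109.5, 65.0)
    c3 = place_from_internal(o1, c1, n1, 1.45, 120.0, 180.0)
    hn = complete_substituents(n1, [c1, c3], 1, constants.BOND_N_H, "sp2")[0]
    h2 = complete_substituents(c2, [c1, o2], 2, constants.BOND_C_H, "sp3")
    ho2 = complete_substituents(o2, [c2], 1, constants.BOND_O_H, "sp3", reference=c1)[0]
    h3 = complete_substituents(c3, [n1], 3, constants.BOND_C_H, "sp3", reference=c1)
    atoms = [
        ("C1", "C", c1), ("O1", "O", o1), ("N1", "N", n1), ("HN", "H", hn),
        ("C2", "C", c2), ("H21", "H", h2[0]), ("H22", "H", h2[1]),
        ("O2", "O", o2), ("HO2", "H", ho2),
        ("C3", "C", c3), ("H31", "H", h3[0]), ("H32", "H", h3[1]), ("H33", "H", h3[2]),
    ]
    return atoms


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from the seeded generator."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def make_toy_complex(spec: ToySpec) -> Structure:
    """Generate a hydrogen-complete, charge-assigned synthetic complex.

    An extended peptide (idealised backbone, template side chains), a rigid
    polar ligand with its centroid `ligand_distance` from the anchor
    residue's CA along the local backbone-plane normal, and waters placed
    2.85 A from the backbone carbonyl oxygens of the target residues.
    Deterministic given the spec (byte-identical PDB output for equal
    seeds).  Raises :class:`GenerationError` on unavoidable steric clashes.
    """
    rng = np.random.default_rng(spec.seed)
    seq = spec.sequence or default_sequence(spec.n_residues)

    backbone = _build_backbone(spec.n_residues)
    residues: list[Residue] = []
    for i, (name, bb) in enumerate(zip(seq, backbone)):
        coords = dict(bb)
        coords.update(_side_chain(name, bb))
        atoms = [Atom(an, an[0], pos + rng.normal(0.0, spec.jitter, 3)
                      if spec.jitter > 0 else pos.copy())
                 for an, pos in coords.items()]
        residues.append(Residue("A", i + 1, name, atoms, Role.PROTEIN))

    # waters near the carbonyl oxygens of the target residues
    targets = spec.water_targets or tuple(
        2 + 2 * (k % max(1, (spec.n_residues - 1) // 2))
        for k in range(spec.n_waters))
    waters: list[Residue] = []
    for k in range(spec.n_waters):
        t = targets[k % len(targets)] - 1
        if not 0 <= t < spec.n_residues:
            raise GenerationError(f"water target residue {t + 1} out of range")
        r = backbone[t]
        direction = unit(r["O"] - r["C"])
        pos = r["O"] + 2.85 * direction
        if spec.jitter > 0:
            pos = pos + rng.normal(0.0, min(spec.jitter, 0.15), 3)
        waters.append(Residue("W", 301 + k, "HOH",
                              [Atom("O", "O", pos)], Role.WATER))

    # hydrogens/termini first so the ligand is placed against the full
    # all-atom environment
    environment = Structure(residues + waters,
                            title=f"toy complex ({spec.n_residues} residues)",
                            source=f"synthetic:seed={spec.seed}")
    assign_protonation(environment)
    env_pts = np.vstack([[a.position for a in res.atoms]
                         for res in environment.residues])

    # ligand: rigid template, centroid at ligand_distance from the anchor CA
    # along the local backbone-plane normal; orientations are drawn from the
    # seeded generator until one is free of steric clashes
    anchor_i = (spec.anchor_index - 1 if spec.anchor_index is not None
                else spec.n_residues // 2)
    bb = backbone[anchor_i]
    normal = unit(np.cross(bb["N"] - bb["CA"], bb["C"] - bb["CA"]))
    target = bb["CA"] + spec.ligand_distance * normal
    template = _build_ligand_template()
    base_pts = np.array([p for _, _, p in template])
    from scipy.spatial.distance import cdist

    pts = None
    for _attempt in range(60):
        rot = _random_rotation(rng)
        cand = base_pts @ rot.T
        cand = cand + (target - cand.mean(axis=0))
        if cdist(env_pts, cand).min() >= _MIN_CONTACT:
            pts = cand
            break
    if pts is None:
        raise GenerationError(
            "no clash-free ligand orientation found; increase "
            "ligand_distance or change the anchor")
    lig_atoms = [Atom(an, el, pts[k]) for k, (an, el, _) in enumerate(template)]
    ligand = Residue("L", 201, "LIG", lig_atoms, Role.LIGAND,
                     formal_charge=spec.ligand_net_charge)

    structure = Structure(environment.residues[:spec.n_residues] + [ligand] + waters,
                          title=environment.title, source=environment.source)

    # charges: explicit noisy template for the ligand, table for the rest
    noise = rng.normal(0.0, spec.charge_noise, len(lig_atoms))
    raw = np.array([_LIGAND_BASE_CHARGES[a.name] for a in lig_atoms]) + noise
    raw += (spec.ligand_net_charge - raw.sum()) / len(raw)
    for a, q in zip(lig_atoms, raw):
        a.partial_charge = float(q)
    DEFAULT_TABLE.assign_charges(structure)
    return structure


def toy_ligand_id() -> ResidueId:
    return ResidueId("L", 201)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def oracle_pairwise(structure: Structure, ligand_id: ResidueId,
                    residue_id: ResidueId, dielectric: float,
                    include_waters: bool = True,
                    hbond_dmax: float = constants.HBOND_DMAX_DEFAULT,
                    include_lj: bool = True,
                    pocket: list[ResidueId] | None = None,
                    water_ids: list[ResidueId] | None = None) -> float:
    """Direct ligand <-> residue(+waters) pairwise interaction sum.

    A deliberately naive double loop over atom pairs using only the pair
    potential — no fragments, no caps — serving as the independent check of
    the four-term combination.  Waters enter either explicitly via
    `water_ids` or through the same nearest-residue H-bond assignment the
    pipeline uses (over `pocket`, defaulting to all protein residues).
    """
    ligand = structure.get(ligand_id)
    target = structure.get(residue_id)
    group: list[Residue] = [target]
    if include_waters:
        if water_ids is None:
            pocket = pocket or [r.id for r in structure.protein_residues]
            water_ids = assign_waters(structure, pocket, hbond_dmax).waters_of(residue_id)
        group += [structure.get(w) for w in water_ids]

    table = DEFAULT_TABLE
    total = 0.0
    for la in ligand.atoms:
        sa, ea = table.lj(ligand.name, la)
        for res in group:
            for ra in res.atoms:
                sb, eb = table.lj(res.name, ra)
                d = float(np.linalg.norm(la.position - ra.position))
                total += coulomb_lj_pair(
                    la.partial_charge, ra.partial_charge, d,
                    sa, sb, ea, eb, dielectric, include_lj)
    return total


def oracle_total(structure: Structure, ligand_id: ResidueId,
                 dielectric: float, include_lj: bool = True) -> float:
    """Whole-protein ligand interaction: sum of per-residue oracle terms."""
    return sum(
        oracle_pairwise(structure, ligand_id, r.id, dielectric,
                        include_waters=False, include_lj=include_lj)
        for r in structure.protein_residues)


# ---------------------------------------------------------------------------
# synthetic convergence profiles
# ---------------------------------------------------------------------------

@dataclass
class SyntheticProfile:
    profile: ShellProfile
    true_converged_radius: float | None


def make_energy_profile(plateau: float = -30.0, approach_rate: float = 0.5,
                        n_points: int = 12, noise_sd: float = 0.0,
                        seed: int = 0,
                        threshold: float = constants.CONVERGENCE_THRESHOLD
                        ) -> SyntheticProfile:
    """Geometric approach to a plateau with a known convergence point.

    Cumulative totals E_k = plateau * (1 - rate^k) for k = 1..n on the
    half-Angstrom grid, plus optional Gaussian noise.  The ground-truth
    radius is derived in closed form from the noiseless series:
    |E_{k+1} - E_k| / |E_{k+1}| = (1 - rate) rate^k / |1 - rate^{k+1}|,
    first k below `threshold` (None when the plateau is zero, by the
    nonzero-total guard).
    """
    if n_points < 3:
        raise ValueError("need at least 3 points")
    if not 0.0 < approach_rate < 1.0:
        raise ValueError("approach_rate must be in (0, 1)")
    rng = np.random.default_rng(seed)
    k = np.arange(1, n_points + 1)
    energies = plateau * (1.0 - approach_rate ** k)
    if noise_sd > 0:
        energies = energies + rng.normal(0.0, noise_sd, n_points)
    radii = constants.SHELL_STEP * k
    profile = ShellProfile(radii, energies, k, threshold=threshold)

    true_radius: float | None = None
    if plateau != 0.0:
        for kk in range(1, n_points):
            ratio = ((1.0 - approach_rate) * approach_rate ** kk
                     / abs(1.0 - approach_rate ** (kk + 1)))
            if ratio < threshold:
                true_radius = float(constants.SHELL_STEP * kk)
                break
    return SyntheticProfile(profile, true_radius)
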