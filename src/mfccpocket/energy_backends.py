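"""Total-energy evaluation backends for fragment systems.

Two backends share one contract:

* ``classical_pairwise`` — a screened-Coulomb + Lennard-Jones pairwise sum
  evaluated in process.  It is strictly additive over atom pairs, which is
  what makes the four-term conjugated-caps combination collapse exactly to
  the direct ligand-residue interaction (the package's headline invariant).
  The uniform dielectric divides the Coulomb term, a deliberately simple
  continuum stand-in for CPCM at desk scale.

* ``qm_deck`` — no energy is computed in process; instead a Gaussian-style
  single-point input deck is written per fragment system for an external
  DFT engine, and the resulting logs are parsed back (final SCF energy in
  hartree, converted at 627.509474 kcal/mol per hartree).

Saturating cap hydrogens are treated as spectators by the classical backend
(zero charge, zero LJ): they are an artifact of valence completion, and
making them inert keeps the cap-term cancellation exact.  QM decks include
them as real hydrogens.
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .constants import COULOMB_KCAL, HARTREE_TO_KCAL
from .errors import DeckError, QMLogError, SCFConvergenceError
from .parameters import DEFAULT_TABLE, ParameterTable, resolve_charge


@dataclass
class BackendSpec:
    """How fragment total energies are obtained.

    kind: ``classical_pairwise`` or ``qm_deck``.
    dielectric: uniform screening constant (the study sweeps 10 and 40).
    functional / basis / solvent_model: route labels for the deck writer.
    parameters: non-bonded table for the classical backend.
    include_lj: disable to get a pure screened-Coulomb model.
    """

    kind: str = "classical_pairwise"
    dielectric: float = 40.0
    functional: str = "B97D"
    basis: str = "6-311+G(d,p)"
    solvent_model: str = "CPCM"
    parameters: ParameterTable = field(default_factory=lambda: DEFAULT_TABLE)
    include_lj: bool = True

    def __post_init__(self):
        if self.kind not in ("classical_pairwise", "qm_deck"):
            raise ValueError(f"unknown backend kind {self.kind!r}")
        if self.dielectric < 1.0:
            raise ValueError("dielectric must be >= 1")


def coulomb_lj_pair(qa: float, qb: float, d: float,
                    sigma_a: float, sigma_b: float,
                    eps_a: float, eps_b: float,
                    dielectric: float, include_lj: bool = True) -> float:
    """Interaction energy (kcal/mol) of one atom pair.

    Screened Coulomb 332.0637 * qa*qb / (dielectric * d) plus, optionally,
    Lennard-Jones 4*eps*((sigma/d)^12 - (sigma/d)^6) with Lorentz-Berthelot
    combining (arithmetic sigma, geometric epsilon).
    """
    e = COULOMB_KCAL * qa * qb / (dielectric * d)
    if include_lj:
        eps = np.sqrt(eps_a * eps_b)
        if eps > 0.0:
            sr6 = ((sigma_a + sigma_b) / (2.0 * d)) ** 6
            e += 4.0 * eps * (sr6 * sr6 - sr6)
    return e


def _gather_parameters(system, spec: BackendSpec):
    atoms = list(system.atoms)
    n = len(atoms)
    q = np.empty(n)
    sig = np.empty(n)
    eps = np.empty(n)
    labels = getattr(system, "residue_names", None) or [""] * n
    for i, atom in enumerate(atoms):
        q[i] = resolve_charge(atom, context=str(getattr(system, "term", "")))
        sig[i], eps[i] = spec.parameters.lj(labels[i], atom)
    pos = np.array([a.position for a in atoms]).reshape(n, 3)
    return pos, q, sig, eps


def evaluate_classical(system, spec: BackendSpec) -> float:
    """Pairwise-additive total energy of a fragment system, in kcal/mol.

    Sums the screened Coulomb + LJ pair potential over all unique atom
    pairs.  Atom pairs closer than 0.5 A trigger a clash warning but the
    energy is still returned.  Systems with fewer than two atoms have no
    pairs and evaluate to zero.
    """
    atoms = list(system.atoms)
    if len(atoms) < 2:
        return 0.0
    pos, q, sig, eps = _gather_parameters(system, spec)
    d = pdist(pos)
    if np.any(d < 0.5):
        warnings.warn(
            f"{getattr(system, 'term', 'system')}: atom pair closer than 0.5 A",
            RuntimeWarning, stacklevel=2)
    iu, ju = np.triu_indices(len(atoms), k=1)
    e_coul = COULOMB_KCAL / spec.dielectric * float(np.sum(q[iu] * q[ju] / d))
    if not spec.include_lj:
        return e_coul
    eps_ij = np.sqrt(eps[iu] * eps[ju])
    sr6 = ((sig[iu] + sig[ju]) / (2.0 * d)) ** 6
    e_lj = float(np.sum(4.0 * eps_ij * (sr6 * sr6 - sr6)))
    return e_coul + e_lj


def interaction_between(atoms_a, atoms_b, spec: BackendSpec,
                        residue_names_a=None, residue_names_b=None) -> float:
    """Cross-interaction energy between two disjoint atom groups."""
    if not atoms_a or not atoms_b:
        return 0.0

    class _G:
        def __init__(self, atoms, names):
            self.atoms = atoms
            self.residue_names = names
            self.term = "cross"

    ga = _G(list(atoms_a), residue_names_a)
    gb = _G(list(atoms_b), residue_names_b)
    pa, qa, sa, ea = _gather_parameters(ga, spec)
    pb, qb, sb, eb = _gather_parameters(gb, spec)
    from scipy.spatial.distance import cdist

    d = cdist(pa, pb)
    e = COULOMB_KCAL / spec.dielectric * float(np.sum(np.outer(qa, qb) / d))
    if spec.include_lj:
        eps_ij = np.sqrt(np.outer(ea, eb))
        sr6 = ((sa[:, None] + sb[None, :]) / (2.0 * d)) ** 6
        e += float(np.sum(4.0 * eps_ij * (sr6 * sr6 - sr6)))
    return e


# ---------------------------------------------------------------------------
# QM deck writer / log parser
# ---------------------------------------------------------------------------

def write_qm_deck(system, spec: BackendSpec, path: str | Path) -> None:
    """Write a Gaussian-style single-point input deck for one fragment.

    The route line carries the functional, basis set, and a CPCM-type
    implicit-solvent keyword whose dielectric is passed via the ``Read``
    block (``eps=<value>``).  Charge and multiplicity come from the
    fragment system.
    """
    if spec.kind != "qm_deck":
        raise DeckError("write_qm_deck requires a qm_deck backend spec")
    charge = getattr(system, "net_charge", 0)
    if not float(charge).is_integer():
        raise DeckError(f"non-integer fragment charge {charge!r}")
    multiplicity = getattr(system, "multiplicity", 1)
    path = Path(path)
    lines = [
        f"%chk={path.stem}.chk",
        f"#P {spec.functional}/{spec.basis} SCRF=({spec.solvent_model},Read) SP",
        "",
        f"{getattr(system, 'term', 'fragment')} single point",
        "",
        f"{int(charge)} {int(multiplicity)}",
    ]
    for atom in system.atoms:
        x, y, z = atom.position
        lines.append(f" {atom.element.capitalize():<2s} {x:14.8f} {y:14.8f} {z:14.8f}")
    lines += ["", f"eps={spec.dielectric:g}", "", ""]
    path.write_text("\n".join(lines))


_SCF_RE = re.compile(r"SCF Done:[^=]*=\s*(-?\d+\.\d+(?:[DdEe][+-]?\d+)?)")
_FAIL_MARKERS = ("Convergence failure", "SCF has not converged",
                 "Error termination")


def parse_qm_energy(log_text: str) -> float:
    """Final SCF energy of a QM log, converted from hartree to kcal/mol.

    The last ``SCF Done`` line wins (optimisation traces print several).
    Raises :class:`SCFConvergenceError` if the log carries a non-convergence
    marker and :class:`QMLogError` if no energy line is present.
    """
    for marker in _FAIL_MARKERS:
        if marker in log_text:
            raise SCFConvergenceError(f"QM log reports: {marker}")
    matches = _SCF_RE.findall(log_text)
    if not matches:
        raise QMLogError("no final SCF energy line found in log")
    hartree = float(matches[-1].replace("D", "E").replace("d", "e"))
    return hartree * HARTREE_TO_KCAL


def engine_stamp(log_text: str) -> str | None:
    """Engine name/version string from a log banner, if recognisable."""
    m = re.search(r"(Gaussian\s+\d+\w*[:,]?\s*[^\n]*)", log_text)
    if m:
        return m.group(1).strip().rstrip(",")
    m = re.search(r"(ORCA[^\n]*\d[^\n]*)", log_text)
    return m.group(1).strip() if m else None
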