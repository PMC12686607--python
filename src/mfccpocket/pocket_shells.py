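"""Radial-shell selection of binding-pocket residues and energy convergence.

Residues are selected by minimum ligand-to-residue atom distance with a
closed boundary (d <= r), on the half-Angstrom grid r = n/2.  The cumulative
total binding energy over shells converges at the first radius where the
next shell changes the total by less than a relative threshold (10% by
default); the relative change is measured against the newer total.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy.spatial.distance import cdist

from . import constants
from .errors import CompletenessError, InsufficientDataError
from .structure_model import Residue, ResidueId, Role, Structure


@dataclass
class ShellProfile:
    """Cumulative binding energy and residue counts on the r = n/2 grid."""

    radii: np.ndarray
    cumulative_energy: np.ndarray
    residue_counts: np.ndarray
    converged_radius: float | None = None
    threshold: float = constants.CONVERGENCE_THRESHOLD
    convention: str = "relative change |E_next - E| / |E_next| against the newer total"

    def __post_init__(self):
        self.radii = np.asarray(self.radii, dtype=float)
        self.cumulative_energy = np.asarray(self.cumulative_energy, dtype=float)
        self.residue_counts = np.asarray(self.residue_counts, dtype=int)
        if not (len(self.radii) == len(self.cumulative_energy) == len(self.residue_counts)):
            raise ValueError("profile arrays must be aligned")
        if np.any(np.diff(self.radii) <= 0):
            raise ValueError("radii must be strictly increasing")
        if np.any(np.diff(self.residue_counts) < 0):
            raise ValueError("residue counts must be non-decreasing in radius")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "radius": self.radii,
            "residue_count": self.residue_counts,
            "cumulative_energy": self.cumulative_energy,
            "converged": [
                self.converged_radius is not None and r >= self.converged_radius
                for r in self.radii
            ],
        })

    def to_dict(self) -> dict:
        return {
            "radii": self.radii.tolist(),
            "cumulative_energy": self.cumulative_energy.tolist(),
            "residue_counts": self.residue_counts.tolist(),
            "converged_radius": self.converged_radius,
            "threshold": self.threshold,
            "convention": self.convention,
        }


def shell_grid(r_max: float) -> np.ndarray:
    """The radius grid r = n/2 for n = 1 .. floor(2*r_max)."""
    n_max = int(round(r_max / constants.SHELL_STEP))
    return constants.SHELL_STEP * np.arange(1, n_max + 1)


def _residue_min_distances(structure: Structure, ligand_id: ResidueId,
                           atom_mode: str, include_waters: bool) -> dict[ResidueId, float]:
    if atom_mode not in ("all_atoms", "heavy_atoms"):
        raise ValueError(f"unknown atom_mode {atom_mode!r}")
    heavy = atom_mode == "heavy_atoms"
    ligand = structure.get(ligand_id)
    if ligand.role != Role.LIGAND:
        raise KeyError(f"{ligand_id} does not have the ligand role")
    lig_coords = ligand.coords(heavy_only=heavy)
    roles = (Role.PROTEIN, Role.WATER) if include_waters else (Role.PROTEIN,)
    out: dict[ResidueId, float] = {}
    for res in structure.residues:
        if res.role not in roles:
            continue
        coords = res.coords(heavy_only=heavy)
        if len(coords) == 0:
            continue
        out[res.id] = float(cdist(coords, lig_coords).min())
    return out


def select_shell(structure: Structure, ligand_id: ResidueId, r: float,
                 atom_mode: str = "all_atoms",
                 include_waters: bool = False) -> set[ResidueId]:
    """Residues with at least one atom within `r` of any ligand atom.

    The boundary is closed (a residue exactly at `r` is included), so
    membership is monotone in `r`.  `atom_mode` chooses whether hydrogens
    participate in the distance scan on both sides.
    """
    if r <= 0:
        raise ValueError("shell radius must be positive")
    dmin = _residue_min_distances(structure, ligand_id, atom_mode, include_waters)
    return {rid for rid, d in dmin.items() if d <= r}


def shell_sweep(records: Mapping[ResidueId, float] | Iterable,
                structure: Structure, ligand_id: ResidueId,
                r_max: float = constants.DEFAULT_R_MAX,
                atom_mode: str = "all_atoms",
                threshold: float = constants.CONVERGENCE_THRESHOLD) -> ShellProfile:
    """Cumulative total binding energy at every grid radius up to `r_max`.

    `records` maps residue ids to interaction energies (an iterable of
    objects with ``residue_id``/``E_interaction`` is also accepted).  Every
    residue inside `r_max` must have a record.  Convergence is detected on
    the resulting profile and stored on it.
    """
    if r_max < constants.SHELL_STEP:
        raise ValueError(f"r_max must be at least {constants.SHELL_STEP}")
    if isinstance(records, Mapping):
        energies = {ResidueId(*k): float(v) for k, v in records.items()}
    else:
        energies = {ResidueId(*rec.residue_id): float(rec.E_interaction)
                    for rec in records}

    dmin = _residue_min_distances(structure, ligand_id, atom_mode, include_waters=False)
    grid = shell_grid(r_max)
    totals = np.zeros_like(grid)
    counts = np.zeros(len(grid), dtype=int)
    for k, r in enumerate(grid):
        members = [rid for rid, d in dmin.items() if d <= r]
        missing = [rid for rid in members if rid not in energies]
        if missing:
            raise CompletenessError(
                "no energy record for in-shell residue(s): "
                + ", ".join(str(m) for m in missing))
        counts[k] = len(members)
        totals[k] = sum(energies[rid] for rid in members)

    profile = ShellProfile(grid, totals, counts, threshold=threshold)
    profile.converged_radius = detect_convergence(profile, threshold)
    return profile


def detect_convergence(profile: ShellProfile,
                       threshold: float = constants.CONVERGENCE_THRESHOLD) -> float | None:
    """Smallest grid radius at which the total binding energy has stabilised.

    Returns the first radius r_k whose successor total E_{k+1} satisfies
    |E_{k+1} - E_k| / |E_{k+1}| < threshold with E_{k+1} nonzero, or None
    if the profile never stabilises.  The ratio is scale-free, so the result
    is invariant under uniform energy rescaling.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be a fraction in (0, 1)")
    e = profile.cumulative_energy
    if len(e) < 2:
        raise InsufficientDataError("need at least two grid points")
    for k in range(len(e) - 1):
        nxt = e[k + 1]
        if nxt == 0.0:
            continue
        if abs(nxt - e[k]) / abs(nxt) < threshold:
            return float(profile.radii[k])
    return None


def profile_to_csv(profile: ShellProfile, path: str | Path, header: str = "") -> None:
    """Export the profile as CSV (optionally prefixed by a comment header)."""
    frame = profile.to_frame()
    text = frame.to_csv(index=False)
    if header:
        text = "".join(f"# {line}\n" for line in header.splitlines()) + text
    Path(path).write_text(text)
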