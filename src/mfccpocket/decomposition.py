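"""Per-residue interaction-energy decomposition and reporting.

The four fragment energies combine as

    E(L-R_i) = E(L_CRC) - E(L_CC) - E(CRC) + E(CC)

with negative values attractive and positive values repulsive.  This module
drives the whole pocket: shell selection, cap construction, water
attachment, backend evaluation, cumulative-energy convergence, ranking and
ligand-region contact annotation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from . import constants
from .energy_backends import BackendSpec, evaluate_classical
from .errors import AnnotationError, MfccError
from .mfcc_fragmentation import (
    CappedResidue, FragmentSystem, assign_waters, build_caps,
    build_fragment_systems,
)
from .pocket_shells import ShellProfile, select_shell, shell_sweep
from .structure_model import ResidueId, Role, Structure

log = logging.getLogger(__name__)

# a pocket run aborts when more than this fraction of residues fail
FAILURE_BUDGET = 0.10


@dataclass
class EnergyRecord:
    """One residue's ligand interaction energy with its context."""

    residue_id: ResidueId
    residue_name: str
    E_interaction: float
    dielectric: float
    backend: str
    min_distance: float | None = None
    contact_region: str | None = None
    nearest_ligand_atom: str | None = None
    waters_included: list[ResidueId] = field(default_factory=list)

    @property
    def is_attractive(self) -> bool:
        return self.E_interaction < 0.0

    def to_dict(self) -> dict:
        return {
            "residue": str(self.residue_id),
            "residue_name": self.residue_name,
            "E_interaction_kcal_mol": self.E_interaction,
            "dielectric": self.dielectric,
            "backend": self.backend,
            "min_distance_A": self.min_distance,
            "contact_region": self.contact_region,
            "nearest_ligand_atom": self.nearest_ligand_atom,
            "waters": [str(w) for w in self.waters_included],
        }


def mfcc_energy(systems: Mapping[str, FragmentSystem], backend: BackendSpec) -> float:
    """Combine the four fragment total energies into E(L-R_i), kcal/mol."""
    missing = [t for t in ("L_CRC", "L_CC", "CRC", "CC") if t not in systems]
    if missing:
        raise MfccError(f"missing fragment term(s): {', '.join(missing)}")
    if backend.kind != "classical_pairwise":
        raise MfccError(
            "in-process evaluation requires the classical backend; use the "
            "deck writer + harvest path for QM engines")
    term_energy = {}
    for term, system in systems.items():
        try:
            term_energy[term] = evaluate_classical(system, backend)
        except MfccError as exc:
            raise MfccError(f"term {term}: {exc}") from exc
    return (term_energy["L_CRC"] - term_energy["L_CC"]
            - term_energy["CRC"] + term_energy["CC"])


def combine_term_energies(energies: Mapping[str, float]) -> float:
    """The four-term combination applied to externally computed energies."""
    return energies["L_CRC"] - energies["L_CC"] - energies["CRC"] + energies["CC"]


@dataclass
class PocketDecomposition:
    records: list[EnergyRecord]
    profile: ShellProfile
    water_map: dict[ResidueId, ResidueId]
    failures: dict[ResidueId, str]
    capped: dict[ResidueId, CappedResidue] = field(default_factory=dict)

    @property
    def total_energy(self) -> float:
        return sum(r.E_interaction for r in self.records)

    def total_at(self, radius: float) -> float:
        idx = np.searchsorted(self.profile.radii, radius, side="right") - 1
        return float(self.profile.cumulative_energy[idx]) if idx >= 0 else 0.0


def decompose_pocket(structure: Structure, ligand_id: ResidueId,
                     r_max: float = constants.DEFAULT_R_MAX,
                     backend: BackendSpec | None = None,
                     hbond_dmax: float = constants.HBOND_DMAX_DEFAULT,
                     atom_mode: str = "all_atoms",
                     threshold: float = constants.CONVERGENCE_THRESHOLD,
                     include_waters: bool = True) -> PocketDecomposition:
    """Decompose every pocket residue within `r_max` of the ligand.

    For each residue of ``select_shell(r_max)``: build caps, attach the
    waters H-bonded to it, assemble the four fragment systems, evaluate the
    backend and record the combined interaction energy.  The cumulative
    energy profile over the r = n/2 grid and its convergence radius are
    computed from the records.  Per-residue failures are collected; the run
    aborts only if more than 10% of the pocket fails.
    """
    backend = backend or BackendSpec()
    ligand_id = ResidueId(*ligand_id)
    pocket = sorted(select_shell(structure, ligand_id, r_max, atom_mode))
    water_map = (assign_waters(structure, pocket, hbond_dmax)
                 if include_waters else None)

    records: list[EnergyRecord] = []
    failures: dict[ResidueId, str] = {}
    capped_by_id: dict[ResidueId, CappedResidue] = {}
    energies: dict[ResidueId, float] = {}
    for rid in pocket:
        try:
            capped = build_caps(structure, rid)
            if water_map is not None:
                capped.attached_waters = water_map.waters_of(rid)
            systems = build_fragment_systems(capped, ligand_id, structure)
            e = mfcc_energy(systems, backend)
        except MfccError as exc:
            failures[rid] = str(exc)
            log.warning("residue %s failed: %s", rid, exc)
            continue
        capped_by_id[rid] = capped
        energies[rid] = e
        records.append(EnergyRecord(
            residue_id=rid,
            residue_name=structure.get(rid).name,
            E_interaction=e,
            dielectric=backend.dielectric,
            backend=backend.kind,
            waters_included=list(capped.attached_waters),
        ))

    if pocket and len(failures) / len(pocket) > FAILURE_BUDGET:
        raise MfccError(
            f"{len(failures)}/{len(pocket)} pocket residues failed "
            f"(budget {FAILURE_BUDGET:.0%}): "
            + "; ".join(f"{k}: {v}" for k, v in failures.items()))

    if records:
        profile = shell_sweep(energies, structure, ligand_id, r_max,
                              atom_mode=atom_mode, threshold=threshold)
    else:
        from .pocket_shells import shell_grid

        grid = shell_grid(r_max)
        profile = ShellProfile(grid, np.zeros_like(grid),
                               np.zeros(len(grid), dtype=int),
                               threshold=threshold)
    return PocketDecomposition(
        records=records, profile=profile,
        water_map=dict(water_map.items()) if water_map is not None else {},
        failures=failures, capped=capped_by_id)


@dataclass
class RankedReport:
    """Residues ordered by interaction energy, attractive before repulsive."""

    attractive: list[EnergyRecord]
    repulsive: list[EnergyRecord]
    totals_by_dielectric: dict[float, float]

    def to_dict(self) -> dict:
        return {
            "attractive": [r.to_dict() for r in self.attractive],
            "repulsive": [r.to_dict() for r in self.repulsive],
            "totals_by_dielectric": {
                str(k): v for k, v in self.totals_by_dielectric.items()
            },
        }

    def to_text(self) -> str:
        lines = ["Attractive residues (most favourable first):"]
        for r in self.attractive:
            lines.append(f"  {r.residue_name:>3s} {r.residue_id}: "
                         f"{r.E_interaction:9.3f} kcal/mol (eps={r.dielectric:g})")
        lines.append("Repulsive residues (strongest first):")
        for r in self.repulsive:
            lines.append(f"  {r.residue_name:>3s} {r.residue_id}: "
                         f"{r.E_interaction:9.3f} kcal/mol (eps={r.dielectric:g})")
        lines.append("Totals by dielectric:")
        for eps, tot in sorted(self.totals_by_dielectric.items()):
            lines.append(f"  eps={eps:g}: {tot:9.3f} kcal/mol")
        return "\n".join(lines)


def rank_residues(records: Sequence[EnergyRecord]) -> RankedReport:
    """Sort records most-attractive first; repulsive ones reported apart.

    Attractive and zero-energy residues are sorted ascending (ties keep
    input order); repulsive residues descending.  Totals are accumulated per
    dielectric across all records.
    """
    if not records:
        raise MfccError("cannot rank an empty record table")
    attractive = sorted((r for r in records if r.E_interaction <= 0.0),
                        key=lambda r: r.E_interaction)
    repulsive = sorted((r for r in records if r.E_interaction > 0.0),
                       key=lambda r: -r.E_interaction)
    totals: dict[float, float] = {}
    for r in records:
        totals[r.dielectric] = totals.get(r.dielectric, 0.0) + r.E_interaction
    return RankedReport(attractive, repulsive, totals)


def annotate_contact(record: EnergyRecord, structure: Structure,
                     region_map: Mapping[str, str],
                     ligand_id: ResidueId | None = None) -> EnergyRecord:
    """Attach nearest-ligand-atom and region labels to a record.

    The nearest ligand heavy atom (hydrogens ride on their heavy atom) to
    any atom of the residue determines ``nearest_ligand_atom``,
    ``contact_region`` (via `region_map`) and ``min_distance``.  Ties are
    broken by the lower ligand atom index.  A heavy atom missing from
    `region_map` raises :class:`AnnotationError`.
    """
    ligands = structure.ligands
    if ligand_id is not None:
        ligand = structure.get(ligand_id)
    elif len(ligands) == 1:
        ligand = ligands[0]
    else:
        raise AnnotationError("ambiguous ligand: pass ligand_id explicitly")

    heavy = ligand.heavy_atoms()
    gaps = [a.name for a in heavy if a.name not in region_map]
    if gaps:
        raise AnnotationError(
            "region map does not cover ligand atom(s): " + ", ".join(gaps))

    res = structure.get(record.residue_id)
    res_coords = res.coords()
    lig_coords = np.array([a.position for a in heavy])
    d = cdist(lig_coords, res_coords).min(axis=1)
    best = int(np.argmin(d))  # argmin takes the lowest index on ties
    return replace(
        record,
        min_distance=float(d[best]),
        nearest_ligand_atom=heavy[best].name,
        contact_region=region_map[heavy[best].name],
    )
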