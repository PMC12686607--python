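"""Small vector-geometry helpers for hydrogen placement and chain building.

All routines take and return (3,) float64 numpy arrays in Angstrom.
"""
from __future__ import annotations

import numpy as np

TETRAHEDRAL_DEG = 109.4712206  # arccos(-1/3)


def unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n < 1e-12:
        raise ValueError("cannot normalise a zero vector")
    return v / n


def any_perpendicular(u: np.ndarray) -> np.ndarray:
    """A deterministic unit vector perpendicular to `u`."""
    u = unit(u)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(u, ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    return unit(np.cross(u, ref))


def place_from_internal(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """Place atom D given chain A-B-C with |C-D|=bond, angle(B,C,D) and
    torsion(A,B,C,D) — the standard natural-extension (NeRF) construction."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def complete_substituents(
    center: np.ndarray,
    neighbors: list[np.ndarray],
    n_new: int,
    bond: float,
    geometry: str,
    reference: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Idealised positions for `n_new` hydrogens on `center`.

    `neighbors` are the existing bonded heavy-atom positions; `geometry` is
    "sp3" or "sp2".  `reference` disambiguates the rotational degree of
    freedom for methyl/hydroxyl-type placements (typically a neighbour of the
    first neighbour); when absent a deterministic perpendicular is used.
    """
    us = [unit(n - center) for n in neighbors]
    if geometry not in ("sp3", "sp2"):
        raise ValueError(f"unknown geometry {geometry!r}")

    if len(us) >= 3 and n_new == 1:
        # fourth-vertex direction: normal of the neighbour triangle pointing
        # away from the neighbours (stable even when the three bond vectors
        # nearly cancel, where -(u1+u2+u3) loses its direction)
        n = np.cross(us[1] - us[0], us[2] - us[0])
        if np.linalg.norm(n) < 1e-8:
            return [center + bond * unit(-sum(us))]
        n = unit(n)
        s = sum(us)
        if np.dot(n, s) > 0:
            n = -n
        return [center + bond * n]

    if len(us) == 2 and n_new == 1:
        return [center + bond * unit(-(us[0] + us[1]))]

    if len(us) == 2 and n_new == 2:  # sp3 CH2
        b = unit(-(us[0] + us[1]))
        p = unit(np.cross(us[0], us[1]))
        half = np.deg2rad(TETRAHEDRAL_DEG / 2.0)
        return [
            center + bond * (b * np.cos(half) + p * np.sin(half)),
            center + bond * (b * np.cos(half) - p * np.sin(half)),
        ]

    if len(us) == 1:
        u = us[0]
        if reference is not None:
            proj = (reference - center) - np.dot(reference - center, u) * u
            v1 = unit(proj) if np.linalg.norm(proj) > 1e-6 else any_perpendicular(u)
        else:
            v1 = any_perpendicular(u)
        v2 = np.cross(u, v1)
        if geometry == "sp2":
            # in-plane positions at 120 degrees from the existing bond
            out = []
            for sign in (1.0, -1.0)[:n_new]:
                d = -u * np.cos(np.deg2rad(60.0)) + sign * v1 * np.sin(np.deg2rad(60.0))
                out.append(center + bond * unit(d))
            return out
        theta = np.deg2rad(TETRAHEDRAL_DEG)
        out = []
        # start anti-periplanar to the reference, then space by 120 degrees
        for k in range(n_new):
            phi = np.deg2rad(180.0 + 120.0 * k)
            d = np.cos(theta) * u + np.sin(theta) * (v1 * np.cos(phi) + v2 * np.sin(phi))
            out.append(center + bond * unit(d))
        return out

    if len(us) == 0 and n_new == 2:  # isolated water oxygen
        half = np.deg2rad(104.52 / 2.0)
        ax = np.array([0.0, 0.0, 1.0])
        px = np.array([1.0, 0.0, 0.0])
        return [
            center + bond * (ax * np.cos(half) + px * np.sin(half)),
            center + bond * (ax * np.cos(half) - px * np.sin(half)),
        ]

    raise ValueError(
        f"unsupported completion: {len(us)} neighbours, {n_new} new atoms"
    )


def min_pair_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum Euclidean distance between two coordinate sets (n,3), (m,3)."""
    from scipy.spatial.distance import cdist

    return float(cdist(a, b).min())
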