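"""Energy-based pocket detection and inhibitor-occupancy filtering.

A united-atom methyl probe is evaluated on a regular grid over the surface
shell of the structure; grid points where the summed Lennard-Jones 12-6
interaction energy with nearby protein atoms is favorable (below an energy
cutoff) are kept, clustered by single linkage, and the clusters are ranked
by total energy.  Pockets "at the interface" are those at least partly
occupied by the superposed inhibitor.  Absolute energies depend on the
probe parameters and are configuration values, not physical claims; pocket
counts and volumes should be read as order-of-magnitude descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from ppiface.structure import Structure

#: united-atom methyl probe (kcal/mol, A)
PROBE_EPSILON = 0.16
PROBE_SIGMA = 3.6

#: per-element Lennard-Jones parameters, OPLS-flavored united-atom values
ELEMENT_LJ = {
    "C": (0.105, 3.50), "N": (0.170, 3.25), "O": (0.210, 2.96),
    "S": (0.250, 3.55), "P": (0.200, 3.74), "SE": (0.290, 3.62),
    "F": (0.061, 2.94), "CL": (0.300, 3.40), "BR": (0.470, 3.47),
    "ZN": (0.250, 1.95), "MG": (0.875, 1.64), "CA": (0.450, 2.41),
    "FE": (0.013, 2.59), "NA": (0.003, 3.33), "K": (0.000328, 4.06),
}
_DEFAULT_LJ = (0.105, 3.50)


@dataclass
class Pocket:
    probe_points: np.ndarray     # (n, 3)
    total_energy: float          # kcal/mol, negative = favorable
    volume: float                # A^3 = n_points * cell volume
    rank: int


def _lj_params(element: str):
    return ELEMENT_LJ.get(element.upper(), _DEFAULT_LJ)


def find_pockets(
    structure: Structure,
    indices: Sequence[int] | None = None,
    grid_spacing: float = 0.9,
    energy_cutoff: float = -1.4,
    cluster_dist: float = 1.6,
    max_pockets: int = 10,
    interaction_cutoff: float = 8.0,
    shell_max: float = 5.0,
) -> list[Pocket]:
    """Detect surface pockets of (a subset of) *structure*.

    Grid points within the surface shell (not inside any atom's LJ core,
    within *shell_max* of the nearest heavy atom) are scored with the
    methyl probe; points with energy <= *energy_cutoff* kcal/mol are
    single-linkage clustered at *cluster_dist* and the *max_pockets*
    lowest-total-energy clusters returned, ranked by ascending energy.
    """
    if indices is None:
        indices = range(len(structure.atoms))
    heavy = [i for i in indices if not structure.atoms[i].is_hydrogen]
    if not heavy:
        raise ValueError("no heavy atoms for pocket detection")
    coords = structure.coords(heavy)
    eps = np.empty(len(heavy))
    sig = np.empty(len(heavy))
    for k, i in enumerate(heavy):
        e, s = _lj_params(structure.atoms[i].element)
        eps[k] = np.sqrt(e * PROBE_EPSILON)          # Lorentz-Berthelot
        sig[k] = 0.5 * (s + PROBE_SIGMA)

    lo = coords.min(axis=0) - shell_max
    hi = coords.max(axis=0) + shell_max
    axes = [np.arange(lo[d], hi[d] + grid_spacing, grid_spacing) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    grid = np.column_stack((gx.ravel(), gy.ravel(), gz.ravel()))

    tree = cKDTree(coords)
    dmin, _ = tree.query(grid, k=1)
    # surface shell: outside the repulsive core, within reach of the surface
    shell = (dmin >= 0.8 * sig.min()) & (dmin <= shell_max)
    grid = grid[shell]
    if len(grid) == 0:
        return []

    energies = np.zeros(len(grid))
    neighbor_lists = tree.query_ball_point(grid, interaction_cutoff)
    for gi, neighbors in enumerate(neighbor_lists):
        if not neighbors:
            energies[gi] = 0.0
            continue
        nb = np.asarray(neighbors)
        d = np.linalg.norm(coords[nb] - grid[gi], axis=1)
        sr6 = (sig[nb] / np.maximum(d, 0.3)) ** 6
        energies[gi] = np.sum(4.0 * eps[nb] * (sr6 * sr6 - sr6))
    keep = energies <= energy_cutoff
    pts = grid[keep]
    en = energies[keep]
    if len(pts) == 0:
        return []

    # single-linkage clustering via the neighbor graph (union-find)
    parent = np.arange(len(pts))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    pt_tree = cKDTree(pts)
    for i, j in pt_tree.query_pairs(cluster_dist):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    labels = np.array([find(i) for i in range(len(pts))])

    cell = grid_spacing ** 3
    pockets = []
    for lab in np.unique(labels):
        sel = labels == lab
        pockets.append(Pocket(
            probe_points=pts[sel],
            total_energy=float(en[sel].sum()),
            volume=float(sel.sum()) * cell,
            rank=0,
        ))
    pockets.sort(key=lambda p: p.total_energy)
    pockets = pockets[:max_pockets]
    for r, p in enumerate(pockets, start=1):
        p.rank = r
    return pockets


def interface_pockets(
    pockets: list[Pocket],
    ligand_coords: np.ndarray,
    overlap_dist: float = 2.0,
) -> tuple[int, float]:
    """Count and total volume of pockets at least partly occupied by the ligand.

    A pocket qualifies when any of its probe points lies within
    *overlap_dist* of any (already superposed) ligand atom.
    """
    lig = np.asarray(ligand_coords, dtype=float)
    if lig.ndim != 2 or lig.shape[1] != 3:
        raise ValueError("ligand coordinates must be an (n, 3) array; "
                         "superpose the ligand structure first")
    if len(lig) == 0 or not pockets:
        return 0, 0.0
    tree = cKDTree(lig)
    count = 0
    volume = 0.0
    for p in pockets:
        d, _ = tree.query(p.probe_points, k=1)
        if np.any(d <= overlap_dist):
            count += 1
            volume += p.volume
    return count, volume


def pockets_to_pdb(pockets: list[Pocket]) -> str:
    """Write pocket probe points as HETATM pseudo-atoms for inspection."""
    lines = []
    serial = 1
    for p in pockets:
        for pt in p.probe_points:
            lines.append(
                f"HETATM{serial:>5d}  C   PKT P{p.rank:>4d}    "
                f"{pt[0]:8.3f}{pt[1]:8.3f}{pt[2]:8.3f}{1.0:6.2f}"
                f"{-p.total_energy:6.2f}           C"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
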