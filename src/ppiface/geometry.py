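"""Shape descriptors of the interface: least-squares plane, planarity,
eccentricity, gap volume / gap-volume index, and CA superposition.

Planarity is the RMS perpendicular deviation of the interface atoms from
their least-squares plane.  Eccentricity is the ratio of the lengths of
the two in-plane principal axes (1 = circular patch, -> 0 = elongated);
the axis-length convention (square root of the eigenvalue ratio) is a
documented constant of the package.  The gap volume is estimated on a
regular grid as the empty space enclosed between the two partners'
van der Waals surfaces, and the gap-volume index divides it by the total
(two-sided) buried surface area, giving a tightness measure in Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from ppiface.structure import Structure, PartnerSelection
from ppiface.sasa import InterfaceDefinition, vdw_radius


@dataclass
class InterfacePlane:
    centroid: np.ndarray         # (3,)
    axes: np.ndarray             # (3, 3) rows: major in-plane, minor in-plane, normal
    eigenvalues: np.ndarray      # (3,) descending, A^2


@dataclass
class GapVolumeResult:
    gap_volume: float            # A^3
    gap_index: float             # A  (gap_volume / total two-sided dASA)
    grid_spacing: float
    shell_cutoff: float
    n_grid_points: int = 0
    grid_points: np.ndarray | None = None


@dataclass
class Superposition:
    rotation: np.ndarray         # (3, 3), det = +1
    translation: np.ndarray      # (3,)
    rmsd: float
    n_pairs: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _as_coords(x) -> np.ndarray:
    c = np.asarray(x, dtype=float)
    if c.ndim != 2 or c.shape[1] != 3:
        raise ValueError("expected an (n, 3) coordinate array")
    return c


def fit_plane(coords) -> InterfacePlane:
    """Least-squares plane through a set of atoms.

    Principal-component decomposition of the centered coordinates; the
    plane is spanned by the two largest-eigenvalue axes and the third axis
    is the plane normal.
    """
    c = _as_coords(coords)
    if len(c) < 3:
        raise ValueError(f"need >= 3 atoms to fit a plane, got {len(c)}")
    centroid = c.mean(axis=0)
    x = c - centroid
    cov = x.T @ x / len(c)
    evals, evecs = np.linalg.eigh(cov)      # ascending
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    axes = evecs[:, order].T                # rows
    if evals[1] <= 1e-12 * max(evals[0], 1.0):
        raise ValueError("atoms are collinear; the plane is undefined")
    # deterministic sign convention: largest component positive
    for i in range(3):
        j = np.argmax(np.abs(axes[i]))
        if axes[i, j] < 0:
            axes[i] = -axes[i]
    return InterfacePlane(
        centroid=centroid, axes=axes, eigenvalues=np.maximum(evals, 0.0)
    )


def planarity(coords) -> float:
    """RMS perpendicular distance of the atoms to their least-squares plane (A)."""
    plane = fit_plane(coords)
    c = _as_coords(coords) - plane.centroid
    d = c @ plane.axes[2]
    return float(np.sqrt(np.mean(d * d)))


def eccentricity(coords) -> float:
    """Ratio of in-plane principal-axis lengths, sqrt(lambda_minor/lambda_major)."""
    plane = fit_plane(coords)
    major, minor = plane.eigenvalues[0], plane.eigenvalues[1]
    if major <= 0:
        raise ValueError("degenerate interface: zero major axis")
    return float(np.sqrt(minor / major))


def gap_volume(
    complex_structure: Structure,
    selection: PartnerSelection,
    interface: InterfaceDefinition | None = None,
    grid_spacing: float = 1.0,
    shell_cutoff: float = 5.0,
    keep_points: bool = False,
) -> GapVolumeResult:
    """Grid estimate of the empty volume enclosed between the two partners.

    A grid cell counts toward the gap volume when its center is
      - outside every atom's van der Waals sphere,
      - within *shell_cutoff* of at least one heavy atom of EACH partner
        (which restricts the count to space between the partners).

    gap_index = gap_volume / (dASA_A + dASA_B); requires a non-zero
    interface.
    """
    idx_a = complex_structure.atom_indices(selection.side_a, heavy_only=True, hetero=False)
    idx_b = complex_structure.atom_indices(selection.side_b, heavy_only=True, hetero=False)
    if not idx_a or not idx_b:
        raise ValueError("both sides of the selection must contain heavy atoms")
    if interface is None:
        from ppiface.sasa import define_interface
        interface = define_interface(complex_structure, selection)
    if interface.delta_asa_total <= 0:
        raise ValueError("zero interface: gap-volume index is undefined")

    ca = complex_structure.coords(idx_a)
    cb = complex_structure.coords(idx_b)
    ra = np.array([vdw_radius(complex_structure.atoms[i].element) for i in idx_a])
    rb = np.array([vdw_radius(complex_structure.atoms[i].element) for i in idx_b])

    lo = np.minimum(ca.min(axis=0), cb.min(axis=0)) - grid_spacing
    hi = np.maximum(ca.max(axis=0), cb.max(axis=0)) + grid_spacing
    axes = [np.arange(lo[d], hi[d] + grid_spacing, grid_spacing) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    grid = np.column_stack((gx.ravel(), gy.ravel(), gz.ravel()))

    tree_a = cKDTree(ca)
    tree_b = cKDTree(cb)
    da, ja = tree_a.query(grid, k=1)
    db, jb = tree_b.query(grid, k=1)
    near_both = (da <= shell_cutoff) & (db <= shell_cutoff)
    # "between the partners": the nearest atom of each side lies on the
    # opposite side of the point (excludes the rim around the contact patch)
    va = ca[ja] - grid
    vb = cb[jb] - grid
    between = np.einsum("ij,ij->i", va, vb) < 0
    grid = grid[near_both & between]
    if len(grid) == 0:
        return GapVolumeResult(0.0, 0.0, grid_spacing, shell_cutoff, 0,
                               np.empty((0, 3)) if keep_points else None)

    # outside every vdW sphere: check all atoms within the largest radius
    all_coords = np.vstack((ca, cb))
    all_radii = np.concatenate((ra, rb))
    tree_all = cKDTree(all_coords)
    rmax = all_radii.max()
    inside = np.zeros(len(grid), dtype=bool)
    pairs = tree_all.query_ball_point(grid, rmax, return_sorted=False)
    for gi, neighbors in enumerate(pairs):
        if not neighbors:
            continue
        d = np.linalg.norm(all_coords[neighbors] - grid[gi], axis=1)
        if np.any(d < all_radii[neighbors]):
            inside[gi] = True
    empty = grid[~inside]

    vol = float(len(empty)) * grid_spacing ** 3
    gvi = vol / interface.delta_asa_total
    return GapVolumeResult(
        gap_volume=vol,
        gap_index=gvi,
        grid_spacing=grid_spacing,
        shell_cutoff=shell_cutoff,
        n_grid_points=len(empty),
        grid_points=empty if keep_points else None,
    )


def superpose(mobile, reference) -> Superposition:
    """Optimal least-squares (Kabsch) superposition of paired coordinates.

    *mobile* and *reference* are (n, 3) arrays of already-paired atoms
    (typically CA atoms matched by residue identity).  Returns the proper
    rotation/translation minimizing the RMSD and the residual RMSD itself.
    """
    m = _as_coords(mobile)
    r = _as_coords(reference)
    if len(m) != len(r):
        raise ValueError(f"pairing mismatch: {len(m)} vs {len(r)} atoms")
    if len(m) < 3:
        raise ValueError("need >= 3 paired atoms for superposition")
    mc = m.mean(axis=0)
    rc = r.mean(axis=0)
    rot, rssd = Rotation.align_vectors(r - rc, m - mc)
    matrix = rot.as_matrix()
    translation = rc - mc @ matrix.T
    moved = m @ matrix.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - r) ** 2, axis=1))))
    return Superposition(
        rotation=matrix, translation=translation, rmsd=rmsd, n_pairs=len(m)
    )


def pair_ca_atoms(
    mobile: Structure,
    reference: Structure,
    mobile_chains: set[str] | None = None,
    reference_chains: set[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pair CA atoms of two structures by (chain, residue number, icode).

    Falls back to pairing by residue number alone (longest common stretch)
    when the chain naming differs between the two structures.
    """
    def ca_map(st: Structure, chains):
        out = {}
        for i, a in enumerate(st.atoms):
            if a.name != "CA" or a.is_hetero or a.is_hydrogen:
                continue
            if chains is not None and a.chain_id not in chains:
                continue
            out[a.residue_id] = i
        return out

    mob = ca_map(mobile, mobile_chains)
    ref = ca_map(reference, reference_chains)
    common = [k for k in mob if k in ref]
    if len(common) < 3:
        mob2 = {(k[1], k[2]): v for k, v in mob.items()}
        ref2 = {(k[1], k[2]): v for k, v in ref.items()}
        common2 = [k for k in mob2 if k in ref2]
        if len(common2) < 3:
            raise ValueError("fewer than 3 CA atoms could be paired")
        return (
            mobile.coords([mob2[k] for k in sorted(common2)]),
            reference.coords([ref2[k] for k in sorted(common2)]),
        )
    common.sort()
    return (
        mobile.coords([mob[k] for k in common]),
        reference.coords([ref[k] for k in common]),
    )
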