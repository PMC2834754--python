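"""Solvent-accessible surface area and the buried-surface interface definition.

The interface between two protein partners is defined through the change in
solvent-accessible surface area (ASA) on complexation: for each side,
dASA = ASA(side alone) - ASA(side within the complex).  Atoms that lose
more than a small burial threshold are interface atoms; residues with at
least one such atom are interface residues.  The per-complex "interface
area" descriptor is the mean of the two sides' dASA, i.e. half the total
buried surface.

SASA itself is computed with a deterministic Shrake-Rupley sphere-point
estimator (probe radius 1.4 A, 960 points per atom by default) over heavy
atoms only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from ppiface.structure import Structure, PartnerSelection, Atom

#: van der Waals radii (A) for protein heavy atoms, Bondi-type element set.
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "H": 1.20, "D": 1.20,
    # common structural ions
    "ZN": 1.39, "MG": 1.73, "CA": 2.31, "NA": 2.27, "K": 2.75,
    "FE": 1.95, "MN": 1.96, "CU": 1.40, "NI": 1.63,
}
RADII_SET_NAME = "bondi-protein"

DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960


def vdw_radius(element: str) -> float:
    try:
        return VDW_RADII[element.upper()]
    except KeyError:
        raise KeyError(f"no van der Waals radius for element {element!r}") from None


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (Fibonacci spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


@dataclass
class SasaResult:
    per_atom_area: dict[int, float]  # atom index -> A^2
    total: float
    probe_radius: float
    n_sphere_points: int
    radii_set_name: str = RADII_SET_NAME


def shrake_rupley(
    structure: Structure,
    indices: Sequence[int] | None = None,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> SasaResult:
    """Shrake-Rupley SASA of the heavy atoms of *structure*.

    *indices* restricts the computation to a subset of atoms (e.g. one
    partner evaluated in isolation).  Hydrogens are always excluded.
    Deterministic: the same input always yields the same areas.
    """
    if indices is None:
        indices = range(len(structure.atoms))
    heavy = [i for i in indices if not structure.atoms[i].is_hydrogen]
    if not heavy:
        raise ValueError("no heavy atoms to compute SASA for")
    coords = structure.coords(heavy)
    radii = np.array(
        [vdw_radius(structure.atoms[i].element) for i in heavy], dtype=float
    )
    ext = radii + probe
    pts = sphere_points(n_points)

    tree = cKDTree(coords)
    max_reach = 2.0 * ext.max()
    per_atom: dict[int, float] = {}
    total = 0.0
    for k, idx in enumerate(heavy):
        center = coords[k]
        r = ext[k]
        neigh = [j for j in tree.query_ball_point(center, r + ext.max()) if j != k]
        surface = center + r * pts
        if neigh:
            nc = coords[neigh]
            nr = ext[np.asarray(neigh)]
            d2 = ((surface[:, None, :] - nc[None, :, :]) ** 2).sum(axis=2)
            exposed = np.all(d2 >= (nr ** 2)[None, :], axis=1)
            frac = exposed.mean()
        else:
            frac = 1.0
        area = frac * 4.0 * np.pi * r * r
        per_atom[idx] = area
        total += area
    return SasaResult(
        per_atom_area=per_atom,
        total=total,
        probe_radius=probe,
        n_sphere_points=n_points,
    )


@dataclass
class InterfaceDefinition:
    delta_asa_side_a: float
    delta_asa_side_b: float
    interface_atoms_a: set[int]
    interface_atoms_b: set[int]
    interface_residues_a: set[tuple]
    interface_residues_b: set[tuple]
    per_atom_delta: dict[int, float] = field(default_factory=dict)
    atom_burial_threshold: float = 0.1

    @property
    def asa_mean_side(self) -> float:
        """The "interface ASA" descriptor: mean of the two sides' dASA."""
        return 0.5 * (self.delta_asa_side_a + self.delta_asa_side_b)

    @property
    def delta_asa_total(self) -> float:
        return self.delta_asa_side_a + self.delta_asa_side_b

    def side_of_residue(self, residue_id: tuple) -> str | None:
        if residue_id in self.interface_residues_a:
            return "a"
        if residue_id in self.interface_residues_b:
            return "b"
        return None


def define_interface(
    complex_structure: Structure,
    selection: PartnerSelection,
    atom_burial_threshold: float = 0.1,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> InterfaceDefinition:
    """Buried-surface interface between the two sides of *selection*.

    dASA per side = SASA(side alone) - SASA(side in complex), computed over
    heavy protein atoms of the selected chains only (the ligand, if any, is
    not part of either side).
    """
    idx_a = complex_structure.atom_indices(selection.side_a, hetero=False)
    idx_b = complex_structure.atom_indices(selection.side_b, hetero=False)
    if not idx_a or not idx_b:
        raise ValueError("both sides of the selection must contain atoms")

    both = idx_a + idx_b
    sasa_ab = shrake_rupley(complex_structure, both, probe, n_points)
    sasa_a = shrake_rupley(complex_structure, idx_a, probe, n_points)
    sasa_b = shrake_rupley(complex_structure, idx_b, probe, n_points)

    per_atom_delta: dict[int, float] = {}
    for res in (sasa_a, sasa_b):
        for i, area in res.per_atom_area.items():
            per_atom_delta[i] = area - sasa_ab.per_atom_area.get(i, 0.0)

    def collect(indices):
        atoms = {
            i for i in indices
            if per_atom_delta.get(i, 0.0) > atom_burial_threshold
        }
        residues = {complex_structure.atoms[i].residue_id for i in atoms}
        delta = sum(max(per_atom_delta.get(i, 0.0), 0.0) for i in indices)
        return atoms, residues, delta

    atoms_a, res_a, delta_a = collect(idx_a)
    atoms_b, res_b, delta_b = collect(idx_b)
    return InterfaceDefinition(
        delta_asa_side_a=delta_a,
        delta_asa_side_b=delta_b,
        interface_atoms_a=atoms_a,
        interface_atoms_b=atoms_b,
        interface_residues_a=res_a,
        interface_residues_b=res_b,
        per_atom_delta=per_atom_delta,
        atom_burial_threshold=atom_burial_threshold,
    )


def ligand_coverage(
    target_with_ligand: Structure,
    selection: PartnerSelection,
    pp_interface: InterfaceDefinition,
    pp_complex: Structure,
    target_side: str = "a",
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> float:
    """Percentage of the protein-protein interface occluded by the inhibitor.

    Interface atoms of the target side (from the protein-protein complex)
    are mapped onto the protein/ligand structure by chain, residue number
    and atom name; the returned value is

        100 * dASA(those atoms, caused by the ligand)
            / dASA(those same atoms, caused by the protein partner)

    clamped to [0, 100].  Raises if interface atoms cannot be mapped.
    """
    from ppiface.structure import extract_ligand

    lig_idx = extract_ligand(target_with_ligand, selection)
    iface_atoms = (
        pp_interface.interface_atoms_a if target_side == "a"
        else pp_interface.interface_atoms_b
    )
    if not iface_atoms:
        return 0.0

    # map pp-complex interface atoms onto the ligand-complex structure
    lookup = {
        (a.chain_id, a.residue_seq, a.insertion_code, a.name): i
        for i, a in enumerate(target_with_ligand.atoms)
        if not a.is_hetero
    }
    mapped: dict[int, int] = {}
    missing = []
    for i in iface_atoms:
        a = pp_complex.atoms[i]
        key = (a.chain_id, a.residue_seq, a.insertion_code, a.name)
        j = lookup.get(key)
        if j is None:
            missing.append(key)
        else:
            mapped[i] = j
    if missing:
        raise ValueError(f"unmappable interface atoms: {missing[:10]}")

    target_chains = selection.side_a if target_side == "a" else selection.side_b
    prot_idx = target_with_ligand.atom_indices(target_chains, hetero=False)
    sasa_alone = shrake_rupley(target_with_ligand, prot_idx, probe, n_points)
    sasa_with = shrake_rupley(target_with_ligand, prot_idx + lig_idx, probe, n_points)

    num = 0.0
    den = 0.0
    for i, j in mapped.items():
        hidden = sasa_alone.per_atom_area.get(j, 0.0) - sasa_with.per_atom_area.get(j, 0.0)
        num += max(hidden, 0.0)
        den += max(pp_interface.per_atom_delta.get(i, 0.0), 0.0)
    if den <= 0:
        return 0.0
    return float(min(100.0 * num / den, 100.0))


def ligand_neighborhood(
    complex_structure: Structure,
    ligand_atoms: Sequence[int],
    cutoff: float = 4.5,
) -> tuple[set[int], set[tuple]]:
    """Protein atoms within *cutoff* (closed interval) of any ligand atom.

    Returns (atom index set, residue id set); the subset on which all
    interface descriptors can be re-evaluated around the inhibitor.
    """
    if not len(ligand_atoms):
        raise ValueError("ligand atom list is empty")
    lig_set = set(ligand_atoms)
    prot = [
        i for i, a in enumerate(complex_structure.atoms)
        if i not in lig_set and not a.is_hetero
    ]
    if not prot:
        return set(), set()
    tree = cKDTree(complex_structure.coords(ligand_atoms))
    d, _ = tree.query(complex_structure.coords(prot), k=1)
    atoms = {i for i, dist in zip(prot, d) if dist <= cutoff}
    residues = {complex_structure.atoms[i].residue_id for i in atoms}
    return atoms, residues
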