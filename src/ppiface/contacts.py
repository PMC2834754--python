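"""Cross-interface contacts and sequence structure of the interface.

Hydrogen bonds use the distance criterion between the hydrogen atom and
the acceptor (3.2 A by default).  Crystal structures usually lack
hydrogens, so polar hydrogens are placed with ideal geometry (1.0 A N-H,
0.96 A O-H; sp2 hydrogens from the heavy-atom frame, rotatable OH/NH3
groups oriented toward the best acceptor).  A salt bridge is an acidic
side chain (Asp/Glu) on one side of the interface and a basic one
(Arg/His/Lys) on the other with functional atoms closer than 4.0 A.

An interface *segment* is a stretch of residues that starts and ends with
interface residues and may contain a bounded number of intervening
non-interface residues; only interface residues count toward its length.
The number of segments separates peptide-like interfaces (class I, < 6
segments) from globular ones (class II).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from ppiface.structure import Structure
from ppiface.sasa import InterfaceDefinition

NH_BOND = 1.0
OH_BOND = 0.96

#: rotatable donor hydroxyl / ammonium groups: oriented toward the acceptor
ROTATABLE_DONORS = {
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"), ("LYS", "NZ"),
}
#: fixed-geometry donors (residue, atom) -> number of hydrogens
FIXED_DONORS = {
    ("ARG", "NE"): 1, ("ARG", "NH1"): 2, ("ARG", "NH2"): 2,
    ("ASN", "ND2"): 2, ("GLN", "NE2"): 2,
    ("TRP", "NE1"): 1, ("HIS", "ND1"): 1, ("HIS", "NE2"): 1,
    ("CYS", "SG"): 0,  # thiol donors excluded from the default table
}
ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC_ATOMS = {
    "LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"), "HIS": ("ND1", "NE2"),
}


@dataclass
class HydrogenBond:
    donor_index: int
    acceptor_index: int
    hydrogen_coords: np.ndarray
    h_acceptor_distance: float
    donor_acceptor_distance: float
    hydrogen_index: int | None = None  # set when the H was explicit in the input


@dataclass
class SaltBridge:
    acidic_residue: tuple
    basic_residue: tuple
    distance: float


@dataclass
class SegmentSet:
    segments: list[list[int]]        # per segment: positions of interface residues
    n_segments: int
    max_gap: int

    @property
    def segment_lengths(self) -> list[int]:
        return [len(s) for s in self.segments]


@dataclass
class SSClass:
    helix_fraction_a: float
    strand_fraction_a: float
    helix_fraction_b: float
    strand_fraction_b: float
    label_a: str
    label_b: str

    @property
    def pair_label(self) -> str:
        return f"{self.label_a}/{self.label_b}"


def _covalent_neighbors(structure, tree, coords, heavy_idx, i, cutoff=1.75):
    pos = structure.atoms[i].coords
    out = []
    for j in tree.query_ball_point(pos, cutoff):
        k = heavy_idx[j]
        if k != i:
            out.append(k)
    return out


def _unit(v):
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise ValueError("degenerate geometry while placing hydrogens")
    return v / n


def _sp2_bisector_h(donor, n1, n2, bond):
    d = _unit(2.0 * donor - n1 - n2)
    return [donor + bond * d]


def _sp2_amide_h(donor, n1, n2, bond):
    """Two in-plane hydrogens for an -NH2 bonded to n1 (n2 defines the plane)."""
    a = _unit(donor - n1)
    w = n1 - n2
    p = w - np.dot(w, a) * a
    p = _unit(p)
    out = []
    for sign in (+1.0, -1.0):
        d = 0.5 * a + sign * (np.sqrt(3.0) / 2.0) * p
        out.append(donor + bond * _unit(d))
    return out


class _DonorTable:
    """Resolves donors/acceptors and hydrogen positions for one structure."""

    def __init__(self, structure: Structure):
        self.st = structure
        self.heavy = [i for i, a in enumerate(structure.atoms) if not a.is_hydrogen]
        self.coords = structure.coords(self.heavy)
        self.tree = cKDTree(self.coords) if self.heavy else None
        self.h_idx = [i for i, a in enumerate(structure.atoms) if a.is_hydrogen]
        self.h_tree = (
            cKDTree(structure.coords(self.h_idx)) if self.h_idx else None
        )

    def explicit_hydrogens(self, i: int) -> list[int]:
        if self.h_tree is None:
            return []
        out = []
        for j in self.h_tree.query_ball_point(self.st.atoms[i].coords, 1.25):
            out.append(self.h_idx[j])
        return out

    def neighbors(self, i: int) -> list[int]:
        return _covalent_neighbors(self.st, self.tree, self.coords, self.heavy, i)

    def is_donor(self, i: int) -> bool:
        a = self.st.atoms[i]
        if a.is_hetero:
            return a.element in ("N", "O")
        if a.name == "N" and a.residue_name != "PRO":
            return True
        key = (a.residue_name, a.name)
        return key in ROTATABLE_DONORS or (key in FIXED_DONORS and FIXED_DONORS[key] > 0)

    def is_acceptor(self, i: int) -> bool:
        a = self.st.atoms[i]
        if a.element == "O":
            return True
        if a.element == "N":
            if a.is_hetero:
                return True
            # His ring nitrogens act as donor-or-acceptor
            return (a.residue_name, a.name) in (("HIS", "ND1"), ("HIS", "NE2"))
        return False

    def hydrogen_positions(self, i: int, acceptor_pos=None):
        """Hydrogen positions for donor *i*; explicit H win over placement.

        Rotatable donors return a single H pointed at *acceptor_pos*
        (None when no acceptor candidate is being evaluated), valid only
        when the antecedent-donor-acceptor angle is >= 90 degrees.
        Returns a list of (position, explicit_index_or_None).
        """
        st = self.st
        a = st.atoms[i]
        explicit = self.explicit_hydrogens(i)
        if explicit:
            return [(st.atoms[j].coords, j) for j in explicit]
        donor = a.coords
        key = (a.residue_name, a.name)
        bond = OH_BOND if a.element == "O" else NH_BOND
        neigh = self.neighbors(i)

        if key in ROTATABLE_DONORS or (a.is_hetero and len(neigh) <= 1):
            if acceptor_pos is None:
                return []
            if neigh:
                ante = st.atoms[neigh[0]].coords
                v1 = ante - donor
                v2 = acceptor_pos - donor
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                if cosang > 0.0:          # acceptor on the wrong side (< 90 deg)
                    return []
            return [(donor + bond * _unit(acceptor_pos - donor), None)]

        if len(neigh) >= 2:
            return [(p, None) for p in _sp2_bisector_h(
                donor, st.atoms[neigh[0]].coords, st.atoms[neigh[1]].coords, bond)]
        if len(neigh) == 1:
            n1 = neigh[0]
            n1_neigh = [j for j in self.neighbors(n1) if j != i]
            if not n1_neigh:
                return []
            return [(p, None) for p in _sp2_amide_h(
                donor, st.atoms[n1].coords, st.atoms[n1_neigh[0]].coords, bond)]
        return []


def _interface_chain_sides(interface: InterfaceDefinition):
    chains_a = {rid[0] for rid in interface.interface_residues_a}
    chains_b = {rid[0] for rid in interface.interface_residues_b}
    return chains_a, chains_b


def hydrogen_bonds(
    complex_structure: Structure,
    interface: InterfaceDefinition,
    h_acceptor_cutoff: float = 3.2,
    donor_angle_filter: bool = True,
    search_margin: float = 1.2,
) -> list[HydrogenBond]:
    """Cross-interface hydrogen bonds (donor and acceptor on opposite sides).

    The criterion is the H...acceptor distance <= *h_acceptor_cutoff*.
    Each donor hydrogen contributes at most one bond (its nearest
    acceptor).  With *donor_angle_filter* a D-H...A angle >= 90 degrees is
    additionally required (a sanity check standing in for the visual
    inspection step of the original protocol).
    """
    chains_a, chains_b = _interface_chain_sides(interface)
    if not chains_a or not chains_b:
        return []
    table = _DonorTable(complex_structure)

    def side_of(i):
        ch = complex_structure.atoms[i].chain_id
        if ch in chains_a:
            return "a"
        if ch in chains_b:
            return "b"
        return None

    donors = [i for i in table.heavy if table.is_donor(i) and side_of(i)]
    acceptors = [i for i in table.heavy if table.is_acceptor(i) and side_of(i)]
    if not donors or not acceptors:
        return []
    acc_coords = complex_structure.coords(acceptors)
    acc_tree = cKDTree(acc_coords)

    bonds: list[HydrogenBond] = []
    seen_hydrogens: set[tuple[int, int]] = set()
    for d in donors:
        d_side = side_of(d)
        d_pos = complex_structure.atoms[d].coords
        cand = [
            acceptors[j]
            for j in acc_tree.query_ball_point(d_pos, h_acceptor_cutoff + search_margin)
            if side_of(acceptors[j]) != d_side
        ]
        if not cand:
            continue
        # fixed/explicit hydrogens first
        fixed = table.hydrogen_positions(d)
        for h_pos, h_idx in fixed:
            best = None
            for acc in cand:
                a_pos = complex_structure.atoms[acc].coords
                dha = float(np.linalg.norm(a_pos - h_pos))
                if dha > h_acceptor_cutoff:
                    continue
                if donor_angle_filter:
                    v1 = d_pos - h_pos
                    v2 = a_pos - h_pos
                    denom = np.linalg.norm(v1) * np.linalg.norm(v2)
                    if denom > 0 and np.dot(v1, v2) / denom > 0.0:
                        continue  # D-H...A angle below 90 degrees
                if best is None or dha < best[0]:
                    best = (dha, acc)
            if best is not None:
                dha, acc = best
                bonds.append(HydrogenBond(
                    donor_index=d,
                    acceptor_index=acc,
                    hydrogen_coords=h_pos,
                    h_acceptor_distance=dha,
                    donor_acceptor_distance=float(np.linalg.norm(
                        complex_structure.atoms[acc].coords - d_pos)),
                    hydrogen_index=h_idx,
                ))
        if fixed:
            continue
        # rotatable donor: single H oriented toward the best acceptor
        best = None
        for acc in cand:
            a_pos = complex_structure.atoms[acc].coords
            placed = table.hydrogen_positions(d, acceptor_pos=a_pos)
            if not placed:
                continue
            h_pos, _ = placed[0]
            dha = float(np.linalg.norm(a_pos - h_pos))
            if dha > h_acceptor_cutoff:
                continue
            if best is None or dha < best[0]:
                best = (dha, acc, h_pos)
        if best is not None:
            dha, acc, h_pos = best
            bonds.append(HydrogenBond(
                donor_index=d,
                acceptor_index=acc,
                hydrogen_coords=h_pos,
                h_acceptor_distance=dha,
                donor_acceptor_distance=float(np.linalg.norm(
                    complex_structure.atoms[acc].coords - d_pos)),
            ))
    return bonds


def hb_density(n_bonds: int, interface: InterfaceDefinition) -> float:
    """Hydrogen bonds per 100 A^2 of interface (the Hb descriptor)."""
    if interface.asa_mean_side <= 0:
        raise ValueError("zero interface: hydrogen-bond density is undefined")
    return 100.0 * n_bonds / interface.asa_mean_side


def salt_bridges(
    complex_structure: Structure,
    interface: InterfaceDefinition,
    cutoff: float = 4.0,
) -> list[SaltBridge]:
    """Cross-interface salt bridges: Asp/Glu vs Arg/His/Lys below *cutoff*.

    One bridge is reported per acidic-basic residue pair (the minimum over
    functional-atom pairs), strictly below 4.0 A by default, with the two
    residues required to be interface residues on opposite sides.
    """
    resname_of: dict[tuple, str] = {}
    members: dict[tuple, dict[str, list[int]]] = {}
    wanted = interface.interface_residues_a | interface.interface_residues_b
    for i, a in enumerate(complex_structure.atoms):
        rid = a.residue_id
        if rid not in wanted:
            continue
        resname_of[rid] = a.residue_name
        for table in (ACIDIC_ATOMS, BASIC_ATOMS):
            names = table.get(a.residue_name)
            if names and a.name in names:
                members.setdefault(rid, {}).setdefault("atoms", []).append(i)

    def gather(residue_ids, table):
        found = {}
        for rid in residue_ids:
            if resname_of.get(rid) in table:
                atoms = members.get(rid, {}).get("atoms", [])
                if atoms:
                    found[rid] = atoms
                else:
                    warnings.warn(
                        f"charged residue {resname_of[rid]} {rid} has no "
                        "functional atoms; skipped in salt-bridge detection"
                    )
        return found

    acid_a = gather(interface.interface_residues_a, ACIDIC_ATOMS)
    base_a = gather(interface.interface_residues_a, BASIC_ATOMS)
    acid_b = gather(interface.interface_residues_b, ACIDIC_ATOMS)
    base_b = gather(interface.interface_residues_b, BASIC_ATOMS)

    bridges: list[SaltBridge] = []
    for acids, bases in ((acid_a, base_b), (acid_b, base_a)):
        for arid, ai in acids.items():
            ac = complex_structure.coords(ai)
            for brid, bi in bases.items():
                bc = complex_structure.coords(bi)
                d = np.linalg.norm(ac[:, None, :] - bc[None, :, :], axis=2).min()
                if d < cutoff:
                    bridges.append(SaltBridge(
                        acidic_residue=arid, basic_residue=brid, distance=float(d)
                    ))
    bridges.sort(key=lambda b: (b.acidic_residue, b.basic_residue))
    return bridges


def interface_segments(
    n_residues: int | Sequence,
    interface_mask: Sequence[bool],
    max_gap: int = 4,
) -> SegmentSet:
    """Split one chain's interface residues into continuous segments.

    Two interface residues belong to the same segment iff they are
    separated by at most *max_gap* consecutive non-interface residues.
    Segment length counts interface residues only.
    """
    mask = np.asarray(interface_mask, dtype=bool)
    if not np.isscalar(n_residues) and n_residues is not None:
        if len(mask) != len(n_residues):
            raise ValueError("interface mask not aligned with residue list")
    positions = np.flatnonzero(mask)
    segments: list[list[int]] = []
    current: list[int] = []
    for p in positions:
        if current and p - current[-1] - 1 > max_gap:
            segments.append(current)
            current = []
        current.append(int(p))
    if current:
        segments.append(current)
    return SegmentSet(segments=segments, n_segments=len(segments), max_gap=max_gap)


def segments_for_interface(
    complex_structure: Structure,
    interface: InterfaceDefinition,
    max_gap: int = 4,
) -> SegmentSet:
    """Total interface segment count over the chains of both partners."""
    all_iface = interface.interface_residues_a | interface.interface_residues_b
    chains = sorted({rid[0] for rid in all_iface})
    merged: list[list[int]] = []
    for ch in chains:
        residues = complex_structure.residues(ch)
        mask = [rid in all_iface for rid, _ in residues]
        seg = interface_segments(len(mask), mask, max_gap=max_gap)
        merged.extend(seg.segments)
    return SegmentSet(segments=merged, n_segments=len(merged), max_gap=max_gap)


def _dihedral(p0, p1, p2, p3) -> float:
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1u = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def assign_secondary_structure(structure: Structure, chain_id: str) -> list[str]:
    """Per-residue H/E/C assignment from backbone dihedral windows.

    Helix: phi in [-100, -30] and psi in [-80, -5]; strand: phi in
    [-180, -45] and psi in [80, 180] (or below -160).  Runs shorter than
    3 residues and residues at chain breaks fall back to coil.
    """
    residues = structure.residues(chain_id)
    backbone = []
    for rid, idxs in residues:
        atoms = {structure.atoms[i].name: structure.atoms[i].coords for i in idxs}
        backbone.append((rid, atoms))
    raw = ["C"] * len(backbone)
    for i in range(len(backbone)):
        if i == 0 or i == len(backbone) - 1:
            continue
        prev_a, cur_a, next_a = backbone[i - 1][1], backbone[i][1], backbone[i + 1][1]
        needed = ("C" in prev_a and all(k in cur_a for k in ("N", "CA", "C"))
                  and "N" in next_a)
        if not needed:
            continue
        # chain-break guard: peptide bond lengths must be plausible
        if (np.linalg.norm(cur_a["N"] - prev_a["C"]) > 2.0
                or np.linalg.norm(next_a["N"] - cur_a["C"]) > 2.0):
            continue
        phi = _dihedral(prev_a["C"], cur_a["N"], cur_a["CA"], cur_a["C"])
        psi = _dihedral(cur_a["N"], cur_a["CA"], cur_a["C"], next_a["N"])
        if -100.0 <= phi <= -30.0 and -80.0 <= psi <= -5.0:
            raw[i] = "H"
        elif -180.0 <= phi <= -45.0 and (psi >= 80.0 or psi <= -160.0):
            raw[i] = "E"
    # suppress runs shorter than 3
    out = ["C"] * len(raw)
    i = 0
    while i < len(raw):
        j = i
        while j < len(raw) and raw[j] == raw[i]:
            j += 1
        if raw[i] in ("H", "E") and j - i >= 3:
            for k in range(i, j):
                out[k] = raw[i]
        i = j
    return out


def _side_ss_fractions(structure, residue_ids):
    chains = sorted({rid[0] for rid in residue_ids})
    n = helix = strand = 0
    for ch in chains:
        residues = structure.residues(ch)
        ss = assign_secondary_structure(structure, ch)
        for (rid, _), code in zip(residues, ss):
            if rid in residue_ids:
                n += 1
                helix += code == "H"
                strand += code == "E"
    if n == 0:
        return 0.0, 0.0
    return 100.0 * helix / n, 100.0 * strand / n


def _ss_label(helix_pct: float, strand_pct: float) -> str:
    if helix_pct > 30.0 and strand_pct < 30.0:
        return "H"
    if helix_pct < 30.0 and strand_pct > 30.0:
        return "S"
    if helix_pct > 30.0 and strand_pct > 30.0:
        return "HS"
    return "C"


def ss_interface_class(
    complex_structure: Structure,
    interface: InterfaceDefinition,
) -> SSClass:
    """Four-way secondary-structure class of each side of the interface.

    H: >30% helix and <30% strand among interface residues; S: the
    converse; HS: both above 30%; C (coil): both below.
    """
    ha, sa = _side_ss_fractions(complex_structure, interface.interface_residues_a)
    hb, sb = _side_ss_fractions(complex_structure, interface.interface_residues_b)
    return SSClass(
        helix_fraction_a=ha, strand_fraction_a=sa,
        helix_fraction_b=hb, strand_fraction_b=sb,
        label_a=_ss_label(ha, sa), label_b=_ss_label(hb, sb),
    )
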