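"""Synthetic toy complexes and descriptor tables for pipeline testing.

Two kinds of geometry are emulated.  Class-I-like complexes bind a single
helical or extended peptide segment in a groove of a pseudo-protein slab:
few interface segments, small buried area.  Class-II-like complexes press
a serpentine multi-strand patch (a stand-in for a globular domain face)
onto a larger slab: 7-10 segments, larger buried area.  A flat variant
with a surface-lying ligand reproduces the situation of an inhibitor that
does not penetrate the target surface, where no pocket exists at the
interface.

Receptors are built from pseudo-residues (one CA-like interaction sphere
each, serpentine-numbered so that a contact patch maps onto few sequence
segments); peptides carry a real ideal backbone (helix phi/psi -57/-47,
strand -120/+120) so that dihedral-based secondary structure assignment
works on them.  Charged residues and hydrogen-bond sites are created by
renaming pseudo-residues and attaching functional atoms at canonical
distances, so salt-bridge and hydrogen-bond detection see realistic
geometry.  No physical realism beyond hard-sphere plausibility is
attempted.

Everything is deterministic under the spec seed; the same spec yields
byte-identical PDB output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ppiface.structure import Atom, Structure, PartnerSelection

SLAB_SPACING = 4.0
CONTACT_DISTANCE = 3.7     # target minimum heavy-atom distance at the interface

KINDS = ("class_I_helix_groove", "class_I_strand", "class_II_globular",
         "zipA_like_flat")


@dataclass
class ToyComplexSpec:
    kind: str = "class_I_helix_groove"
    target_interface_asa: tuple[float, float] | None = None   # expectation band, A^2
    n_interface_segments: int | None = None
    pct_charged: float = 19.0
    n_hbond_sites: int | None = None
    n_salt_bridge_pairs: int | None = None
    pocket_depth: float | None = None   # A; 0 = flat surface
    peptide_length: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown toy kind {self.kind!r}")
        defaults = {
            "class_I_helix_groove": dict(
                band=(150.0, 700.0), segments=4, hb=1, sb=0, depth=4.0, length=12),
            "class_I_strand": dict(
                band=(150.0, 700.0), segments=3, hb=1, sb=0, depth=4.0, length=10),
            "class_II_globular": dict(
                band=(500.0, 1300.0), segments=8, hb=7, sb=1, depth=0.0, length=None),
            "zipA_like_flat": dict(
                band=(100.0, 700.0), segments=3, hb=1, sb=0, depth=0.0, length=8),
        }[self.kind]
        if self.target_interface_asa is None:
            self.target_interface_asa = defaults["band"]
        if self.n_interface_segments is None:
            self.n_interface_segments = defaults["segments"]
        if self.n_hbond_sites is None:
            self.n_hbond_sites = defaults["hb"]
        if self.n_salt_bridge_pairs is None:
            self.n_salt_bridge_pairs = defaults["sb"]
        if self.pocket_depth is None:
            self.pocket_depth = defaults["depth"]
        if self.peptide_length is None:
            self.peptide_length = defaults["length"]
        if self.kind in ("class_I_helix_groove", "class_I_strand") \
                and self.n_interface_segments > 5:
            raise ValueError("class I specs require <= 5 interface segments")
        if self.kind == "class_II_globular" and self.n_interface_segments < 7:
            raise ValueError("class II specs require >= 7 interface segments")
        for count in (self.n_hbond_sites, self.n_salt_bridge_pairs):
            if count < 0:
                raise ValueError("site counts must be non-negative")


@dataclass
class ToyComplex:
    complex: Structure                # chains A (receptor) + B (partner)
    unbound: Structure                # receptor alone, jittered
    ligand_complex: Structure         # receptor + LIG hetero fragment
    selection: PartnerSelection
    ligand_selection: PartnerSelection
    manifest: dict


# ---------------------------------------------------------------- backbone

def _nerf(a, b, c, bond, angle_deg, dihedral_deg):
    """Place atom d given three reference atoms and internal coordinates."""
    angle = np.radians(angle_deg)
    dihedral = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(dihedral),
        bond * np.sin(angle) * np.sin(dihedral),
    ])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def build_peptide_backbone(n_res: int, phi: float, psi: float, omega: float = 180.0):
    """Ideal poly-backbone as a list of per-residue atom dicts (N, CA, C, O, CB)."""
    if n_res < 2:
        raise ValueError("need at least 2 residues")
    residues = []
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([1.458, 0.0, 0.0])
    c = _nerf(np.array([0.0, 1.0, 0.0]), n, ca, 1.525, 111.2, 0.0)
    residues.append({"N": n, "CA": ca, "C": c})
    for _ in range(1, n_res):
        n_next = _nerf(residues[-1]["N"], residues[-1]["CA"], residues[-1]["C"],
                       1.329, 116.2, psi)
        ca_next = _nerf(residues[-1]["CA"], residues[-1]["C"], n_next,
                        1.458, 121.7, omega)
        c_next = _nerf(residues[-1]["C"], n_next, ca_next, 1.525, 111.2, phi)
        residues.append({"N": n_next, "CA": ca_next, "C": c_next})
    for i, res in enumerate(residues):
        if i + 1 < len(residues):
            res["O"] = _nerf(residues[i + 1]["N"], res["CA"], res["C"],
                             1.231, 120.5, 180.0)
        else:
            res["O"] = _nerf(res["N"], res["CA"], res["C"], 1.231, 120.5, psi + 180.0)
        v1 = res["CA"] - res["N"]
        v2 = res["CA"] - res["C"]
        bisec = v1 / np.linalg.norm(v1) + v2 / np.linalg.norm(v2)
        perp = np.cross(v2, v1)
        direction = bisec / np.linalg.norm(bisec) + 0.9 * perp / np.linalg.norm(perp)
        res["CB"] = res["CA"] + 1.53 * direction / np.linalg.norm(direction)
    return residues


def _principal_axis(coords):
    x = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    axis = vt[0]
    if axis[np.argmax(np.abs(axis))] < 0:
        axis = -axis
    return axis


def _rotation_between(a, b):
    """Rotation matrix mapping unit vector a onto unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    s = np.linalg.norm(v)
    cth = np.dot(a, b)
    if s < 1e-12:
        return np.eye(3) if cth > 0 else -np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - cth) / s ** 2)


# ---------------------------------------------------------------- receptor

def _serpentine_layer(nx, ny, skip_rows=frozenset()):
    """(ix, iy) positions of one slab layer in serpentine sequence order."""
    cells = []
    for iy in range(ny):
        xs = range(nx) if iy % 2 == 0 else range(nx - 1, -1, -1)
        for ix in xs:
            if iy in skip_rows:
                continue
            cells.append((ix, iy))
    return cells


def _build_receptor(nx, ny, nz, groove_rows=frozenset(), chain="A"):
    """Slab of CA-only pseudo-residues; groove rows omitted from the top layer.

    Lower layers come first in sequence; the top (contact) layer is
    serpentine-numbered last so a surface patch maps onto few segments.
    """
    atoms = []
    seq = 1
    for iz in range(nz):
        skip = groove_rows if iz == nz - 1 else frozenset()
        for ix, iy in _serpentine_layer(nx, ny, skip):
            atoms.append(Atom(
                serial=0, name="CA", element="C",
                coords=np.array([ix * SLAB_SPACING, iy * SLAB_SPACING,
                                 iz * SLAB_SPACING]),
                residue_name="ALA", chain_id=chain, residue_seq=seq,
            ))
            seq += 1
    return atoms


def _renumber(atoms):
    for i, a in enumerate(atoms, start=1):
        a.serial = i
    return atoms


def _contact_shift(partner_coords, receptor_coords, contact=CONTACT_DISTANCE):
    """z-shift placing the partner at vdW contact above the receptor."""
    from scipy.spatial import cKDTree
    tree = cKDTree(receptor_coords)
    d, _ = tree.query(partner_coords, k=1)
    return contact - d.min()


def _clone_atom(a: Atom, **overrides) -> Atom:
    data = dict(
        serial=a.serial, name=a.name, element=a.element,
        coords=a.coords.copy(), residue_name=a.residue_name,
        chain_id=a.chain_id, residue_seq=a.residue_seq,
        insertion_code=a.insertion_code, is_hetero=a.is_hetero,
        occupancy=a.occupancy, altloc=a.altloc,
    )
    data.update(overrides)
    return Atom(**data)


# ---------------------------------------------------------------- assembly

def _attach_sites(receptor, partner, rng, spec, top_z):
    """Rename residues / add functional atoms for salt bridges, hydrogen
    bonds and the target charged-residue fraction.  Returns manifests."""
    partner_res = {}
    for a in partner:
        partner_res.setdefault(a.residue_seq, []).append(a)
    receptor_top = [a for a in receptor if abs(a.coords[2] - top_z) < 0.1]

    def nearest_receptor(pos, exclude):
        best, best_d = None, np.inf
        for a in receptor_top:
            if a.residue_seq in exclude:
                continue
            d = np.linalg.norm(a.coords[:2] - pos[:2])
            if d < best_d:
                best, best_d = a, d
        return best

    seqs = sorted(partner_res)
    interior = seqs[1:-1] if len(seqs) > 2 else list(seqs)
    # only contact-layer residues can carry interface sites (class II
    # serpentines have raised turn residues that never touch the receptor)
    z_floor = min(
        next(a for a in partner_res[s] if a.name == "CA").coords[2] for s in seqs)
    interior = [
        s for s in interior
        if next(a for a in partner_res[s] if a.name == "CA").coords[2]
        < z_floor + 2.5
    ]
    rng.shuffle(interior)
    used_receptor: set[int] = set()
    extra_atoms = []
    hb_pairs = []
    sb_pairs = []
    pool = list(interior)

    partner_coords = np.array([a.coords for a in partner])
    receptor_coords = np.array([a.coords for a in receptor])

    def clearance(pos, against, min_d, ignore=None):
        """True when *pos* keeps min_d from every row of *against*."""
        d = np.linalg.norm(against - pos, axis=1)
        if ignore is not None:
            d = d[d > ignore]            # drop the intended close contact
        return d.size == 0 or d.min() >= min_d

    def extras_clear(pos, min_d=2.0):
        return all(np.linalg.norm(e.coords - pos) >= min_d for e in extra_atoms)

    def pop_feasible(check):
        for k, seq in enumerate(pool):
            placement = check(seq)
            if placement is not None:
                del pool[k]
                return seq, placement
        return None, None

    for _ in range(spec.n_salt_bridge_pairs):
        def check_sb(seq):
            ca = next(a for a in partner_res[seq] if a.name == "CA")
            nz = ca.coords + np.array([0.0, 0.0, -1.8])
            od1 = nz + np.array([0.0, 0.0, -3.5])
            od2 = od1 + np.array([1.1, 0.0, -0.6])
            # nz travels with the ligand fragment: keep it off the receptor;
            # od1/od2 are receptor side: keep them off the partner
            if not (clearance(nz, receptor_coords, 2.2) and extras_clear(nz)
                    and clearance(od1, partner_coords, 2.2)
                    and clearance(od2, partner_coords, 2.2)
                    and extras_clear(od1) and extras_clear(od2)):
                return None
            return ca, nz, od1, od2
        seq, placement = pop_feasible(check_sb)
        if seq is None:
            raise ValueError("infeasible spec: cannot place the requested "
                             "number of salt bridges on the interface")
        ca, nz, od1, od2 = placement
        for a in partner_res[seq]:
            a.residue_name = "LYS"
        extra_atoms.append(_clone_atom(ca, name="NZ", element="N", coords=nz))
        racc = nearest_receptor(ca.coords, used_receptor)
        used_receptor.add(racc.residue_seq)
        racc.residue_name = "ASP"
        for name, pos in (("OD1", od1), ("OD2", od2)):
            extra_atoms.append(_clone_atom(racc, name=name, element="O", coords=pos))
        sb_pairs.append((seq, racc.residue_seq))

    for _ in range(spec.n_hbond_sites):
        def check_hb(seq):
            ca = next(a for a in partner_res[seq] if a.name == "CA")
            o_bb = next((a for a in partner_res[seq] if a.name == "O"), None)
            if o_bb is not None:
                og = o_bb.coords + np.array([0.0, 0.0, -2.8])
                # donor is receptor side: 2.8 A to its acceptor, clear of
                # every other partner atom and of the receptor core
                if (clearance(og, partner_coords, 2.3, ignore=None)
                        and extras_clear(og)):
                    return ("receptor_donor", ca, o_bb, og)
                return None
            og = ca.coords + np.array([0.0, 0.0, -1.3])
            oacc = og + np.array([0.0, 0.0, -2.8])
            if (clearance(og, receptor_coords, 2.2) and extras_clear(og)
                    and clearance(oacc, partner_coords, 2.3)
                    and extras_clear(oacc)):
                return ("partner_donor", ca, None, (og, oacc))
            return None
        seq, placement = pop_feasible(check_hb)
        if seq is None:
            break
        racc = nearest_receptor(
            next(a for a in partner_res[seq] if a.name == "CA").coords,
            used_receptor)
        used_receptor.add(racc.residue_seq)
        if placement[0] == "receptor_donor":
            _, ca, o_bb, og = placement
            racc.residue_name = "SER"
            extra_atoms.append(_clone_atom(racc, name="OG", element="O", coords=og))
        else:
            _, ca, _, (og, oacc) = placement
            for a in partner_res[seq]:
                a.residue_name = "SER"
            extra_atoms.append(_clone_atom(ca, name="OG", element="O", coords=og))
            extra_atoms.append(_clone_atom(racc, name="O", element="O", coords=oacc))
        hb_pairs.append((seq, racc.residue_seq))
    take = 0
    interior = pool

    # additional charged residues (functional atoms pointing away from the
    # interface so they do not create extra bridges)
    n_iface_est = len(seqs) + len(used_receptor) + 6
    n_charged_target = int(round(spec.pct_charged / 100.0 * n_iface_est))
    charged = [partner_res[s][0].residue_seq for s, r in sb_pairs] if sb_pairs else []
    extra_charged = []
    for seq in interior[take:]:
        if len(charged) + len(extra_charged) >= n_charged_target:
            break
        ca = next(a for a in partner_res[seq] if a.name == "CA")
        for a in partner_res[seq]:
            a.residue_name = "LYS"
        nz = ca.coords + np.array([0.0, 0.0, +2.8])
        extra_atoms.append(_clone_atom(ca, name="NZ", element="N", coords=nz))
        extra_charged.append(seq)
    return extra_atoms, hb_pairs, sb_pairs, charged + extra_charged


def _peptide_atoms(residues, chain, start_seq=1):
    atoms = []
    for i, res in enumerate(residues):
        for name in ("N", "CA", "C", "O", "CB"):
            el = name[0]
            atoms.append(Atom(
                serial=0, name=name, element=el, coords=np.asarray(res[name], float),
                residue_name="ALA", chain_id=chain, residue_seq=start_seq + i,
            ))
    return atoms


def _serpentine_partner(n_strands, strand_len, chain="B", turn_len=5):
    """CA-only serpentine: n_strands contact strands linked by raised turns.

    Turns are *turn_len* residues lifted away from the interface: longer
    than the default segment-merging gap, so each strand is counted as its
    own interface segment.
    """
    atoms = []
    seq = 1
    xstep, ystep, lift = 3.5, 4.5, 6.0
    for s in range(n_strands):
        xs = range(strand_len) if s % 2 == 0 else range(strand_len - 1, -1, -1)
        for ix in xs:
            atoms.append(Atom(
                serial=0, name="CA", element="C",
                coords=np.array([ix * xstep, s * ystep, 0.0]),
                residue_name="ALA", chain_id=chain, residue_seq=seq,
            ))
            seq += 1
        if s + 1 < n_strands:
            edge = (strand_len - 1) * xstep if s % 2 == 0 else 0.0
            off = xstep if s % 2 == 0 else -xstep
            for t in range(turn_len):
                frac = (t + 1) / (turn_len + 1)
                atoms.append(Atom(
                    serial=0, name="CA", element="C",
                    coords=np.array([edge + off, (s + frac) * ystep, lift]),
                    residue_name="GLY", chain_id=chain, residue_seq=seq,
                ))
                seq += 1
    return atoms


def build_toy_complex(spec: ToyComplexSpec) -> ToyComplex:
    """Build the protein/protein, unbound and protein/ligand forms of a toy.

    Deterministic under ``spec.seed``.  The manifest records the intended
    ground truth (class, segment/bond/bridge bookkeeping, expectation band
    for the buried area).
    """
    rng = np.random.default_rng(spec.seed)

    if spec.kind in ("class_I_helix_groove", "class_I_strand", "zipA_like_flat"):
        nx, ny, nz = 10, 7, 2
        groove = frozenset({3}) if spec.pocket_depth and spec.pocket_depth > 0 else frozenset()
        receptor = _build_receptor(nx, ny, nz, groove_rows=groove)
        phi, psi = ((-57.0, -47.0) if spec.kind == "class_I_helix_groove"
                    else (-120.0, 120.0))
        residues = build_peptide_backbone(spec.peptide_length, phi, psi)
        partner = _peptide_atoms(residues, chain="B")
        pc = np.array([a.coords for a in partner])
        rot = _rotation_between(_principal_axis(pc), np.array([1.0, 0.0, 0.0]))
        pc = (pc - pc.mean(axis=0)) @ rot.T
        top_z = (nz - 1) * SLAB_SPACING
        target_center = np.array([(nx - 1) * SLAB_SPACING / 2.0,
                                  3 * SLAB_SPACING, top_z + 3.0])
        pc = pc + target_center
        rc = np.array([a.coords for a in receptor])
        pc[:, 2] += _contact_shift(pc, rc)
        for a, xyz in zip(partner, pc):
            a.coords = xyz
    elif spec.kind == "class_II_globular":
        # receptor narrower than the strand patch so its contacted rows
        # merge into a single sequence segment
        nx, ny, nz = 7, 12, 2
        receptor = _build_receptor(nx, ny, nz)
        n_strands = max(spec.n_interface_segments - 1, 2)
        partner = _serpentine_partner(n_strands, strand_len=6)
        pc = np.array([a.coords for a in partner])
        top_z = (nz - 1) * SLAB_SPACING
        strand_mask = np.array([a.residue_name == "ALA" for a in partner])
        shift = np.array([1.5 - pc[strand_mask, 0].min(),
                          2.0 - pc[strand_mask, 1].min(),
                          top_z + 3.0 - pc[:, 2].min()])
        pc = pc + shift
        rc = np.array([a.coords for a in receptor])
        pc[:, 2] += _contact_shift(pc, rc)
        for a, xyz in zip(partner, pc):
            a.coords = xyz
    else:  # pragma: no cover
        raise ValueError(spec.kind)

    top_z = (nz - 1) * SLAB_SPACING
    extra, hb_pairs, sb_pairs, charged = _attach_sites(
        receptor, partner, rng, spec, top_z)

    complex_atoms = _renumber([
        _clone_atom(a) for a in receptor + extra + partner
        if True
    ])
    # keep chain A atoms first, then chain B
    complex_atoms.sort(key=lambda a: (a.chain_id, a.residue_seq))
    complex_atoms = _renumber(complex_atoms)
    cx = Structure(atoms=complex_atoms, id=f"toy-{spec.kind}-{spec.seed}")

    # unbound receptor: same atoms, small seeded jitter
    unbound_atoms = []
    for a in complex_atoms:
        if a.chain_id != "A":
            continue
        unbound_atoms.append(_clone_atom(
            a, coords=a.coords + rng.normal(0.0, 0.2, size=3)))
    unbound = Structure(atoms=_renumber(unbound_atoms),
                        id=f"toy-{spec.kind}-{spec.seed}-unbound")

    # ligand form: receptor + truncated partner fragment as hetero LIG
    partner_sorted = [a for a in complex_atoms if a.chain_id == "B"]
    seqs = sorted({a.residue_seq for a in partner_sorted})
    if spec.kind == "zipA_like_flat":
        keep = set(seqs)          # the whole surface-lying fragment
    else:
        lo = len(seqs) // 4
        keep = set(seqs[lo:lo + max(len(seqs) // 2, 2)])
    lig_atoms = []
    for i, a in enumerate(
            a for a in partner_sorted
            if a.residue_seq in keep and not a.is_hydrogen):
        lig_atoms.append(_clone_atom(
            a, chain_id="L", residue_name="LIG", residue_seq=1,
            is_hetero=True, name=f"{a.element}{i + 1}"))
    lig_structure_atoms = _renumber(
        [_clone_atom(a) for a in complex_atoms if a.chain_id == "A"] + lig_atoms)
    ligand_complex = Structure(atoms=lig_structure_atoms,
                               id=f"toy-{spec.kind}-{spec.seed}-lig")

    manifest = {
        "kind": spec.kind,
        "seed": spec.seed,
        "ppi_class": "II" if spec.kind == "class_II_globular" else "I",
        "intended_segments": spec.n_interface_segments,
        "target_interface_asa": list(spec.target_interface_asa),
        "hbond_pairs": hb_pairs,
        "salt_bridge_pairs": sb_pairs,
        "charged_partner_residues": charged,
        "pocket_depth": spec.pocket_depth,
        "n_receptor_atoms": sum(a.chain_id == "A" for a in complex_atoms),
        "n_partner_atoms": sum(a.chain_id == "B" for a in complex_atoms),
    }
    return ToyComplex(
        complex=cx,
        unbound=unbound,
        ligand_complex=ligand_complex,
        selection=PartnerSelection(side_a={"A"}, side_b={"B"}),
        ligand_selection=PartnerSelection(side_a={"A"}, side_b=set(),
                                          ligand=("LIG", "L", None)),
        manifest=manifest,
    )


# ------------------------------------------------------- descriptor tables

def default_class_params() -> dict[str, dict[str, tuple[float, float]]]:
    """Class-conditional (mean, sd) for the six key descriptors.

    Taken from the bundled reference panel's class aggregates; the
    charged-residue percentage, whose per-complex values are not
    published, uses the published overall moments for both classes.
    """
    from ppiface.reference_data import (
        load_reference, aggregate, KEY_DESCRIPTORS, PCT_CHARGED_OVERALL,
    )
    ref = load_reference()
    out: dict[str, dict[str, tuple[float, float]]] = {"I": {}, "II": {}}
    for cls, subset in (("I", "classI"), ("II", "classII")):
        for d in KEY_DESCRIPTORS:
            if d == "pct_charged_residues":
                out[cls][d] = PCT_CHARGED_OVERALL
            else:
                g = aggregate(ref, d, subset)
                out[cls][d] = (g.mean, g.sd)
    return out


#: descriptors whose simulated values are rounded to integer counts
_COUNT_DESCRIPTORS = {"n_segments", "salt_bridges"}
_PERCENT_DESCRIPTORS = {"pct_charged_residues", "h_asa_percent"}


def simulate_descriptor_table(
    class_params: dict[str, dict[str, tuple[float, float]]] | None = None,
    n_per_class: dict[str, int] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Class-conditional Gaussian descriptor panels with known labels.

    Descriptors are drawn independently per class from (mean, sd),
    truncated to valid ranges (counts rounded and floored at 0, percents
    clipped to [0, 100], areas/volumes floored at 0).  Returns the panel
    DataFrame and the true class labels.
    """
    if class_params is None:
        class_params = default_class_params()
    if n_per_class is None:
        n_per_class = {"I": 6, "II": 11}
    rng = np.random.default_rng(seed)
    rows = []
    labels = []
    for cls in sorted(n_per_class):
        params = class_params[cls]
        n = n_per_class[cls]
        if n < 1:
            raise ValueError("n_per_class entries must be >= 1")
        draws = {}
        for d, (mean, sd) in params.items():
            if sd < 0:
                raise ValueError(f"negative sd for descriptor {d!r}")
            x = rng.normal(mean, sd, size=n)
            if d in _COUNT_DESCRIPTORS:
                x = np.maximum(np.round(x), 0)
            elif d in _PERCENT_DESCRIPTORS:
                x = np.clip(x, 0.0, 100.0)
            else:
                x = np.maximum(x, 0.0)
            draws[d] = x
        for i in range(n):
            rows.append({d: draws[d][i] for d in params})
            labels.append(cls)
    panel = pd.DataFrame(rows)
    panel.index = [f"sim_{lab}_{i}" for i, lab in enumerate(labels)]
    return panel, np.array(labels)
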