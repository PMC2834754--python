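"""SASA estimator and the buried-surface interface definition."""

import numpy as np
import pytest

from ppiface.structure import PartnerSelection
from ppiface.sasa import (
    shrake_rupley, define_interface, ligand_neighborhood, vdw_radius,
)
from tests.conftest import make_structure


def quadrature_sasa(coords, radii, probe=1.4, n_theta=200, n_phi=400):
    """Independent oracle: latitude-band spherical quadrature.

    Integrates the exposed fraction of each extended sphere on a regular
    (theta, phi) grid with correct sin(theta) area weights - a different
    discretization from the Fibonacci point lattice under test.
    """
    total = 0.0
    per_atom = []
    ext = np.asarray(radii) + probe
    theta = (np.arange(n_theta) + 0.5) * np.pi / n_theta
    phi = (np.arange(n_phi) + 0.5) * 2 * np.pi / n_phi
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    dirs = np.stack([np.sin(tt) * np.cos(pp), np.sin(tt) * np.sin(pp),
                     np.cos(tt)], axis=-1).reshape(-1, 3)
    weights = np.repeat(np.sin(theta), n_phi)
    weights = weights / weights.sum()
    for i, (c, r) in enumerate(zip(coords, ext)):
        pts = c + r * dirs
        exposed = np.ones(len(pts), dtype=bool)
        for j, (c2, r2) in enumerate(zip(coords, ext)):
            if j == i:
                continue
            exposed &= np.sum((pts - c2) ** 2, axis=1) >= r2 ** 2
        area = float(np.sum(weights[exposed])) * 4 * np.pi * r * r
        per_atom.append(area)
        total += area
    return total, per_atom


class TestShrakeRupley:
    def test_isolated_sphere_analytic(self):
        st = make_structure([[0.0, 0.0, 0.0]])
        res = shrake_rupley(st)
        exact = 4 * np.pi * (1.70 + 1.4) ** 2
        assert res.total == pytest.approx(exact, rel=0.01)
        assert res.total == pytest.approx(120.76, rel=0.01)

    def test_distant_atoms_additive(self):
        st = make_structure([[0.0, 0.0, 0.0], [50.0, 0.0, 0.0]],
                            elements=["C", "N"])
        res = shrake_rupley(st)
        exact = 4 * np.pi * ((1.70 + 1.4) ** 2 + (1.55 + 1.4) ** 2)
        assert res.total == pytest.approx(exact, rel=1e-6)

    def test_linear_triple_matches_quadrature_oracle(self):
        coords = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0], [4.0, 0.0, 0.0]])
        st = make_structure(coords, elements=["C", "N", "O"])
        res = shrake_rupley(st)
        radii = [vdw_radius(e) for e in ("C", "N", "O")]
        oracle_total, oracle_atoms = quadrature_sasa(coords, radii)
        assert res.total == pytest.approx(oracle_total, rel=0.02)
        for i, area in enumerate(oracle_atoms):
            assert res.per_atom_area[i] == pytest.approx(area, rel=0.03, abs=0.5)

    def test_agrees_with_independent_library(self):
        import biotite.structure as struc
        rng = np.random.default_rng(5)
        n = 40
        coords = rng.normal(0.0, 4.0, size=(n, 3))
        elements = list(rng.choice(["C", "N", "O"], size=n))
        st = make_structure(coords, elements=elements)
        res = shrake_rupley(st)
        arr = struc.AtomArray(n)
        arr.coord = coords.astype(np.float32)
        arr.element = elements
        arr.atom_name = ["CA"] * n
        arr.res_name = ["ALA"] * n
        arr.res_id = np.arange(1, n + 1)
        arr.chain_id = ["A"] * n
        ref = struc.sasa(arr, probe_radius=1.4, point_number=960,
                         vdw_radii="Single")
        assert res.total == pytest.approx(float(ref.sum()), rel=0.02)

    def test_monotonicity_adding_atom_never_increases_area(self):
        rng = np.random.default_rng(11)
        coords = rng.normal(0.0, 3.0, size=(12, 3))
        st_small = make_structure(coords[:-1])
        st_full = make_structure(coords)
        a = shrake_rupley(st_small).per_atom_area
        b = shrake_rupley(st_full).per_atom_area
        for i in range(11):
            assert b[i] <= a[i] + 1e-9

    def test_hydrogens_excluded(self):
        st = make_structure([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]],
                            elements=["C", "H"], names=["CA", "HA"])
        res = shrake_rupley(st)
        assert 1 not in res.per_atom_area
        assert res.total == pytest.approx(4 * np.pi * 3.10 ** 2, rel=0.01)

    def test_missing_radius_named(self):
        st = make_structure([[0.0, 0.0, 0.0]], elements=["XX"])
        with pytest.raises(KeyError, match="XX"):
            shrake_rupley(st)


def _plate_complex(separation=4.0, n=5, spacing=2.0):
    """Two parallel n x n pseudo-atom plates, chains A and B."""
    coords = []
    chains = []
    for z, ch in ((0.0, "A"), (separation, "B")):
        for i in range(n):
            for j in range(n):
                coords.append([i * spacing, j * spacing, z])
                chains.append(ch)
    return make_structure(coords, chain_ids=chains,
                          residue_seqs=list(range(1, len(coords) + 1)))


class TestDefineInterface:
    def test_disjoint_partners_zero_interface(self):
        st = make_structure([[0.0, 0.0, 0.0], [50.0, 0.0, 0.0]],
                            chain_ids=["A", "B"])
        iface = define_interface(st, PartnerSelection({"A"}, {"B"}))
        assert iface.delta_asa_side_a == 0.0
        assert iface.delta_asa_side_b == 0.0
        assert not iface.interface_residues_a

    def test_mirror_symmetric_dimer(self):
        # the deterministic sphere lattice is not mirror-symmetric, so the
        # two sides converge together only as the point count grows
        st = _plate_complex()
        iface = define_interface(st, PartnerSelection({"A"}, {"B"}),
                                 n_points=4000)
        assert iface.delta_asa_side_a == pytest.approx(
            iface.delta_asa_side_b, rel=0.01)
        assert iface.asa_mean_side > 0

    def test_delta_asa_identity_exact(self):
        # dA + dB = SASA(A) + SASA(B) - SASA(AB), by construction exact
        st = _plate_complex()
        sel = PartnerSelection({"A"}, {"B"})
        iface = define_interface(st, sel, atom_burial_threshold=0.1)
        idx_a = st.atom_indices({"A"})
        idx_b = st.atom_indices({"B"})
        sa = shrake_rupley(st, idx_a).total
        sb = shrake_rupley(st, idx_b).total
        sab = shrake_rupley(st, idx_a + idx_b).total
        assert iface.delta_asa_total == pytest.approx(sa + sb - sab, abs=1e-6)

    def test_plate_interface_matches_quadrature_oracle(self):
        st = _plate_complex()
        sel = PartnerSelection({"A"}, {"B"})
        iface = define_interface(st, sel)
        coords = st.coords()
        radii = [1.70] * len(coords)
        total_ab, _ = quadrature_sasa(coords, radii, n_theta=100, n_phi=200)
        total_a, _ = quadrature_sasa(coords[:25], radii[:25],
                                     n_theta=100, n_phi=200)
        total_b, _ = quadrature_sasa(coords[25:], radii[25:],
                                     n_theta=100, n_phi=200)
        oracle_mean_side = 0.5 * (total_a + total_b - total_ab)
        assert iface.asa_mean_side == pytest.approx(oracle_mean_side, rel=0.05)

    def test_interface_shrinks_with_threshold(self):
        st = _plate_complex()
        sel = PartnerSelection({"A"}, {"B"})
        sizes = []
        for thr in (0.1, 1.0, 5.0, 20.0):
            iface = define_interface(st, sel, atom_burial_threshold=thr)
            sizes.append(len(iface.interface_atoms_a))
        assert sizes == sorted(sizes, reverse=True)

    def test_empty_side_rejected(self):
        st = make_structure([[0.0, 0.0, 0.0]], chain_ids=["A"])
        with pytest.raises(ValueError):
            define_interface(st, PartnerSelection({"A"}, {"B"}))


class TestLigandCoverage:
    def test_full_partner_copy_covers_everything(self, toys):
        """The flat-surface toy's ligand is an exact copy of the partner's
        atoms, so it hides 100% of the partner-caused interface burial."""
        from ppiface.sasa import ligand_coverage
        toy = toys["zipA_like_flat"]
        iface = define_interface(toy.complex, toy.selection)
        pct = ligand_coverage(toy.ligand_complex, toy.ligand_selection,
                              iface, toy.complex)
        assert pct == pytest.approx(100.0, abs=1e-6)

    def test_distant_ligand_covers_nothing(self, toys):
        from ppiface.sasa import ligand_coverage
        from ppiface.structure import Structure
        import copy
        toy = toys["zipA_like_flat"]
        iface = define_interface(toy.complex, toy.selection)
        moved = []
        for a in toy.ligand_complex.atoms:
            b = copy.deepcopy(a)
            if b.is_hetero:
                b.coords = b.coords + np.array([200.0, 0.0, 0.0])
            moved.append(b)
        far = Structure(atoms=moved, id="far")
        pct = ligand_coverage(far, toy.ligand_selection, iface, toy.complex)
        assert pct == pytest.approx(0.0, abs=1e-6)

    def test_partial_fragment_between_bounds(self, toys):
        from ppiface.sasa import ligand_coverage
        toy = toys["class_I_helix_groove"]   # ligand = middle ~half of peptide
        iface = define_interface(toy.complex, toy.selection)
        pct = ligand_coverage(toy.ligand_complex, toy.ligand_selection,
                              iface, toy.complex)
        assert 10.0 < pct < 95.0


class TestLigandNeighborhood:
    def test_cutoff_is_closed_interval(self):
        st = make_structure(
            [[0.0, 0.0, 0.0], [4.4, 0.0, 0.0], [4.6, 0.0, 0.0]],
            chain_ids=["L", "A", "A"],
            hetero=[True, False, False])
        atoms, residues = ligand_neighborhood(st, [0], cutoff=4.5)
        assert atoms == {1}
        assert len(residues) == 1

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(3)
        prot = rng.uniform(0.0, 20.0, size=(60, 3))
        lig = rng.uniform(5.0, 15.0, size=(8, 3))
        coords = np.vstack([prot, lig])
        st = make_structure(
            coords,
            chain_ids=["A"] * 60 + ["L"] * 8,
            hetero=[False] * 60 + [True] * 8)
        lig_idx = list(range(60, 68))
        atoms, _ = ligand_neighborhood(st, lig_idx, cutoff=4.5)
        brute = set()
        for i in range(60):
            for j in lig_idx:
                if np.linalg.norm(coords[i] - coords[j]) <= 4.5:
                    brute.add(i)
        assert atoms == brute

    def test_empty_ligand_rejected(self):
        st = make_structure([[0.0, 0.0, 0.0]])
        with pytest.raises(ValueError):
            ligand_neighborhood(st, [])
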