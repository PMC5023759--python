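"""Interface scoring: area, residues, H-bonds, energies, class labels."""

import numpy as np
import pytest
import biotite.structure as struc
from scipy.spatial.distance import cdist

import dimerscan as ds
from dimerscan import forcefield as ff
from dimerscan.scoring import (
    binding_energy,
    classify_interface,
    detect_hbonds,
    interface_area,
    interface_classes,
    interface_residues,
    per_atom_burial,
    score_dimer,
)
from dimerscan.structure import Structure, rotation_about_z


def toy_structure(atoms_spec):
    """Build a small structure from (chain, res_id, res_name, name, el, xyz)."""
    n = len(atoms_spec)
    arr = struc.AtomArray(n)
    arr.coord = np.array([a[5] for a in atoms_spec], dtype=float)
    arr.chain_id = np.array([a[0] for a in atoms_spec], dtype="U4")
    arr.res_id = np.array([a[1] for a in atoms_spec], dtype=int)
    arr.res_name = np.array([a[2] for a in atoms_spec], dtype="U5")
    arr.atom_name = np.array([a[3] for a in atoms_spec], dtype="U6")
    arr.element = np.array([a[4] for a in atoms_spec], dtype="U2")
    arr.hetero = np.zeros(n, dtype=bool)
    return Structure(arr)


class TestInterfaceClasses:
    def test_exactly_28_canonical_labels(self):
        labels = interface_classes()
        assert len(labels) == 28
        assert len(set(labels)) == 28
        for lab in labels:
            a, b = lab.split("_")
            assert a <= b

    def test_far_apart_pose_is_none(self, far_dimer):
        assert classify_interface(far_dimer) == "none"

    def test_symmetric_tm45_pose(self, matched_pose):
        assert classify_interface(matched_pose.structure) == "45_45"

    def test_constructed_heterotypic_contact(self, monomer):
        # A presents its TM4/TM5 face, B its TM7/TM1 face
        poses = ds.enumerate_dimer_poses(monomer, steps_a=2, steps_b=7)
        by_grid = {p.grid_index: p for p in poses}
        label = classify_interface(by_grid[(1, 4)].structure)
        assert label == "45_71"


class TestInterfaceArea:
    def test_far_apart_dimer_buries_nothing(self, far_dimer):
        assert interface_area(far_dimer) == 0.0

    def test_chain_swap_symmetry(self, matched_pose):
        dimer = matched_pose.structure
        swapped = dimer.copy()
        cid = swapped.atoms.chain_id.copy()
        swapped.atoms.chain_id = np.where(cid == "A", "B", "A")
        a1 = interface_area(dimer)
        a2 = interface_area(swapped)
        assert a1 == pytest.approx(a2, rel=1e-9)

    def test_burial_sum_matches_three_term_difference(self, matched_pose):
        # independent recomputation at a different quadrature density
        dimer = matched_pose.structure
        fast = per_atom_burial(dimer).sum()
        dense = interface_area(dimer, n_points=240)
        assert fast == pytest.approx(dense, rel=0.05)

    def test_subadditivity_bound(self, matched_pose):
        from dimerscan.sasa import shrake_rupley
        dimer = matched_pose.structure
        mask_a = dimer.atoms.chain_id == "A"
        sasa_a = shrake_rupley(dimer.coord[mask_a],
                               dimer.atoms.element[mask_a]).sum()
        area = interface_area(dimer)
        assert 0.0 <= area <= sasa_a


class TestInterfaceResidues:
    def test_far_apart_dimer_has_empty_sets(self, far_dimer):
        res = interface_residues(far_dimer)
        assert res == {"A": [], "B": []}

    def test_threshold_monotonicity(self, matched_pose):
        burial = per_atom_burial(matched_pose.structure)
        loose = interface_residues(matched_pose.structure, 0.1, burial=burial)
        strict = interface_residues(matched_pose.structure, 10.0, burial=burial)
        for chain in ("A", "B"):
            assert set(strict[chain]) <= set(loose[chain])
            assert len(loose[chain]) > 0

    def test_reported_residues_exceed_threshold(self, matched_pose):
        # per-residue burial recomputed independently from the dense path
        dimer = matched_pose.structure
        threshold = 1.0
        reported = interface_residues(dimer, threshold)
        burial = per_atom_burial(dimer, n_points=144)
        atoms = dimer.atoms
        for chain in ("A", "B"):
            chain_mask = atoms.chain_id == chain
            for rid in np.unique(atoms.res_id[chain_mask]):
                b = burial[chain_mask & (atoms.res_id == rid)].sum()
                # wide margins absorb the quadrature difference between the
                # two point densities
                if b > 5 * threshold:
                    assert int(rid) in reported[chain]
                if b < threshold / 5:
                    assert int(rid) not in reported[chain]


class TestHydrogenBonds:
    def base_pair(self, d, angle_deg=180.0):
        # donor N with antecedent C; acceptor backbone O on the other chain
        a = np.deg2rad(180.0 - angle_deg)
        ant = np.array([-1.2 * np.cos(a), -1.2 * np.sin(a), 0.0])
        return toy_structure([
            ("A", 1, "GLY", "C", "C", tuple(ant)),
            ("A", 1, "GLY", "N", "N", (0.0, 0.0, 0.0)),
            ("B", 2, "GLY", "O", "O", (d, 0.0, 0.0)),
            ("B", 2, "GLY", "C", "C", (d + 1.2, 0.0, 0.0)),
        ])

    def test_collinear_pair_at_optimum_scores_full_depth(self):
        config = ff.EnergyConfig()
        bonds = detect_hbonds(self.base_pair(2.9), config)
        assert len(bonds) == 1
        assert bonds[0].energy == pytest.approx(-config.hbond_eps, abs=1e-9)

    def test_pair_beyond_distance_cutoff_not_reported(self):
        assert detect_hbonds(self.base_pair(5.0)) == []

    def test_pair_below_angle_cutoff_not_reported(self):
        assert detect_hbonds(self.base_pair(2.9, angle_deg=90.0)) == []

    def test_energy_in_well_range_and_summable(self, matched_pose):
        bonds = detect_hbonds(matched_pose.structure)
        config = ff.EnergyConfig()
        for b in bonds:
            assert -config.hbond_eps - 1e-9 <= b.energy <= 0.0
        be = binding_energy(matched_pose.structure)
        assert be.hbond_energy == pytest.approx(sum(b.energy for b in bonds),
                                                abs=1e-9)


class TestBindingEnergy:
    def test_infinite_separation_is_zero(self, far_dimer):
        be = binding_energy(far_dimer)
        assert be.dg_bind == 0.0
        assert be.interface_score == 0.0
        assert be.hbond_energy == 0.0

    def test_global_rigid_motion_invariance(self, matched_pose):
        dimer = matched_pose.structure
        be1 = binding_energy(dimer)
        rot = rotation_about_z(73.0) @ np.array(
            [[1, 0, 0], [0, np.cos(0.3), -np.sin(0.3)],
             [0, np.sin(0.3), np.cos(0.3)]])
        moved = dimer.transformed(rotation=rot, translation=np.array([5., -3., 11.]))
        be2 = binding_energy(moved)
        # coordinates carry PDB (float32) precision; 1e-6 relative agreement
        assert be2.dg_bind == pytest.approx(be1.dg_bind, rel=1e-6, abs=1e-5)
        assert be2.interface_score == pytest.approx(be1.interface_score,
                                                    rel=1e-6, abs=1e-5)
        assert be2.hbond_energy == pytest.approx(be1.hbond_energy,
                                                 rel=1e-6, abs=1e-5)

    def test_cross_terms_equal_three_term_difference(self, matched_pose):
        # dg_bind must equal E(AB) - E(A) - E(B) computed with full pair sums
        dimer = matched_pose.structure
        config = ff.EnergyConfig()
        mask_a = dimer.atoms.chain_id == "A"
        pa = ff.type_atoms(dimer.atoms[mask_a], config)
        pb = ff.type_atoms(dimer.atoms[~mask_a], config)
        pab = ff.type_atoms(dimer.atoms, config)
        e_ab = ff.internal_energy(dimer.coord, pab, config)
        e_a = ff.internal_energy(dimer.coord[mask_a], pa, config)
        e_b = ff.internal_energy(dimer.coord[~mask_a], pb, config)
        be = binding_energy(dimer)
        assert be.dg_bind == pytest.approx(e_ab - e_a - e_b, abs=1e-6)

    def test_clash_flagged_and_capped(self):
        s = toy_structure([
            ("A", 1, "GLY", "CA", "C", (0.0, 0.0, 0.0)),
            ("B", 2, "GLY", "CA", "C", (0.3, 0.0, 0.0)),
        ])
        be = binding_energy(s)
        assert be.clash
        assert be.dg_bind <= ff.DEFAULT_CONFIG.clash_cap


class TestScoreRecord:
    def test_score_dimer_consistency(self, matched_pose):
        rec = score_dimer(matched_pose.structure, "m")
        be = binding_energy(matched_pose.structure)
        assert rec.dg_bind == pytest.approx(be.dg_bind)
        assert rec.interface_score == pytest.approx(be.interface_score)
        assert rec.hbond_energy == pytest.approx(be.hbond_energy)
        assert rec.interface_area >= 0.0
        assert rec.class_label == "45_45"
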