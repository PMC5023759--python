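"""Geometry and ground-truth contracts of the synthetic-structure generator."""

import numpy as np
import pytest

import dimerscan as ds
from dimerscan.scoring import binding_energy
from dimerscan.structure import select
from dimerscan.synthetic import BundleTemplate, TemplateError


def helix_ca(structure, label):
    idx = select(structure, f"A:{label}:CA")
    order = np.argsort(structure.atoms.res_id[idx])
    return structure.coord[idx][order]


class TestIdealHelixGeometry:
    def test_consecutive_ca_distances(self, monomer):
        for k in range(1, 8):
            ca = helix_ca(monomer, f"TM{k}")
            d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
            assert np.all(np.abs(d - 3.80) <= 0.05)

    def test_axial_rise_per_residue(self, monomer):
        for k in range(1, 8):
            ca = helix_ca(monomer, f"TM{k}")
            center = ca.mean(axis=0)
            _, _, vt = np.linalg.svd(ca - center)
            axis = vt[0]
            proj = (ca - center) @ axis
            rises = np.abs(np.diff(proj))
            assert np.all(np.abs(rises - 1.50) <= 0.05)

    def test_alpha_helix_i_i3_signature(self, monomer):
        for k in range(1, 8):
            ca = helix_ca(monomer, f"TM{k}")
            d3 = np.linalg.norm(ca[3:] - ca[:-3], axis=1)
            assert np.all((d3 >= 4.9) & (d3 <= 5.4))

    def test_helices_alternate_direction_along_z(self, monomer):
        signs = []
        for k in range(1, 8):
            ca = helix_ca(monomer, f"TM{k}")
            signs.append(np.sign(ca[-1, 2] - ca[0, 2]))
        assert all(a * b < 0 for a, b in zip(signs, signs[1:]))

    def test_zero_length_helix_rejected(self):
        lengths = [26] * 7
        lengths[2] = 0
        with pytest.raises(TemplateError):
            ds.build_ideal_tm_bundle(BundleTemplate(helix_lengths=tuple(lengths)))

    def test_overlapping_helix_axes_rejected(self):
        pos = BundleTemplate().helix_axis_positions.copy()
        pos[1] = pos[0] + 0.5
        with pytest.raises(TemplateError):
            BundleTemplate(helix_axis_positions=pos)

    def test_ionic_lock_planted_at_requested_gap(self):
        mono = ds.build_ideal_tm_bundle(BundleTemplate(lock_gap=3.5))
        n_idx = select(mono, "A:3.50:NH1,NH2,NE")
        o_idx = select(mono, "A:6.30:OE1,OE2")
        d = np.linalg.norm(mono.coord[n_idx][:, None] - mono.coord[o_idx][None],
                           axis=2)
        assert d.min() == pytest.approx(3.5, abs=1e-5)

    def test_pocket_residues_face_central_axis(self, monomer):
        for gen in ("3.32", "6.48", "6.55"):
            res = monomer.numbering.resolve(gen)
            mask = monomer.atoms.res_id == res
            ca = monomer.coord[mask & (monomer.atoms.atom_name == "CA")][0]
            cb = monomer.coord[mask & (monomer.atoms.atom_name == "CB")][0]
            # CB points inward: closer to the bundle axis than CA in xy
            assert np.linalg.norm(cb[:2]) < np.linalg.norm(ca[:2])


class TestInterfacePatch:
    def test_zero_counts_is_identity(self, monomer):
        patch = ds.PatchSpec(donor_count=0, acceptor_count=0, guard_count=0)
        out = ds.plant_interface_patch(monomer, patch)
        assert len(out) == len(monomer)
        assert np.array_equal(out.coord, monomer.coord)
        assert list(out.atoms.atom_name) == list(monomer.atoms.atom_name)

    def test_unknown_helix_rejected(self, monomer):
        with pytest.raises(ValueError):
            ds.PatchSpec(helix_pair=("TM9", "TM5"))

    def test_existing_atoms_unchanged(self, monomer, decorated):
        n = len(monomer)
        assert np.allclose(decorated.coord[:n], monomer.coord)
        assert list(decorated.atoms.atom_name[:n]) == list(monomer.atoms.atom_name)

    def test_decorated_face_pose_beats_undecorated_face_pose(self, decorated):
        poses = ds.enumerate_dimer_poses(decorated, steps_a=12, steps_b=12)
        by_grid = {p.grid_index: p for p in poses}
        matched = by_grid[(6, 0)]     # decorated TM4/TM5 faces meet
        other = by_grid[(0, 6)]       # opposite faces (TM1 side) meet
        e_matched = binding_energy(matched.structure).dg_bind
        e_other = binding_energy(other.structure).dg_bind
        assert e_matched < e_other

    def test_binding_energy_monotone_in_charge_magnitude(self, monomer):
        energies = []
        for q in (0.25, 0.5, 1.0, 2.0):
            dec = ds.plant_interface_patch(monomer, ds.PatchSpec(charge_magnitude=q))
            pose = ds.enumerate_dimer_poses(dec, steps_a=2, steps_b=2)[2]
            energies.append(binding_energy(pose.structure).dg_bind)
        assert all(b <= a + 1e-9 for a, b in zip(energies, energies[1:]))


class TestSyntheticTrajectory:
    def test_single_noiseless_frame_is_identity(self, monomer):
        traj = ds.simulate_trajectory(monomer, ds.TrajectorySpec(1, 0.0, (), 0))
        assert traj.n_frames == 1
        assert np.array_equal(traj.frames[0], monomer.coord)

    def test_same_seed_bit_identical(self, monomer):
        spec = ds.TrajectorySpec(20, 0.3, (), 42)
        t1 = ds.simulate_trajectory(monomer, spec)
        t2 = ds.simulate_trajectory(monomer, spec)
        assert np.array_equal(t1.frames, t2.frames)

    def test_planted_event_steps_distance_series(self, monomer):
        # displace the 6.30 carboxylate 6 A directly away from the 3.50
        # guanidinium: the min-distance series must step up by ~6 A
        arg = monomer.coord[select(monomer, "A:3.50:NH1,NH2,NE")].mean(axis=0)
        glu = monomer.coord[select(monomer, "A:6.30:OE1,OE2")].mean(axis=0)
        away = (glu - arg) / np.linalg.norm(glu - arg) * 6.0
        ev = ds.TrajectoryEvent(50, "A:6.30:OE1,OE2", tuple(away))
        spec = ds.TrajectorySpec(100, 0.0, (ev,), 0)
        traj = ds.simulate_trajectory(monomer, spec)
        series = ds.distance_series(traj, "A:3.50:NH1,NH2,NE", "A:6.30:OE1,OE2")
        before = series.values[:50]
        after = series.values[50:]
        assert np.allclose(before, before[0])
        assert after[0] - before[0] == pytest.approx(6.0, abs=0.5)
        assert np.allclose(after, after[0])

    def test_unknown_event_group_errors(self, monomer):
        ev = ds.TrajectoryEvent(0, "A:9.99:CA", (1.0, 0.0, 0.0))
        with pytest.raises(Exception):
            ds.simulate_trajectory(monomer, ds.TrajectorySpec(2, 0.0, (ev,), 0))

    def test_event_frame_outside_range_rejected(self):
        ev = ds.TrajectoryEvent(5, "A:CA", (1.0, 0.0, 0.0))
        with pytest.raises(ValueError):
            ds.TrajectorySpec(3, 0.0, (ev,), 0)

    def test_rmsd_grows_with_jitter(self, monomer):
        from dimerscan.geometry import kabsch
        means = []
        for sd in (0.1, 0.4, 0.8):
            traj = ds.simulate_trajectory(monomer, ds.TrajectorySpec(10, sd, (), 7))
            vals = [kabsch(traj.frames[f], traj.frames[0])[2]
                    for f in range(1, traj.n_frames)]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]
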