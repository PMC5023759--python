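"""Trajectory diagnostics: distances, ionic lock, H-bond occupancy, RMSD."""

import numpy as np
import pytest

import dimerscan as ds
from dimerscan.structure import SelectionError, Trajectory
from dimerscan.trajectory import (
    distance_series,
    hbond_persistence,
    ionic_lock_series,
    rmsd_series,
    water_bridges,
)
from tests.test_scoring import toy_structure


@pytest.fixture(scope="module")
def locked_traj(monomer):
    return ds.simulate_trajectory(
        monomer, ds.TrajectorySpec(n_frames=200, jitter_sd=0.2, seed=17))


def lock_break_traj(monomer, break_frame, n_frames=200, jitter=0.2, seed=23):
    ev = ds.TrajectoryEvent(break_frame, "A:6.30:OE1,OE2,CD,CB", (8.0, 0.0, 0.0))
    return ds.simulate_trajectory(
        monomer, ds.TrajectorySpec(n_frames, jitter, (ev,), seed))


class TestDistanceSeries:
    def test_static_trajectory_constant(self, monomer):
        traj = ds.simulate_trajectory(monomer, ds.TrajectorySpec(10, 0.0, (), 0))
        series = distance_series(traj, "A:3.50:NH1", "A:6.30:OE1")
        assert np.allclose(series.values, series.values[0])

    def test_same_selection_min_is_zero(self, monomer):
        traj = ds.simulate_trajectory(monomer, ds.TrajectorySpec(3, 0.0, (), 0))
        series = distance_series(traj, "A:TM1:CA", "A:TM1:CA", reduction="min")
        assert np.allclose(series.values, 0.0)

    def test_centroid_reduction(self, monomer):
        traj = ds.simulate_trajectory(monomer, ds.TrajectorySpec(2, 0.0, (), 0))
        series = distance_series(traj, "A:TM1:CA", "A:TM2:CA", reduction="centroid")
        i1 = ds.select(monomer, "A:TM1:CA")
        i2 = ds.select(monomer, "A:TM2:CA")
        expected = np.linalg.norm(monomer.coord[i1].mean(0) - monomer.coord[i2].mean(0))
        assert series.values[0] == pytest.approx(expected, abs=1e-6)

    def test_empty_selection_errors(self, monomer):
        traj = ds.simulate_trajectory(monomer, ds.TrajectorySpec(2, 0.0, (), 0))
        with pytest.raises(SelectionError):
            distance_series(traj, "A:9.99", "A:TM1")


class TestIonicLock:
    def test_locked_trajectory_fraction_near_one(self, locked_traj):
        series = ionic_lock_series(locked_traj, "A")
        # planted gap 3.5 A, jitter 0.2 A: < 4.5 A in essentially all frames
        assert series.fraction_below >= 0.99

    def test_lock_break_fraction_matches_event_frame(self, monomer):
        k, n = 120, 200
        series = ionic_lock_series(lock_break_traj(monomer, k, n), "A")
        assert series.fraction_below == pytest.approx(k / n, abs=0.02)

    def test_break_detected_at_planted_frame(self, monomer):
        k = 77
        series = ionic_lock_series(lock_break_traj(monomer, k), "A")
        above = np.flatnonzero(series.values >= 4.5)
        assert abs(int(above.min()) - k) <= 1

    def test_chain_without_lock_annotation_errors(self, monomer):
        from dimerscan.structure import Structure
        bare = Structure(monomer.atoms.copy(), dict(monomer.segments))
        traj = ds.simulate_trajectory(bare, ds.TrajectorySpec(2, 0.0, (), 0))
        with pytest.raises(SelectionError):
            ionic_lock_series(traj, "A")


class TestHbondPersistence:
    def hbond_traj(self, p_present, n_frames, seed=5):
        topo = toy_structure([
            ("A", 1, "GLY", "C", "C", (-1.2, 0.0, 0.0)),
            ("A", 1, "GLY", "N", "N", (0.0, 0.0, 0.0)),
            ("B", 2, "GLY", "O", "O", (2.9, 0.0, 0.0)),
        ])
        rng = np.random.default_rng(seed)
        present = rng.random(n_frames) < p_present
        frames = np.repeat(topo.coord[None], n_frames, axis=0)
        frames[~present, 2, 0] += 5.0  # push the acceptor out of range
        return Trajectory(topo, frames), present

    def test_always_bonded_occupancy_one(self):
        traj, _ = self.hbond_traj(1.1, 20)
        rep = hbond_persistence(traj, "A:N", "B:O")
        assert rep.occupancy == 1.0

    def test_never_bonded_occupancy_zero(self):
        traj, _ = self.hbond_traj(-0.1, 20)
        rep = hbond_persistence(traj, "A:N", "B:O")
        assert rep.occupancy == 0.0

    def test_planted_occupancy_within_binomial_bound(self):
        p, n = 0.6, 500
        traj, present = self.hbond_traj(p, n)
        rep = hbond_persistence(traj, "A:N", "B:O")
        assert np.array_equal(rep.present, present)
        assert abs(rep.occupancy - p) <= 3.0 * np.sqrt(p * (1 - p) / n)

    def test_occupancy_converges_with_frames(self):
        p = 0.3
        errs = []
        for n in (50, 2000):
            traj, _ = self.hbond_traj(p, n, seed=9)
            errs.append(abs(hbond_persistence(traj, "A:N", "B:O").occupancy - p))
        assert errs[1] < errs[0]


class TestWaterBridges:
    def bridge_topology(self, water_xyz):
        return toy_structure([
            ("A", 1, "GLY", "CA", "C", (0.0, 0.0, 0.0)),
            ("B", 2, "GLY", "CA", "C", (5.0, 0.0, 0.0)),
            ("W", 3, "HOH", "O", "O", water_xyz),
        ])

    def test_no_waters_gives_zeros(self, monomer):
        traj = ds.simulate_trajectory(monomer, ds.TrajectorySpec(3, 0.0, (), 0))
        counts = water_bridges(traj, "A:TM1", "A:TM2")
        assert np.array_equal(counts, np.zeros(3, dtype=int))

    def test_midway_water_bridges(self):
        topo = self.bridge_topology((2.5, 0.0, 0.0))
        traj = Trajectory(topo, topo.coord[None])
        assert water_bridges(traj, "A:CA", "B:CA", d_max=3.5).tolist() == [1]

    def test_distant_water_does_not_bridge(self):
        topo = self.bridge_topology((2.5, 10.0, 0.0))
        traj = Trajectory(topo, topo.coord[None])
        assert water_bridges(traj, "A:CA", "B:CA", d_max=3.5).tolist() == [0]


class TestRmsdSeries:
    def test_reference_frame_rmsd_zero(self, locked_traj):
        series, _ = rmsd_series(locked_traj, 0)
        assert series.values[0] == pytest.approx(0.0, abs=1e-9)

    def test_jittered_trajectory_is_stable(self, monomer):
        traj = ds.simulate_trajectory(monomer, ds.TrajectorySpec(200, 0.3, (), 3))
        series, stable = rmsd_series(traj, 0)
        assert stable
        assert series.max <= 4.0

    def test_large_event_breaks_stability(self, monomer):
        half = f"A:1-{int(np.median(monomer.atoms.res_id))}"
        ev = ds.TrajectoryEvent(10, half, (12.0, 0.0, 0.0))
        traj = ds.simulate_trajectory(monomer, ds.TrajectorySpec(20, 0.1, (ev,), 1))
        series, stable = rmsd_series(traj, 0)
        assert not stable
        assert series.values[10:].min() > 4.0

    def test_series_invariant_under_global_motion_of_frames(self, monomer):
        traj = ds.simulate_trajectory(monomer, ds.TrajectorySpec(5, 0.2, (), 2))
        series1, _ = rmsd_series(traj, 0)
        from dimerscan.structure import rotation_about_z
        rot = rotation_about_z(35.0)
        moved = Trajectory(traj.topology,
                           traj.frames @ rot.T + np.array([1.0, -2.0, 3.0]))
        series2, _ = rmsd_series(moved, 0)
        assert np.allclose(series1.values, series2.values, atol=1e-9)
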