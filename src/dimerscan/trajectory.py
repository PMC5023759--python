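"""Inactive-state diagnostics over trajectories.

The analyses mirror what one inspects after a membrane-protein
simulation: the ionic-lock distance between Arg 3.50 and Glu 6.30 (the
inactive-state salt bridge of the conserved (D/E)RY motif), persistence
of specific intersubunit hydrogen bonds, water-mediated bridges across
the dimer interface, and superposed-RMSD stability against a reference
frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from . import forcefield as ff
from .geometry import kabsch
from .structure import SelectionError, Trajectory, select


@dataclass
class DistanceSeries:
    values: np.ndarray          # per-frame distance, Å
    selection1: str
    selection2: str
    reduction: str
    threshold: float | None = None

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def min(self) -> float:
        return float(self.values.min())

    @property
    def max(self) -> float:
        return float(self.values.max())

    @property
    def fraction_below(self) -> float | None:
        if self.threshold is None:
            return None
        return float((self.values < self.threshold).mean())


@dataclass
class OccupancyReport:
    pair_name: str
    present: np.ndarray         # per-frame booleans

    @property
    def occupancy(self) -> float:
        return float(self.present.mean())


def _resolve(traj: Trajectory, selector: str) -> np.ndarray:
    idx = select(traj.topology, selector)
    if idx.size == 0:
        raise SelectionError(f"selection {selector!r} matches no atoms")
    return idx


def distance_series(traj: Trajectory, sel1: str, sel2: str,
                    reduction: str = "min",
                    threshold: float | None = None) -> DistanceSeries:
    """Per-frame distance between two atom sets (min pair or centroid)."""
    i1 = _resolve(traj, sel1)
    i2 = _resolve(traj, sel2)
    if reduction not in ("min", "centroid"):
        raise ValueError(f"unknown reduction {reduction!r}")
    vals = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        a = traj.frames[f, i1]
        b = traj.frames[f, i2]
        if reduction == "centroid":
            vals[f] = np.linalg.norm(a.mean(axis=0) - b.mean(axis=0))
        else:
            d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
            vals[f] = d.min()
    return DistanceSeries(vals, sel1, sel2, reduction, threshold)


def ionic_lock_series(traj: Trajectory, chain: str = "A",
                      threshold: float = 4.5) -> DistanceSeries:
    """Arg 3.50 guanidinium – Glu 6.30 carboxylate minimum distance.

    ``fraction_below`` the 4.5 Å salt-bridge threshold reports how often
    the lock is formed (1.0 = fully inactive-state-like).
    """
    topo = traj.topology
    if topo.numbering is None:
        raise SelectionError("trajectory topology carries no generic numbering")
    sel1 = f"{chain}:3.50:NH1,NH2,NE"
    sel2 = f"{chain}:6.30:OE1,OE2"
    for sel, gen in ((sel1, "3.50"), (sel2, "6.30")):
        try:
            idx = select(topo, sel)
        except SelectionError as exc:
            raise SelectionError(f"cannot resolve {gen} on chain {chain}: {exc}") from exc
        if idx.size == 0:
            res = topo.numbering.resolve(gen)
            raise SelectionError(
                f"residue {res} ({gen}) lacks side-chain atoms for the ionic lock")
    return distance_series(traj, sel1, sel2, reduction="min", threshold=threshold)


def hbond_persistence(traj: Trajectory, donor_sel: str, acceptor_sel: str,
                      d_max: float = 3.5, theta_min: float = 120.0
                      ) -> OccupancyReport:
    """Fraction of frames in which any selected donor–acceptor pair bonds.

    Uses the same heavy-atom geometric criteria as dimer scoring:
    donor–acceptor distance ≤ ``d_max`` and antecedent–donor–acceptor
    angle ≥ ``theta_min``.
    """
    di = _resolve(traj, donor_sel)
    ai = _resolve(traj, acceptor_sel)
    topo = traj.topology
    config = ff.EnergyConfig(hbond_d_max=d_max, hbond_theta_min=theta_min)
    params = ff.type_atoms(topo.atoms, config)
    ant = params.antecedent[di]
    usable = ant >= 0
    if not usable.any():
        raise SelectionError("no donor in selection has an antecedent atom")
    di, ant = di[usable], ant[usable]
    present = np.zeros(traj.n_frames, dtype=bool)
    for f in range(traj.n_frames):
        co = traj.frames[f]
        dpos, apos, antpos = co[di], co[ai], co[ant]
        diff = apos[None, :, :] - dpos[:, None, :]
        dist = np.linalg.norm(diff, axis=2)
        v1 = antpos - co[di]
        v1n = v1 / np.maximum(np.linalg.norm(v1, axis=1, keepdims=True), 1e-12)
        cosang = (v1n[:, None, :] * diff).sum(axis=2) / np.maximum(dist, 1e-12)
        theta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        present[f] = bool(((dist <= d_max) & (theta >= theta_min)).any())
    return OccupancyReport(f"{donor_sel}..{acceptor_sel}", present)


def water_bridges(traj: Trajectory, sel1: str, sel2: str,
                  d_max: float = 3.5) -> np.ndarray:
    """Per-frame count of waters bridging two atom sets.

    A water counts if its oxygen lies within ``d_max`` of at least one
    atom of each set.  Topologies without waters give an all-zero series.
    """
    topo = traj.topology
    res_name = topo.atoms.res_name
    wmask = np.isin(res_name, ("HOH", "WAT")) & \
        np.isin(topo.atoms.element, ("O",))
    widx = np.flatnonzero(wmask)
    counts = np.zeros(traj.n_frames, dtype=int)
    if widx.size == 0:
        return counts
    i1 = _resolve(traj, sel1)
    i2 = _resolve(traj, sel2)
    for f in range(traj.n_frames):
        co = traj.frames[f]
        w = co[widx]
        d1 = cKDTree(co[i1]).query(w, k=1)[0]
        d2 = cKDTree(co[i2]).query(w, k=1)[0]
        counts[f] = int(((d1 <= d_max) & (d2 <= d_max)).sum())
    return counts


def rmsd_series(traj: Trajectory, reference_frame: int = 0,
                selection: str | None = None,
                stability_threshold: float = 4.0
                ) -> tuple[DistanceSeries, bool]:
    """Kabsch-superposed RMSD of every frame to a reference frame.

    Returns the series and a stability verdict (True iff the maximum RMSD
    stays at or below ``stability_threshold``).
    """
    idx = _resolve(traj, selection) if selection is not None \
        else np.arange(traj.frames.shape[1])
    ref = traj.frames[reference_frame, idx]
    vals = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        _, _, vals[f] = kabsch(traj.frames[f, idx], ref)
    series = DistanceSeries(vals, selection or "*", f"frame {reference_frame}",
                            "rmsd", stability_threshold)
    stable = bool(vals.max() <= stability_threshold)
    return series, stable
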