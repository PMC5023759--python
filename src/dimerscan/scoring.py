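"""Per-dimer scoring: four interface parameters plus interface class.

For every dimer the pipeline records

* ``interface_score`` — cross-protomer Lennard-Jones + Coulomb energy,
* ``interface_area`` — SASA buried on complexation,
  ``SASA(A) + SASA(B) − SASA(AB)``,
* ``dg_bind`` — binding free-energy surrogate ``E(AB) − E(A) − E(B)``
  (for rigid protomers: all cross terms including H-bonds),
* ``hbond_energy`` — the cross-protomer hydrogen-bond component,

together with an interface class label ``pq_rs`` naming the dominant
adjacent-TM pair of each protomer (28 possible labels, e.g. ``45_71`` for
TM4–TM5 against TM7–TM1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import forcefield as ff
from .sasa import DEFAULT_RADII, shrake_rupley, shrake_rupley_subset
from .structure import Structure, TM_LABELS

#: the seven sequentially adjacent TM pairs, in tie-break priority order
ADJACENT_PAIRS: tuple[str, ...] = ("12", "23", "34", "45", "56", "67", "71")

#: planted decoration pseudo-atom names (synthetic ground-truth machinery)
PSEUDO_SITE_NAMES = ("PD1", "PA1", "PG1")


def interface_classes() -> list[str]:
    """All canonical ``pq_rs`` labels (28: 7 symmetric + 21 mixed)."""
    labels = []
    for i, a in enumerate(ADJACENT_PAIRS):
        for b in ADJACENT_PAIRS[i:]:
            labels.append(f"{min(a, b)}_{max(a, b)}")
    return sorted(labels)


def canonical_label(pair_a: str, pair_b: str) -> str:
    return f"{min(pair_a, pair_b)}_{max(pair_a, pair_b)}"


@dataclass
class HBond:
    donor_index: int
    acceptor_index: int
    donor_chain: str
    distance: float
    angle: float
    energy: float


@dataclass
class BindingEnergy:
    dg_bind: float
    interface_score: float
    hbond_energy: float
    clash: bool


@dataclass
class ScoreRecord:
    """One dimer's four raw scoring parameters and its class label."""

    pose_id: str
    class_label: str
    interface_score: float
    interface_area: float
    dg_bind: float
    hbond_energy: float
    normalized: dict[str, float] = field(default_factory=dict)


PARAMETERS = ("interface_score", "interface_area", "dg_bind", "hbond_energy")


def _split_chains(dimer: Structure) -> tuple[np.ndarray, np.ndarray]:
    chains = dimer.chains
    if len(chains) != 2:
        raise ValueError(f"dimer must have exactly two chains, got {chains}")
    a_mask = dimer.atoms.chain_id == chains[0]
    return np.flatnonzero(a_mask), np.flatnonzero(~a_mask)


def interface_area(dimer: Structure, probe_radius: float = 1.4,
                   n_points: int = 92) -> float:
    """Buried SASA of a two-chain dimer (Å², clamped at 0)."""
    ia, ib = _split_chains(dimer)
    el = dimer.atoms.element
    co = dimer.coord
    total_ab = shrake_rupley(co, el, probe_radius, n_points).sum()
    total_a = shrake_rupley(co[ia], el[ia], probe_radius, n_points).sum()
    total_b = shrake_rupley(co[ib], el[ib], probe_radius, n_points).sum()
    return max(total_a + total_b - total_ab, 0.0)


def per_atom_burial(dimer: Structure, probe_radius: float = 1.4,
                    n_points: int = 92) -> np.ndarray:
    """Per-atom SASA loss on complexation.

    Only atoms whose inflated sphere can touch an inflated sphere of the
    other chain change their SASA, so the isolated and complexed surfaces
    are evaluated for that interface shell only; everywhere else the
    burial is exactly zero.
    """
    ia, ib = _split_chains(dimer)
    el = dimer.atoms.element
    co = dimer.coord
    reach = 2.0 * (max(DEFAULT_RADII.values()) + probe_radius)
    ta, tb = cKDTree(co[ia]), cKDTree(co[ib])
    near_b = tb.query(co[ia], k=1, distance_upper_bound=reach)[0] <= reach
    near_a = ta.query(co[ib], k=1, distance_upper_bound=reach)[0] <= reach
    shell = np.concatenate([ia[near_b], ib[near_a]])
    burial = np.zeros(len(co))
    if shell.size == 0:
        return burial
    chain_of = dimer.atoms.chain_id
    alone = np.empty(len(shell))
    for chain in dimer.chains:
        own = shell[chain_of[shell] == chain]
        if own.size:
            vals = shrake_rupley_subset(co, el, own,
                                        occluder_mask=chain_of == chain,
                                        probe_radius=probe_radius,
                                        n_points=n_points)
            alone[np.isin(shell, own)] = vals
    complexed = shrake_rupley_subset(co, el, shell, occluder_mask=None,
                                     probe_radius=probe_radius,
                                     n_points=n_points)
    burial[shell] = alone - complexed
    return burial


def interface_residues(dimer: Structure, burial_threshold: float = 0.1,
                       probe_radius: float = 1.4, n_points: int = 92,
                       burial: np.ndarray | None = None
                       ) -> dict[str, list[int]]:
    """Residues whose summed atomic SASA loss exceeds the threshold, per chain."""
    if burial is None:
        burial = per_atom_burial(dimer, probe_radius, n_points)
    atoms = dimer.atoms
    out: dict[str, list[int]] = {c: [] for c in dimer.chains}
    for chain in out:
        mask = atoms.chain_id == chain
        res_ids = atoms.res_id[mask]
        vals = burial[mask]
        for rid in np.unique(res_ids):
            if vals[res_ids == rid].sum() > burial_threshold:
                out[chain].append(int(rid))
        out[chain].sort()
    return out


def detect_hbonds(dimer: Structure,
                  config: ff.EnergyConfig = ff.DEFAULT_CONFIG,
                  params: tuple[ff.AtomParams, ff.AtomParams] | None = None
                  ) -> list[HBond]:
    """Cross-protomer hydrogen bonds under the heavy-atom geometric criteria."""
    ia, ib = _split_chains(dimer)
    if params is not None:
        pa, pb = params
    else:
        pa = ff.type_atoms(dimer.atoms[ia], config)
        pb = ff.type_atoms(dimer.atoms[ib], config)
    co = dimer.coord
    chains = dimer.chains
    raw = ff.hbond_pairs(co[ia], pa, co[ib], pb, config)
    out = []
    for di, ai, donor_side, dist, angle, energy in raw:
        if donor_side == 0:
            out.append(HBond(int(ia[di]), int(ib[ai]), chains[0], dist, angle, energy))
        else:
            out.append(HBond(int(ib[di]), int(ia[ai]), chains[1], dist, angle, energy))
    return out


def binding_energy(dimer: Structure,
                   config: ff.EnergyConfig = ff.DEFAULT_CONFIG,
                   params: tuple[ff.AtomParams, ff.AtomParams] | None = None
                   ) -> BindingEnergy:
    """Surrogate binding energy decomposition of a rigid two-chain dimer.

    Because the protomers are rigid, intra-chain pair terms cancel in
    ``E(AB) − E(A) − E(B)`` and the binding energy equals the sum of all
    cross-protomer terms; ``interface_score`` is the LJ+Coulomb part and
    ``hbond_energy`` the hydrogen-bond part.
    """
    ia, ib = _split_chains(dimer)
    if params is not None:
        pa, pb = params
    else:
        pa = ff.type_atoms(dimer.atoms[ia], config)
        pb = ff.type_atoms(dimer.atoms[ib], config)
    co = dimer.coord
    ce = ff.cross_energy(co[ia], pa, co[ib], pb, config)
    return BindingEnergy(dg_bind=ce.total, interface_score=ce.lj + ce.coulomb,
                         hbond_energy=ce.hbond, clash=ce.clash)


def _dominant_pair(buried_per_tm: dict[str, float]) -> str | None:
    best, best_val = None, 0.0
    for pair in ADJACENT_PAIRS:  # priority order breaks ties toward lower TM
        a, b = f"TM{pair[0]}", f"TM{pair[1]}"
        val = buried_per_tm.get(a, 0.0) + buried_per_tm.get(b, 0.0)
        if val > best_val + 1e-12:
            best, best_val = pair, val
    return best


def _wrap_angle(a: float) -> float:
    return (a + np.pi) % (2.0 * np.pi) - np.pi


def _pair_label(i: int, j: int) -> str | None:
    lo, hi = sorted((i, j))
    label = f"{lo}{hi}"
    if label in ADJACENT_PAIRS:
        return label
    return "71" if {i, j} == {1, 7} else None


def _chain_burial_profile(dimer: Structure, chain: str, burial: np.ndarray):
    atoms = dimer.atoms
    mask = atoms.chain_id == chain
    per_tm: dict[str, float] = {}
    tm_center: dict[str, np.ndarray] = {}
    tm_centroid: dict[str, np.ndarray] = {}
    for tm in TM_LABELS:
        if tm not in dimer.segments:
            continue
        lo, hi = dimer.segments[tm]
        sel = mask & (atoms.res_id >= lo) & (atoms.res_id <= hi)
        w = np.clip(burial[sel], 0.0, None)
        per_tm[tm] = float(w.sum())
        tm_center[tm] = dimer.coord[sel].mean(axis=0)
        if w.sum() > 0:
            tm_centroid[tm] = (dimer.coord[sel] * w[:, None]).sum(axis=0) / w.sum()
    origin = dimer.coord[mask].mean(axis=0)
    return per_tm, tm_center, tm_centroid, origin


def _chain_pair(profile, partner_dominant: str | None) -> str | None:
    """Dominant adjacent-TM pair of one protomer.

    The pair with the largest summed buried area wins.  When the burial is
    confined to a single helix, the two pairs containing it tie with no
    area information; the tie is resolved, in order, by

    1. cross-chain consistency — the candidate pair that also covers the
       partner protomer's dominant contact helix (the labels describe one
       interface, so a TM4-against-TM5 contact reads 45 on both sides);
    2. the azimuthal lean of the buried surface: the neighbor helix on the
       side of the burial-weighted centroid completes the pair;
    3. the lower TM index.
    """
    per_tm, tm_center, tm_centroid, origin = profile
    best = _dominant_pair(per_tm)
    if best is None:
        return None
    a, b = f"TM{best[0]}", f"TM{best[1]}"
    solo = None
    if per_tm.get(a, 0.0) > 0 and per_tm.get(b, 0.0) == 0:
        solo = a
    elif per_tm.get(b, 0.0) > 0 and per_tm.get(a, 0.0) == 0:
        solo = b
    if solo is None:
        return best
    k = int(solo[2])
    prev_k, next_k = (k - 2) % 7 + 1, k % 7 + 1
    if partner_dominant is not None:
        pk = int(partner_dominant[2])
        covers_prev = pk in (k, prev_k)
        covers_next = pk in (k, next_k)
        if pk != k and covers_prev != covers_next:
            return _pair_label(k, prev_k if covers_prev else next_k) or best
    prev_tm, next_tm = f"TM{prev_k}", f"TM{next_k}"
    if solo not in tm_centroid or prev_tm not in tm_center or next_tm not in tm_center:
        return best
    az = {key: np.arctan2(*(tm_center[key] - origin)[[1, 0]])
          for key in (solo, prev_tm, next_tm)}
    az_c = np.arctan2(*(tm_centroid[solo] - origin)[[1, 0]])
    lean = _wrap_angle(az_c - az[solo])
    toward_next = _wrap_angle(az[next_tm] - az[solo])
    if abs(lean) < 1e-9:
        return best
    partner = next_k if np.sign(lean) == np.sign(toward_next) else prev_k
    return _pair_label(k, partner) or best


def classify_interface(dimer: Structure, probe_radius: float = 1.4,
                       n_points: int = 92,
                       burial: np.ndarray | None = None) -> str:
    """Dominant adjacent-TM-pair class of a dimer, e.g. ``\"45_71\"``.

    Per protomer the adjacent helix pair with the largest summed buried
    area wins (single-helix contacts are attributed by the azimuthal lean
    of the buried surface, see :func:`_chain_pair`); the two pair labels
    are ordered canonically.  Poses with no buried helix area at all are
    labeled ``"none"``.
    """
    if burial is None:
        burial = per_atom_burial(dimer, probe_radius, n_points)
    profiles = [_chain_burial_profile(dimer, chain, burial)
                for chain in dimer.chains]
    dominant = []
    for per_tm, _, _, _ in profiles:
        buried = {tm: v for tm, v in per_tm.items() if v > 0}
        dominant.append(max(buried, key=buried.get) if buried else None)
    pairs = [_chain_pair(profiles[0], dominant[1]),
             _chain_pair(profiles[1], dominant[0])]
    if pairs[0] is None or pairs[1] is None:
        return "none"
    return canonical_label(pairs[0], pairs[1])


def min_cross_distance(dimer: Structure) -> float:
    ia, ib = _split_chains(dimer)
    co = dimer.coord
    d, _ = cKDTree(co[ia]).query(co[ib], k=1)
    return float(d.min())


def score_dimer(dimer: Structure, pose_id: str = "pose",
                config: ff.EnergyConfig = ff.DEFAULT_CONFIG,
                probe_radius: float = 1.4, n_points: int = 92,
                params: tuple[ff.AtomParams, ff.AtomParams] | None = None
                ) -> ScoreRecord:
    """All four scoring parameters plus the interface class for one dimer."""
    burial = per_atom_burial(dimer, probe_radius, n_points)
    area = max(float(burial.sum()), 0.0)
    be = binding_energy(dimer, config, params=params)
    label = classify_interface(dimer, burial=burial)
    return ScoreRecord(pose_id=pose_id, class_label=label,
                       interface_score=be.interface_score, interface_area=area,
                       dg_bind=be.dg_bind, hbond_energy=be.hbond_energy)
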