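"""Coarse pair potential and hydrogen-bond model for dimer scoring.

The surrogate interaction energy is a 6-12 Lennard-Jones term plus a
screened Coulomb term with distance-dependent dielectric ε(r) = 4r and a
directional hydrogen-bond term between typed heavy-atom donors and
acceptors (the synthetic structures carry no hydrogens).  Partial charges
are deliberately coarse: ±0.5 per carboxylate oxygen, +0.33 per
guanidinium nitrogen, ±0.2 on backbone N/O; planted interaction sites
carry the charge stored in their B-factor.  Units are kcal/mol-like
"energy units" — the pipeline only ever compares and ranks them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

ROLE_NONE, ROLE_DONOR, ROLE_ACCEPTOR, ROLE_BOTH = 0, 1, 2, 3

_CARBOXYLATE_O = {"OD1", "OD2", "OE1", "OE2"}
_GUANIDINIUM_N = {"NE", "NH1", "NH2"}
_HYDROXYL_O = {"OG", "OG1", "OH"}
_WATER_RES = {"HOH", "WAT"}


@dataclass
class EnergyConfig:
    lj_radius: dict[str, float] = field(
        default_factory=lambda: {"C": 1.9, "N": 1.7, "O": 1.6, "S": 1.8})
    lj_eps: dict[str, float] = field(
        default_factory=lambda: {"C": 0.10, "N": 0.12, "O": 0.15, "S": 0.15})
    coulomb_k: float = 332.0
    dielectric_slope: float = 4.0  # eps(r) = slope * r
    cutoff: float = 10.0
    clash_dist: float = 0.5
    clash_cap: float = 1000.0
    backbone_charge: float = 0.2
    carboxylate_charge: float = -0.5
    guanidinium_charge: float = 0.33
    hydroxyl_charge: float = -0.2
    hbond_eps: float = 2.0     # well depth of an ideal H-bond
    hbond_d_opt: float = 2.9   # donor–acceptor optimum, Å
    hbond_d_max: float = 3.5   # geometric cutoff, Å
    hbond_theta_min: float = 120.0  # minimum antecedent–donor–acceptor angle


DEFAULT_CONFIG = EnergyConfig()


@dataclass
class AtomParams:
    """Per-atom typing of one chain/protomer, aligned with its coordinates."""

    radius: np.ndarray
    eps: np.ndarray
    charge: np.ndarray
    role: np.ndarray        # ROLE_* flags
    antecedent: np.ndarray  # index of the bonded-neighbor proxy, -1 if none


def type_atoms(atoms, config: EnergyConfig = DEFAULT_CONFIG) -> AtomParams:
    """Assign LJ parameters, partial charges and H-bond roles.

    ``atoms`` is a biotite ``AtomArray``.  The antecedent of each
    donor/acceptor (used for the H-bond alignment angle) is the nearest
    other atom of the same residue — a bonded-neighbor proxy that is exact
    for the generator's minimal side chains.
    """
    n = atoms.array_length()
    element = np.char.upper(np.char.strip(atoms.element.astype("U2")))
    radius = np.empty(n)
    eps = np.empty(n)
    for i, el in enumerate(element):
        if el not in config.lj_radius:
            raise KeyError(f"no LJ parameters for element {el!r}")
        radius[i] = config.lj_radius[el]
        eps[i] = config.lj_eps[el]

    name = atoms.atom_name
    res = atoms.res_name
    b = atoms.b_factor if "b_factor" in atoms.get_annotation_categories() else np.zeros(n)
    charge = np.zeros(n)
    role = np.full(n, ROLE_NONE, dtype=np.int8)
    for i in range(n):
        nm, rn = str(name[i]), str(res[i])
        if rn in _WATER_RES:
            role[i] = ROLE_BOTH
        elif nm == "N":
            charge[i] = config.backbone_charge
            role[i] = ROLE_DONOR
        elif nm == "O":
            charge[i] = -config.backbone_charge
            role[i] = ROLE_ACCEPTOR
        elif nm in _CARBOXYLATE_O:
            charge[i] = config.carboxylate_charge
            role[i] = ROLE_ACCEPTOR
        elif nm in _GUANIDINIUM_N and rn == "ARG":
            charge[i] = config.guanidinium_charge
            role[i] = ROLE_DONOR
        elif nm in _HYDROXYL_O:
            charge[i] = config.hydroxyl_charge
            role[i] = ROLE_BOTH
        elif nm == "NZ":
            charge[i] = config.guanidinium_charge
            role[i] = ROLE_DONOR
        elif nm == "PD1":  # planted donor site; charge travels in B-factor
            charge[i] = abs(float(b[i]))
            role[i] = ROLE_DONOR
        elif nm == "PA1":  # planted acceptor site
            charge[i] = -abs(float(b[i]))
            role[i] = ROLE_ACCEPTOR

    # antecedent = nearest same-residue atom, a bonded-neighbor proxy.
    # Planted pseudo-sites hang off the backbone and are not bonded to each
    # other, so they cannot serve as antecedents.
    pseudo = np.isin(name, ("PD1", "PA1", "PG1"))
    antecedent = np.full(n, -1, dtype=int)
    coords = atoms.coord
    keys = {}
    for i in range(n):
        keys.setdefault((str(atoms.chain_id[i]), int(atoms.res_id[i])), []).append(i)
    for members in keys.values():
        if len(members) < 2:
            continue
        m = np.asarray(members)
        sub = coords[m]
        d2 = ((sub[:, None, :] - sub[None, :, :]) ** 2).sum(axis=2)
        np.fill_diagonal(d2, np.inf)
        d2[:, pseudo[m]] = np.inf
        for loc, i in enumerate(m):
            if role[i] != ROLE_NONE and np.isfinite(d2[loc]).any():
                antecedent[i] = m[d2[loc].argmin()]
    return AtomParams(radius, eps, charge, role, antecedent)


def _hbond_ramp(d: np.ndarray, config: EnergyConfig) -> np.ndarray:
    ramp = np.clip((config.hbond_d_max - d) /
                   max(config.hbond_d_max - config.hbond_d_opt, 1e-9), 0.0, 1.0)
    ramp[d <= config.hbond_d_opt] = 1.0
    return ramp


def hbond_pairs(coords_a: np.ndarray, params_a: AtomParams,
                coords_b: np.ndarray, params_b: AtomParams,
                config: EnergyConfig = DEFAULT_CONFIG,
                pairs: tuple[np.ndarray, np.ndarray] | None = None):
    """Directed donor(A or B) → acceptor(other) hydrogen bonds.

    Returns arrays ``(i_donor, i_acceptor, donor_side, distance, angle_deg,
    energy)`` where ``donor_side`` is 0 if the donor belongs to set A.
    """
    if pairs is None:
        tree = cKDTree(coords_a)
        lists = tree.query_ball_point(coords_b, config.hbond_d_max)
        ia = np.concatenate([np.asarray(l, dtype=int) for l in lists]) \
            if any(lists) else np.empty(0, dtype=int)
        ib = np.concatenate([np.full(len(l), j) for j, l in enumerate(lists)]) \
            if any(lists) else np.empty(0, dtype=int)
    else:
        ia, ib = pairs
    out = []
    for donor_side in (0, 1):
        dp, da = (params_a, params_b) if donor_side == 0 else (params_b, params_a)
        dc, ac = (coords_a, coords_b) if donor_side == 0 else (coords_b, coords_a)
        di, ai = (ia, ib) if donor_side == 0 else (ib, ia)
        mask = ((dp.role[di] & ROLE_DONOR) != 0) & ((da.role[ai] & ROLE_ACCEPTOR) != 0) \
            & (dp.antecedent[di] >= 0)
        if not mask.any():
            continue
        di, ai = di[mask], ai[mask]
        dpos, apos = dc[di], ac[ai]
        dist = np.linalg.norm(apos - dpos, axis=1)
        close = dist <= config.hbond_d_max
        di, ai, dpos, apos, dist = di[close], ai[close], dpos[close], apos[close], dist[close]
        if di.size == 0:
            continue
        ant = dc[dp.antecedent[di]]
        v1 = ant - dpos
        v2 = apos - dpos
        cosang = (v1 * v2).sum(axis=1) / np.maximum(
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1), 1e-12)
        theta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        ok = theta >= config.hbond_theta_min
        if not ok.any():
            continue
        di, ai, dist, theta = di[ok], ai[ok], dist[ok], theta[ok]
        energy = -config.hbond_eps * np.cos(np.deg2rad(180.0 - theta)) ** 2 \
            * _hbond_ramp(dist, config)
        for k in range(di.size):
            out.append((int(di[k]), int(ai[k]), donor_side,
                        float(dist[k]), float(theta[k]), float(energy[k])))
    return out


@dataclass
class CrossEnergy:
    lj: float
    coulomb: float
    hbond: float
    clash: bool

    @property
    def total(self) -> float:
        return self.lj + self.coulomb + self.hbond


def cross_energy(coords_a: np.ndarray, params_a: AtomParams,
                 coords_b: np.ndarray, params_b: AtomParams,
                 config: EnergyConfig = DEFAULT_CONFIG,
                 tree_a: cKDTree | None = None) -> CrossEnergy:
    """Interaction energy between two rigid atom sets (A–B pairs only)."""
    if tree_a is None:
        tree_a = cKDTree(coords_a)
    lists = tree_a.query_ball_point(coords_b, config.cutoff)
    if not any(lists):
        return CrossEnergy(0.0, 0.0, 0.0, False)
    ia = np.concatenate([np.asarray(l, dtype=int) for l in lists if l])
    ib = np.concatenate([np.full(len(l), j) for j, l in enumerate(lists) if l])
    diff = coords_b[ib] - coords_a[ia]
    r = np.linalg.norm(diff, axis=1)
    clash = bool((r < config.clash_dist).any())
    r_eff = np.maximum(r, config.clash_dist)
    rmin = params_a.radius[ia] + params_b.radius[ib]
    epsij = np.sqrt(params_a.eps[ia] * params_b.eps[ib])
    x = (rmin / r_eff) ** 6
    lj = float(np.minimum(epsij * (x * x - 2.0 * x), config.clash_cap).sum())
    lj = min(lj, config.clash_cap)
    qq = params_a.charge[ia] * params_b.charge[ib]
    coulomb = float((config.coulomb_k * qq /
                     (config.dielectric_slope * r_eff * r_eff)).sum())
    near = r <= config.hbond_d_max
    hb = hbond_pairs(coords_a, params_a, coords_b, params_b, config,
                     pairs=(ia[near], ib[near]))
    hb_energy = float(sum(b[5] for b in hb))
    return CrossEnergy(lj, coulomb, hb_energy, clash)


def internal_energy(coords: np.ndarray, params: AtomParams,
                    config: EnergyConfig = DEFAULT_CONFIG) -> float:
    """Full pair energy within one atom set (for additivity checks)."""
    tree = cKDTree(coords)
    pairs = tree.query_pairs(config.cutoff, output_type="ndarray")
    if pairs.size == 0:
        return 0.0
    i, j = pairs[:, 0], pairs[:, 1]
    r = np.linalg.norm(coords[j] - coords[i], axis=1)
    r_eff = np.maximum(r, config.clash_dist)
    rmin = params.radius[i] + params.radius[j]
    epsij = np.sqrt(params.eps[i] * params.eps[j])
    x = (rmin / r_eff) ** 6
    lj = float(np.minimum(epsij * (x * x - 2.0 * x), config.clash_cap).sum())
    coulomb = float((config.coulomb_k * params.charge[i] * params.charge[j] /
                     (config.dielectric_slope * r_eff * r_eff)).sum())
    near = r <= config.hbond_d_max
    hb = hbond_pairs(coords, params, coords, params, config,
                     pairs=(i[near], j[near]))
    return lj + coulomb + float(sum(b[5] for b in hb))
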