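"""Binding-site centroids, inter-site distances and Kabsch superposition."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import SelectionError, Structure, select

#: orthosteric pocket of aminergic receptors, anchored by Asp 3.32
DEFAULT_ORTHOSTERIC = ("3.32", "6.48", "6.55")


@dataclass
class SiteSpec:
    """A binding site defined by generic-number selectors on one chain."""

    name: str = "orthosteric"
    chain: str = "A"
    residues: tuple[str, ...] = DEFAULT_ORTHOSTERIC
    atoms: str = "CA"  # atom-name list, or "*" for all atoms of the residues

    def selectors(self) -> list[str]:
        out = []
        for res in self.residues:
            if self.atoms == "*":
                out.append(f"{self.chain}:{res}")
            else:
                out.append(f"{self.chain}:{res}:{self.atoms}")
        return out


def site_centroid(structure: Structure, site: SiteSpec) -> np.ndarray:
    """Unweighted centroid of the site's selected atoms."""
    idx: list[int] = []
    for sel in site.selectors():
        idx.extend(select(structure, sel).tolist())
    if not idx:
        raise SelectionError(f"site {site.name!r} resolves no atoms")
    return structure.coord[sorted(set(idx))].mean(axis=0)


def site_distance(dimer: Structure, site1: SiteSpec, site2: SiteSpec,
                  mode: str = "direct", clearance: float = 5.0) -> float:
    """Distance between two site centroids.

    ``direct`` is the Euclidean (through-membrane) distance.
    ``extracellular_path`` approximates a route around the extracellular
    surface as the two-segment path via a waypoint on the dimer z-axis at
    ``max(z) + clearance`` — an explicit surrogate, always ≥ direct.
    """
    c1 = site_centroid(dimer, site1)
    c2 = site_centroid(dimer, site2)
    direct = float(np.linalg.norm(c1 - c2))
    if mode == "direct":
        return direct
    if mode != "extracellular_path":
        raise ValueError(f"unknown mode {mode!r}")
    center = dimer.coord.mean(axis=0)
    top = dimer.coord[:, 2].max() + clearance
    waypoint = np.array([center[0], center[1], top])
    return float(np.linalg.norm(c1 - waypoint) + np.linalg.norm(waypoint - c2))


def kabsch(mobile: np.ndarray, target: np.ndarray
           ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns ``(rotation, translation, rmsd)`` with a proper rotation
    (det = +1) such that ``mobile @ R.T + t`` best fits ``target``.
    """
    mobile = np.asarray(mobile, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if mobile.shape != target.shape:
        raise ValueError("coordinate sets must have equal shape")
    if mobile.shape[0] < 3:
        raise ValueError("need at least 3 atoms to superpose")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    p = mobile - mc
    q = target - tc
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = tc - rot @ mc
    moved = p @ rot.T
    rmsd = float(np.sqrt(((moved - q) ** 2).sum() / len(p)))
    return rot, t, rmsd


def superpose_rmsd(struct1: Structure, struct2: Structure,
                   selection: str | None = None
                   ) -> tuple[float, tuple[np.ndarray, np.ndarray]]:
    """Minimized RMSD (Å) between matching selections of two structures."""
    if selection is None:
        c1, c2 = struct1.coord, struct2.coord
    else:
        i1 = select(struct1, selection)
        i2 = select(struct2, selection)
        if len(i1) != len(i2):
            raise ValueError("selections resolve different atom counts")
        c1, c2 = struct1.coord[i1], struct2.coord[i2]
    rot, t, rmsd = kabsch(c2, c1)
    return rmsd, (rot, t)
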