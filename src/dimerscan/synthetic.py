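"""Idealized 7-TM bundle generator, interface decorations and toy trajectories.

Every downstream stage of the package (pose enumeration, interface
scoring, consensus ranking, trajectory diagnostics) is exercised on
structures built here: seven ideal α-helices around a central pocket,
short loops and tails, and minimal pseudo-side-chain interaction sites on
the functionally designated residues of class-A GPCRs — the orthosteric
pocket (3.32, 6.48, 6.55, facing the central axis), the ionic-lock
partners Arg 3.50 / Glu 6.30 (guanidinium-like triplet and
carboxylate-like pair planted facing each other at a configurable gap)
and a hydroxyl on Tyr 5.42.  All dimensions are artifact conventions for
an idealized bundle, not measurements of any receptor.

The generator is the ground truth for recovery tests: a
:class:`PatchSpec` decorates the outward faces of a chosen helix pair
with complementary charged donors/acceptors so that one dimer interface
class is energetically favorable by construction, and a
:class:`TrajectorySpec` plants Gaussian jitter and step displacements
whose magnitude and onset frame the analysis module must report back.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc

from .structure import (
    NumberingMap,
    SelectionError,
    Structure,
    Trajectory,
    select,
)

__all__ = [
    "BundleTemplate",
    "PatchSpec",
    "TrajectoryEvent",
    "TrajectorySpec",
    "default_annotations",
    "build_ideal_tm_bundle",
    "plant_interface_patch",
    "simulate_trajectory",
]

#: residue identity of each functionally designated generic position
DEFAULT_FUNCTIONAL: dict[str, str] = {
    "3.32": "ASP",
    "3.49": "ASP",
    "3.50": "ARG",
    "5.42": "TYR",
    "6.30": "GLU",
    "6.34": "THR",
    "6.48": "TRP",
    "6.55": "SER",
}

#: pocket residues whose side chains face the bundle axis
POCKET_GENERICS = ("3.32", "6.48", "6.55")

_TM = tuple(f"TM{i}" for i in range(1, 8))


class TemplateError(ValueError):
    """Degenerate bundle template."""


def _ellipse_axes(a: float = 13.0, b: float = 11.0) -> np.ndarray:
    az = np.deg2rad(360.0 * np.arange(7) / 7.0)
    return np.stack([a * np.cos(az), b * np.sin(az)], axis=1)


@dataclass
class BundleTemplate:
    """Geometric recipe for an idealized 7-TM helical bundle.

    Helix axes sit on an ellipse in the membrane plane; helices alternate
    up/down orientation along +z with a small alternating tilt.  Ideal
    α-helix parameters (1.5 Å rise, 100° twist, 2.3 Å CA radius) are the
    defaults.
    """

    helix_axis_positions: np.ndarray = field(default_factory=_ellipse_axes)
    helix_tilts: tuple[float, ...] = tuple(10.0 * (-1) ** k for k in range(7))
    helix_lengths: tuple[int, ...] = (26,) * 7
    loop_lengths: tuple[int, ...] = (3,) * 6
    tail_lengths: tuple[int, int] = (4, 4)
    rise_per_residue: float = 1.5
    twist_per_residue: float = 100.0
    calpha_radius: float = 2.3
    lock_gap: float = 3.5  # Arg3.50(N)–Glu6.30(O) planted distance, Å

    def __post_init__(self) -> None:
        self.helix_axis_positions = np.asarray(self.helix_axis_positions, dtype=float)
        if self.helix_axis_positions.shape != (7, 2):
            raise TemplateError("need exactly 7 helix axis positions")
        if len(self.helix_lengths) != 7 or len(self.helix_tilts) != 7:
            raise TemplateError("need 7 helix lengths and tilts")
        if len(self.loop_lengths) != 6:
            raise TemplateError("need 6 loop lengths")
        if self.rise_per_residue <= 0:
            raise TemplateError("rise_per_residue must be positive")
        d = self.helix_axis_positions
        for i in range(7):
            for j in range(i + 1, 7):
                if np.linalg.norm(d[i] - d[j]) < 6.0:
                    raise TemplateError(f"helix axes {i + 1} and {j + 1} closer than 6 Å")

    def helix_direction(self, k: int) -> np.ndarray:
        """Unit chain direction (N→C) of helix ``k`` (0-based); alternates ∓z."""
        sign = -1.0 if k % 2 == 0 else 1.0  # TM1 runs extracellular→intracellular
        tilt = np.deg2rad(self.helix_tilts[k])
        x, y = self.helix_axis_positions[k]
        az = np.arctan2(y, x)
        # lean by `tilt` in the radial plane of the helix position
        d = np.array([
            np.sin(tilt) * np.cos(az),
            np.sin(tilt) * np.sin(az),
            sign * np.cos(tilt),
        ])
        return d / np.linalg.norm(d)


@dataclass
class PatchSpec:
    """Complementary interaction-site decoration for a helix pair.

    Positively charged H-bond donors go on the outward face of
    ``helix_pair[0]`` and negative acceptors on ``helix_pair[1]``; in a
    symmetric dimer pose that presents both helices, each protomer's
    donors meet the partner's acceptors.
    """

    helix_pair: tuple[str, str] = ("TM4", "TM5")
    face_azimuth: float | None = None  # degrees; None = toward the mid-face
    donor_count: int = 6
    acceptor_count: int = 6
    charge_magnitude: float = 1.0  # elementary charges (ion pair), in B-factor
    guard_count: int = 6  # neutral steric knobs per flanking helix

    def __post_init__(self) -> None:
        for h in self.helix_pair:
            if h not in _TM:
                raise ValueError(f"unknown helix id {h!r}")
        if self.donor_count < 0 or self.acceptor_count < 0:
            raise ValueError("site counts must be non-negative")


@dataclass(frozen=True)
class TrajectoryEvent:
    """Step displacement of an atom group from a frame onward."""

    frame_index: int
    atom_group: str  # selection string
    displacement: tuple[float, float, float]


@dataclass
class TrajectorySpec:
    n_frames: int = 100
    jitter_sd: float = 0.2
    events: tuple[TrajectoryEvent, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        for ev in self.events:
            if not 0 <= ev.frame_index < self.n_frames:
                raise ValueError(f"event frame {ev.frame_index} outside trajectory")


# ---------------------------------------------------------------------------
# annotation defaults


def default_annotations(template: BundleTemplate) -> dict:
    """Segment table, x.50 references and functional-residue map.

    References place the conserved-position ranges so the designated
    generic numbers exist: 3.50 near the intracellular end of TM3 and 6.30
    at the intracellular start of TM6, as in class-A receptors; other
    helices take the midpoint.
    """
    segs: dict[str, tuple[int, int]] = {}
    res = 1
    nt, ct = template.tail_lengths
    if nt > 0:
        segs["N-term"] = (res, res + nt - 1)
        res += nt
    loop_labels = ("ICL1", "ECL1", "ICL2", "ECL2", "ICL3", "ECL3")
    for k in range(7):
        L = template.helix_lengths[k]
        segs[f"TM{k + 1}"] = (res, res + L - 1)
        res += L
        if k < 6 and template.loop_lengths[k] > 0:
            segs[loop_labels[k]] = (res, res + template.loop_lengths[k] - 1)
            res += template.loop_lengths[k]
    if ct > 0:
        segs["C-term"] = (res, res + ct - 1)
        res += ct

    refs: dict[str, int] = {}
    for k in range(7):
        label = f"TM{k + 1}"
        if label not in segs:
            continue
        lo, hi = segs[label]
        if label == "TM3":
            refs[label] = hi - 5       # generics span 3.(50-L+6) .. 3.55
        elif label == "TM6":
            refs[label] = lo + 20 if hi - lo >= 20 else (lo + hi) // 2
        else:
            refs[label] = (lo + hi) // 2
    return {"segments": segs, "x50": refs, "functional": dict(DEFAULT_FUNCTIONAL)}


# ---------------------------------------------------------------------------
# bundle construction


def _perp_frame(d: np.ndarray, outward: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal (u, v) ⊥ d with u along the projection of `outward`."""
    u = outward - np.dot(outward, d) * d
    n = np.linalg.norm(u)
    if n < 1e-9:
        u = np.array([1.0, 0.0, 0.0]) - d[0] * d
        n = np.linalg.norm(u)
    u = u / n
    v = np.cross(d, u)
    return u, v


class _AtomBuffer:
    def __init__(self) -> None:
        self.records: list[tuple[str, int, str, str, np.ndarray, float]] = []

    def add(self, res_name: str, res_id: int, atom_name: str, element: str,
            coord: np.ndarray, b_factor: float = 0.0) -> None:
        self.records.append((res_name, res_id, atom_name, element,
                             np.asarray(coord, dtype=float), b_factor))

    def to_structure(self, segments: dict, refs: dict) -> Structure:
        n = len(self.records)
        arr = struc.AtomArray(n)
        arr.coord = np.stack([r[4] for r in self.records])
        arr.chain_id = np.full(n, "A", dtype="U4")
        arr.res_name = np.array([r[0] for r in self.records], dtype="U5")
        arr.res_id = np.array([r[1] for r in self.records], dtype=int)
        arr.atom_name = np.array([r[2] for r in self.records], dtype="U6")
        arr.element = np.array([r[3] for r in self.records], dtype="U2")
        arr.hetero = np.zeros(n, dtype=bool)
        arr.set_annotation("b_factor", np.array([r[5] for r in self.records]))
        s = Structure(arr, dict(segments))
        s.assign_numbering(dict(refs))
        return s


def _sidechain_generic(buf: _AtomBuffer, res_name: str, res_id: int,
                       ca: np.ndarray, w: np.ndarray, helix_dir: np.ndarray) -> None:
    """Minimal interaction-site side chain along direction ``w`` from CA."""
    p = np.cross(w, helix_dir)
    n = np.linalg.norm(p)
    p = p / n if n > 1e-9 else np.array([0.0, 0.0, 1.0])
    cb = ca + 1.53 * w
    buf.add(res_name, res_id, "CB", "C", cb)
    if res_name == "ASP":
        cg = cb + 1.45 * w
        buf.add(res_name, res_id, "CG", "C", cg)
        buf.add(res_name, res_id, "OD1", "O", cg + 1.25 * (0.5 * w + 0.866 * p))
        buf.add(res_name, res_id, "OD2", "O", cg + 1.25 * (0.5 * w - 0.866 * p))
    elif res_name == "GLU":
        cd = cb + 2.4 * w
        buf.add(res_name, res_id, "CD", "C", cd)
        buf.add(res_name, res_id, "OE1", "O", cd + 1.25 * (0.5 * w + 0.866 * p))
        buf.add(res_name, res_id, "OE2", "O", cd + 1.25 * (0.5 * w - 0.866 * p))
    elif res_name == "ARG":
        cz = cb + 2.6 * w
        buf.add(res_name, res_id, "CZ", "C", cz)
        buf.add(res_name, res_id, "NE", "N", cz + 1.33 * (-0.5 * w + 0.866 * p))
        buf.add(res_name, res_id, "NH1", "N", cz + 1.33 * w)
        buf.add(res_name, res_id, "NH2", "N", cz + 1.33 * (-0.5 * w - 0.866 * p))
    elif res_name == "TYR":
        buf.add(res_name, res_id, "OH", "O", cb + 2.6 * w)
    elif res_name == "SER":
        buf.add(res_name, res_id, "OG", "O", cb + 1.4 * w)
    elif res_name == "THR":
        buf.add(res_name, res_id, "OG1", "O", cb + 1.4 * w)
    # TRP and plain ALA keep CB only


def build_ideal_tm_bundle(template: BundleTemplate | None = None,
                          annotations: dict | None = None) -> Structure:
    """Build an idealized inactive-state 7-TM monomer.

    Backbone atoms (N, CA, C, O) plus CB sit on ideal α-helix geometry for
    the seven labeled helices; loops and tails are interpolated.  The
    functional residues named in ``annotations["functional"]`` (generic
    number → residue type) receive pseudo-side-chain interaction sites;
    the Arg 3.50 guanidinium and Glu 6.30 carboxylate are planted facing
    each other ``template.lock_gap`` Å apart (the formed ionic lock of the
    inactive state).

    Raises :class:`TemplateError` for helices shorter than 4 residues or
    overlapping helix axes.
    """
    template = template if template is not None else BundleTemplate()
    if any(L < 4 for L in template.helix_lengths):
        raise TemplateError("helix length < 4 residues")
    ann = annotations if annotations is not None else default_annotations(template)
    segments: dict[str, tuple[int, int]] = ann["segments"]
    refs: dict[str, int] = ann["x50"]
    functional: dict[str, str] = ann.get("functional", dict(DEFAULT_FUNCTIONAL))
    numbering = NumberingMap(dict(refs), dict(segments))

    rise = template.rise_per_residue
    twist = np.deg2rad(template.twist_per_residue)
    r_ca = template.calpha_radius

    # residue id → (generic, res_name) for decorated residues
    special: dict[int, tuple[str, str]] = {}
    for gen, res_name in functional.items():
        try:
            special[numbering.resolve(gen)] = (gen, res_name)
        except SelectionError:
            continue  # generic not present with these helix lengths

    buf = _AtomBuffer()
    helix_frames = {}  # label -> (start, d, u, v, phase, lo)
    ca_of: dict[int, np.ndarray] = {}
    axis_of: dict[int, np.ndarray] = {}  # helix-axis point at each helix residue

    def helix_phase(k: int, lo: int) -> float:
        # rotate the helix so a designated pocket residue's CA faces inward
        anchor = {"TM3": "3.32", "TM6": "6.48"}.get(f"TM{k + 1}")
        if anchor is None:
            return 0.0
        try:
            res = numbering.resolve(anchor)
        except SelectionError:
            return 0.0
        return np.pi - twist * (res - lo)

    for k in range(7):
        label = f"TM{k + 1}"
        lo, hi = segments[label]
        L = hi - lo + 1
        d = template.helix_direction(k)
        base = np.array([*template.helix_axis_positions[k], 0.0])
        start = base - d * (rise * (L - 1) / 2.0)
        outward = np.array([*template.helix_axis_positions[k], 0.0])
        u, v = _perp_frame(d, outward / np.linalg.norm(outward))
        phase = helix_phase(k, lo)
        helix_frames[label] = (start, d, u, v, phase, lo)
        for i in range(L):
            res_id = lo + i
            axis_pt = start + d * rise * i
            theta = phase + twist * i

            def ring(radius: float, dth: float, dz: float) -> np.ndarray:
                t = theta + dth
                return axis_pt + d * dz + radius * (np.cos(t) * u + np.sin(t) * v)

            ca = ring(r_ca, 0.0, 0.0)
            n_at = ring(1.55, np.deg2rad(-27.0), -0.60)
            c_at = ring(1.65, np.deg2rad(+27.0), +0.55)
            o_at = c_at + d * 1.23
            res_name = special.get(res_id, ("", "ALA"))[1]
            buf.add(res_name, res_id, "N", "N", n_at)
            buf.add(res_name, res_id, "CA", "C", ca)
            buf.add(res_name, res_id, "C", "C", c_at)
            buf.add(res_name, res_id, "O", "O", o_at)
            if res_id not in special:  # poly-Ala: CB radially out of the helix
                w = (ca - axis_pt) / r_ca
                buf.add(res_name, res_id, "CB", "C", ca + 1.53 * w)
            ca_of[res_id] = ca
            axis_of[res_id] = axis_pt

    # side chains (lock residues get targeted placement afterwards)
    lock_res = set()
    for gen in ("3.50", "6.30"):
        try:
            lock_res.add(numbering.resolve(gen))
        except SelectionError:
            pass
    for res_id, (gen, res_name) in special.items():
        if res_id in lock_res:
            continue
        ca = ca_of[res_id]
        if gen in POCKET_GENERICS:
            w = -np.array([ca[0], ca[1], 0.0])  # toward the bundle axis
        else:
            w = ca - axis_of[res_id]            # radially out of the helix
        w = w / np.linalg.norm(w)
        label = numbering.generic(res_id)
        helix = f"TM{label.split('.')[0]}"
        d = helix_frames[helix][1]
        _sidechain_generic(buf, res_name, res_id, ca, w, d)

    # ionic lock: guanidinium triplet vs carboxylate pair at lock_gap
    if len(lock_res) == 2:
        r350 = numbering.resolve("3.50")
        r630 = numbering.resolve("6.30")
        a, b = ca_of[r350], ca_of[r630]
        t = (b - a) / np.linalg.norm(b - a)
        m = 0.5 * (a + b)
        p = np.cross(t, np.array([0.0, 0.0, 1.0]))
        if np.linalg.norm(p) < 1e-6:
            p = np.array([1.0, 0.0, 0.0])
        p = p / np.linalg.norm(p)
        g = template.lock_gap / 2.0
        cz = m - t * (g + 1.2)
        buf.add("ARG", r350, "CB", "C", a + 1.53 * (cz - a) / np.linalg.norm(cz - a))
        buf.add("ARG", r350, "CZ", "C", cz)
        buf.add("ARG", r350, "NE", "N", cz - t * 1.30)
        buf.add("ARG", r350, "NH1", "N", m - t * g + p * 1.0)
        buf.add("ARG", r350, "NH2", "N", m - t * g - p * 1.0)
        cd = m + t * (g + 1.2)
        buf.add("GLU", r630, "CB", "C", b + 1.53 * (cd - b) / np.linalg.norm(cd - b))
        buf.add("GLU", r630, "CD", "C", cd)
        buf.add("GLU", r630, "OE1", "O", m + t * g + p * 1.0)
        buf.add("GLU", r630, "OE2", "O", m + t * g - p * 1.0)

    # loops and tails: interpolated backbone, glycine
    def add_coil(res_ids: range, points: np.ndarray) -> None:
        for idx, res_id in enumerate(res_ids):
            ca = points[idx]
            nxt = points[idx + 1] if idx + 1 < len(points) else ca + np.array([1.0, 0, 0])
            prev = points[idx - 1] if idx > 0 else ca - (nxt - ca)
            dirn = nxt - prev
            dirn = dirn / max(np.linalg.norm(dirn), 1e-9)
            out = np.array([ca[0], ca[1], 0.0])
            out = out / max(np.linalg.norm(out), 1e-9)
            buf.add("GLY", res_id, "N", "N", ca - 1.2 * dirn)
            buf.add("GLY", res_id, "CA", "C", ca)
            buf.add("GLY", res_id, "C", "C", ca + 1.2 * dirn)
            buf.add("GLY", res_id, "O", "O", ca + 1.2 * dirn + 1.23 * out)

    loop_labels = ("ICL1", "ECL1", "ICL2", "ECL2", "ICL3", "ECL3")
    for k, lab in enumerate(loop_labels):
        if lab not in segments:
            continue
        lo, hi = segments[lab]
        prev_hi = segments[f"TM{k + 1}"][1]
        next_lo = segments[f"TM{k + 2}"][0]
        p0, p1 = ca_of[prev_hi], ca_of[next_lo]
        L = hi - lo + 1
        pts = []
        zsign = np.sign(p0[2]) or 1.0
        for i in range(L):
            f = (i + 1) / (L + 1)
            pts.append(p0 + f * (p1 - p0)
                       + np.array([0.0, 0.0, zsign * 2.0 * np.sin(np.pi * f)]))
        add_coil(range(lo, hi + 1), np.array(pts))

    if "N-term" in segments:
        lo, hi = segments["N-term"]
        start, d1, u, _, _, _ = helix_frames["TM1"]
        first_ca = ca_of[segments["TM1"][0]]
        pts = [first_ca + (hi + 1 - rid) * (-d1 * 3.2 + u * 0.8)
               for rid in range(lo, hi + 1)]
        add_coil(range(lo, hi + 1), np.array(pts))
    if "C-term" in segments:
        lo, hi = segments["C-term"]
        _, d7, u, _, _, _ = helix_frames["TM7"]
        last_ca = ca_of[segments["TM7"][1]]
        pts = [last_ca + (rid - lo + 1) * (d7 * 3.2 + u * 0.8)
               for rid in range(lo, hi + 1)]
        add_coil(range(lo, hi + 1), np.array(pts))

    return buf.to_structure(segments, refs)


# ---------------------------------------------------------------------------
# interface decoration


def plant_interface_patch(structure: Structure, patch: PatchSpec) -> Structure:
    """Decorate the outward faces of a helix pair with complementary sites.

    Adds ``donor_count`` positively charged donor pseudo-atoms (``PD1``)
    on the first helix and ``acceptor_count`` negative acceptors (``PA1``)
    on the second, as a flush rail along each helix face; the charge
    magnitude is stored in the B-factor column.  Neutral steric rim ridges
    (``PG1``) on the outer edges of the pair make the face a groove with
    shape complementarity: only a face-on approach nests between the rims,
    oblique approaches are held at standoff.  All pre-existing atoms are
    unchanged.
    """
    for h in patch.helix_pair:
        if h not in structure.segments:
            raise SelectionError(f"unknown helix id {h!r}")
    if patch.donor_count == 0 and patch.acceptor_count == 0 \
            and patch.guard_count == 0:
        return structure.copy()

    atoms = structure.atoms
    new_records = []

    # default face: the mid-face between the two helices, so that in the
    # symmetric matched pose each protomer's donors meet the partner's
    # acceptors head-on rather than obliquely
    if patch.face_azimuth is None:
        centers = []
        for h in patch.helix_pair:
            lo, hi = structure.segments[h]
            m = (atoms.res_id >= lo) & (atoms.res_id <= hi) & (atoms.atom_name == "CA")
            centers.append(atoms.coord[m][:, :2].mean(axis=0))
        mid = centers[0] + centers[1]
        face_dir = np.array([mid[0], mid[1], 0.0])
        face_dir = face_dir / np.linalg.norm(face_dir)
    else:
        az = np.deg2rad(patch.face_azimuth)
        face_dir = np.array([np.cos(az), np.sin(az), 0.0])

    def decorate(helix: str, count: int, name: str, element: str,
                 direction: np.ndarray, offset: float, b_factor: float) -> None:
        # sites form a rail along the helix axis at `offset` Å from it in
        # `direction`; evenly spaced, each attached to the nearest residue
        if count == 0:
            return
        lo, hi = structure.segments[helix]
        mask = (atoms.res_id >= lo) & (atoms.res_id <= hi) & (atoms.atom_name == "CA")
        res_ids = atoms.res_id[mask]
        cas = atoms.coord[mask]
        order = np.argsort(res_ids)
        res_ids, cas = res_ids[order], cas[order]
        n = len(res_ids)
        if count > (n + 1) // 2:
            raise ValueError(f"cannot place {count} sites on {helix} ({n} residues)")
        base = cas.mean(axis=0)
        # rails run along the membrane normal, not the (tilted) helix axis:
        # rails of facing protomers then stay parallel in any z-rotation pose
        axis = np.array([0.0, 0.0, 1.0])
        spacing = 3.0
        offsets = (np.arange(count) - (count - 1) / 2.0) * spacing
        ca_proj = (cas - base) @ axis
        for off in offsets:
            pos = base + off * axis + offset * direction
            idx = int(np.abs(ca_proj - off).argmin())  # host residue: nearest CA
            rid = int(res_ids[idx])
            rn = atoms.res_name[np.flatnonzero(atoms.res_id == rid)[0]]
            new_records.append((str(rn), rid, name, element, pos, b_factor))

    # the rails stand slightly proud of the CB ridge so that in a face-on
    # pose the opposing rails meet in a clear lane and can hydrogen-bond
    decorate(patch.helix_pair[0], patch.donor_count, "PD1", "N",
             face_dir, 5.5, patch.charge_magnitude)
    decorate(patch.helix_pair[1], patch.acceptor_count, "PA1", "O",
             face_dir, 5.5, patch.charge_magnitude)

    # steric rim guards: ridges on the outer edges of the decorated pair
    # turn the face into a groove — only a face-on approach nests between
    # them, oblique approaches are held at standoff
    az_face = np.arctan2(face_dir[1], face_dir[0])
    for h in patch.helix_pair:
        if patch.guard_count == 0:
            break
        lo, hi = structure.segments[h]
        m = (atoms.res_id >= lo) & (atoms.res_id <= hi) & (atoms.atom_name == "CA")
        cxy = atoms.coord[m][:, :2].mean(axis=0)
        az_h = np.arctan2(cxy[1], cxy[0])
        delta = np.arctan2(np.sin(az_h - az_face), np.cos(az_h - az_face))
        az_rim = az_h + np.sign(delta or 1.0) * np.deg2rad(15.0)
        rim_dir = np.array([np.cos(az_rim), np.sin(az_rim), 0.0])
        decorate(h, patch.guard_count, "PG1", "C", rim_dir, 6.5, 0.0)

    extra = struc.AtomArray(len(new_records))
    extra.coord = np.stack([r[4] for r in new_records])
    extra.chain_id = np.full(len(new_records), str(atoms.chain_id[0]), dtype="U4")
    extra.res_name = np.array([r[0] for r in new_records], dtype="U5")
    extra.res_id = np.array([r[1] for r in new_records], dtype=int)
    extra.atom_name = np.array([r[2] for r in new_records], dtype="U6")
    extra.element = np.array([r[3] for r in new_records], dtype="U2")
    extra.hetero = np.zeros(len(new_records), dtype=bool)
    extra.set_annotation("b_factor", np.array([r[5] for r in new_records]))
    if "b_factor" not in atoms.get_annotation_categories():
        atoms = atoms.copy()
        atoms.set_annotation("b_factor", np.zeros(atoms.array_length()))
    merged = atoms + extra
    out = Structure(merged, dict(structure.segments), structure.numbering)
    return out


# ---------------------------------------------------------------------------
# synthetic trajectories


def simulate_trajectory(structure: Structure, spec: TrajectorySpec) -> Trajectory:
    """Reference coordinates + i.i.d. Gaussian jitter + planted step events.

    Each event displaces its atom group by a fixed vector in every frame
    from ``frame_index`` onward (a persistent conformational change, e.g.
    an ionic-lock break).  The same seed reproduces the frames bit for
    bit.
    """
    ref = structure.coord.astype(np.float64)
    n_atoms = ref.shape[0]
    offsets = np.zeros((spec.n_frames, n_atoms, 3))
    for ev in spec.events:
        idx = select(structure, ev.atom_group)
        if idx.size == 0:
            raise SelectionError(f"event group {ev.atom_group!r} selects no atoms")
        offsets[ev.frame_index:, idx, :] += np.asarray(ev.displacement, dtype=float)
    rng = np.random.default_rng(spec.seed)
    jitter = rng.normal(0.0, spec.jitter_sd, size=(spec.n_frames, n_atoms, 3)) \
        if spec.jitter_sd > 0 else 0.0
    frames = ref[None, :, :] + offsets + jitter
    return Trajectory(structure.copy(), frames)
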