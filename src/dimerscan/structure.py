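"""Annotated structure data model, generic numbering and atom selection.

The package represents a receptor (or a dimer of two receptors) as a
:class:`Structure`: a ``biotite`` :class:`~biotite.structure.AtomArray`
plus a segment table mapping residue ranges to topology labels
(``N-term``, ``TM1`` … ``TM7``, ``ICL1`` … ``ECL3``, ``H8``, ``C-term``)
and an optional Ballesteros–Weinstein :class:`NumberingMap`.  The membrane
normal is the +z axis by convention; every operation in the package relies
on that frame.

Selections use a small colon-separated grammar::

    "A:3.50:NH1,NH2,NE"   chain A, generic number 3.50, three atoms
    "B:TM4"               all TM4 atoms of chain B
    "A,B:CA"              CA atoms of both chains
    "A:10-20:CA"          CA atoms of residues 10..20 of chain A

Fields after the chain field are classified by shape: a segment label, a
residue number or inclusive range, a generic number ``H.pos``, or a
comma-separated atom-name list.  All fields are combined with AND.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import biotite.structure as struc

TM_LABELS = tuple(f"TM{i}" for i in range(1, 8))

SEGMENT_LABELS = (
    ("N-term",)
    + ("TM1", "ICL1", "TM2", "ECL1", "TM3", "ICL2", "TM4", "ECL2",
       "TM5", "ICL3", "TM6", "ECL3", "TM7")
    + ("H8", "C-term")
)

_GENERIC_RE = re.compile(r"^([1-9])\.(\d+)$")
_RESNUM_RE = re.compile(r"^(\d+)(?:-(\d+))?$")
_ATOMLIST_RE = re.compile(r"^[A-Za-z][A-Za-z0-9']*(,[A-Za-z][A-Za-z0-9']*)*$")


class StructureError(ValueError):
    """Inconsistent structure contents."""


class SelectionError(ValueError):
    """Malformed or unresolvable selection string."""


class NumberingError(ValueError):
    """Invalid Ballesteros–Weinstein reference assignment."""


@dataclass(frozen=True)
class NumberingMap:
    """Ballesteros–Weinstein generic numbering for one segment table.

    ``refs`` gives, per helix label, the residue number that carries the
    generic position ``x.50`` (the most conserved residue of that helix).
    Residue *r* in helix *H* then maps to ``H.(50 + r - ref_H)``; residues
    outside the seven helices have no generic number.
    """

    refs: dict[str, int]
    segments: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        for helix, ref in self.refs.items():
            if helix not in self.segments:
                raise NumberingError(f"reference for unknown segment {helix!r}")
            lo, hi = self.segments[helix]
            if not lo <= ref <= hi:
                raise NumberingError(
                    f"{helix} x.50 reference residue {ref} outside range {lo}-{hi}"
                )

    def generic(self, res_id: int) -> str | None:
        """Generic number of a residue, or ``None`` outside the helices."""
        for helix, ref in self.refs.items():
            lo, hi = self.segments[helix]
            if lo <= res_id <= hi:
                return f"{helix[2:]}.{50 + res_id - ref}"
        return None

    def resolve(self, generic: str) -> int:
        """Residue number carrying a generic number such as ``\"3.50\"``."""
        m = _GENERIC_RE.match(generic)
        if m is None:
            raise SelectionError(f"malformed generic number {generic!r}")
        helix = f"TM{m.group(1)}"
        if helix not in self.refs:
            raise SelectionError(f"no numbering reference for {helix}")
        res_id = self.refs[helix] + int(m.group(2)) - 50
        lo, hi = self.segments[helix]
        if not lo <= res_id <= hi:
            raise SelectionError(f"generic number {generic} outside {helix} range")
        return res_id


@dataclass
class Structure:
    """Atomic model with segment annotations in the membrane frame (+z normal).

    ``segments`` maps a label to an inclusive residue-number range; for a
    dimer the same ranges apply to both chains (the protomers are copies).
    """

    atoms: struc.AtomArray
    segments: dict[str, tuple[int, int]] = field(default_factory=dict)
    numbering: NumberingMap | None = None
    check: bool = True  # skip re-validation for copies of validated structures

    membrane_normal = np.array([0.0, 0.0, 1.0])

    def __post_init__(self) -> None:
        if self.check:
            self.validate()

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return self.atoms.array_length()

    @property
    def coord(self) -> np.ndarray:
        return self.atoms.coord

    @coord.setter
    def coord(self, value: np.ndarray) -> None:
        self.atoms.coord = np.asarray(value, dtype=np.float64)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.atoms.chain_id:
            seen.setdefault(str(c))
        return list(seen)

    def copy(self) -> "Structure":
        return Structure(self.atoms.copy(), dict(self.segments), self.numbering,
                         check=False)

    def validate(self) -> None:
        n = self.atoms.array_length()
        if n == 0:
            raise StructureError("structure has zero atoms")
        if not np.all(np.isfinite(self.atoms.coord)):
            raise StructureError("non-finite coordinates")
        keys = list(zip(self.atoms.chain_id, self.atoms.res_id, self.atoms.atom_name))
        if len(set(keys)) != n:
            raise StructureError("duplicate (chain, residue, atom name) triple")
        ranges = sorted(self.segments.values())
        for (_, hi), (lo2, _) in zip(ranges, ranges[1:]):
            if lo2 <= hi:
                raise StructureError("overlapping segment ranges")

    # -- annotation helpers ------------------------------------------------
    def segment_of(self, res_id: int) -> str | None:
        for label, (lo, hi) in self.segments.items():
            if lo <= res_id <= hi:
                return label
        return None

    def tm_labels(self) -> list[str]:
        return [t for t in TM_LABELS if t in self.segments]

    def assign_numbering(self, refs: dict[str, int]) -> NumberingMap:
        self.numbering = NumberingMap(dict(refs), dict(self.segments))
        return self.numbering

    # -- geometry ----------------------------------------------------------
    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "Structure":
        """Copy with coordinates mapped by ``x -> R x + t``."""
        out = self.copy()
        coord = out.atoms.coord.astype(np.float64)
        if rotation is not None:
            coord = coord @ np.asarray(rotation, dtype=np.float64).T
        if translation is not None:
            coord = coord + np.asarray(translation, dtype=np.float64)
        out.atoms.coord = coord
        return out

    def centroid(self) -> np.ndarray:
        return self.atoms.coord.mean(axis=0)


@dataclass
class Trajectory:
    """Ordered coordinate frames over a fixed topology."""

    topology: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise StructureError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[0] < 1:
            raise StructureError("trajectory needs at least one frame")
        if self.frames.shape[1] != len(self.topology):
            raise StructureError(
                f"frame atom count {self.frames.shape[1]} != topology {len(self.topology)}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame(self, index: int) -> Structure:
        out = self.topology.copy()
        out.atoms.coord = self.frames[index].copy()
        return out


def assign_generic_numbers(structure: Structure, refs: dict[str, int]) -> NumberingMap:
    """Attach a Ballesteros–Weinstein map built from per-helix x.50 references."""
    return structure.assign_numbering(refs)


def rotation_about_z(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _classify_field(text: str) -> tuple[str, object]:
    if text in SEGMENT_LABELS:
        return "segment", text
    m = _GENERIC_RE.match(text)
    if m is not None:
        return "generic", text
    m = _RESNUM_RE.match(text)
    if m is not None:
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) else lo
        if hi < lo:
            raise SelectionError(f"descending residue range {text!r}")
        return "residues", (lo, hi)
    if _ATOMLIST_RE.match(text):
        return "atoms", tuple(text.split(","))
    raise SelectionError(f"cannot interpret selection field {text!r}")


def select(structure: Structure, selector: str) -> np.ndarray:
    """Resolve a selection string to an ordered array of atom indices.

    The first colon-separated field names the chains (``*`` for all);
    every further field narrows the selection (segment label, residue
    number/range, generic number, or atom-name list).
    """
    if not isinstance(selector, str) or not selector.strip():
        raise SelectionError("empty selector")
    fields = [f.strip() for f in selector.split(":")]
    if any(not f for f in fields):
        raise SelectionError(f"empty field in selector {selector!r}")
    atoms = structure.atoms
    mask = np.ones(atoms.array_length(), dtype=bool)

    chains = fields[0]
    if chains != "*":
        wanted = set(chains.split(","))
        known = set(str(c) for c in atoms.chain_id)
        unknown = wanted - known
        if unknown:
            raise SelectionError(f"unknown chain(s) {sorted(unknown)}")
        mask &= np.isin(atoms.chain_id, sorted(wanted))

    for text in fields[1:]:
        kind, value = _classify_field(text)
        if kind == "segment":
            if value not in structure.segments:
                raise SelectionError(f"segment {value!r} not annotated")
            lo, hi = structure.segments[value]
            mask &= (atoms.res_id >= lo) & (atoms.res_id <= hi)
        elif kind == "generic":
            if structure.numbering is None:
                raise SelectionError("structure carries no generic numbering")
            res = structure.numbering.resolve(value)  # may raise
            mask &= atoms.res_id == res
        elif kind == "residues":
            lo, hi = value
            mask &= (atoms.res_id >= lo) & (atoms.res_id <= hi)
        else:  # atom names
            mask &= np.isin(atoms.atom_name, value)
    return np.flatnonzero(mask)


def select_coords(structure: Structure, selector: str) -> np.ndarray:
    return structure.coord[select(structure, selector)]


def concat_chains(parts: Iterable[tuple[str, Structure]]) -> Structure:
    """Assemble a multi-chain structure from (chain_id, monomer) pairs.

    Segment annotations are taken from the first part (the protomers of a
    homodimer share residue numbering).
    """
    parts = list(parts)
    arrays = []
    for chain_id, part in parts:
        a = part.atoms.copy()
        a.chain_id = np.full(a.array_length(), chain_id, dtype="U4")
        arrays.append(a)
    merged = arrays[0]
    for a in arrays[1:]:
        merged += a
    first = parts[0][1]
    return Structure(merged, dict(first.segments), first.numbering,
                     check=len(set(p[0] for p in parts)) != len(parts))
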