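"""PDB reading/writing and sidecar annotation configs.

Single-model PDB files load as :class:`~dimerscan.structure.Structure`;
files with MODEL/ENDMDL records load as
:class:`~dimerscan.structure.Trajectory`.  Segment ranges and x.50
references travel in a YAML sidecar named ``<file>.yaml`` next to the PDB
(they cannot be inferred from coordinates).  Planted interaction-site
charges are carried in the B-factor column, the only PDB field free for
per-atom scalars, so decorated structures round-trip losslessly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
import biotite.structure as struc
from biotite.structure.io import pdb

from .structure import Structure, Trajectory


class PDBFormatError(ValueError):
    """Unreadable or inconsistent PDB content."""


def _validate_atom_lines(path: Path) -> None:
    """Pre-check ATOM/HETATM records so parse failures name the line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBFormatError(f"{path}:{lineno}: truncated ATOM record")
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
                int(line[22:26])
            except ValueError as exc:
                raise PDBFormatError(f"{path}:{lineno}: unparseable ATOM record") from exc


def sidecar_path(pdb_path: str | Path) -> Path:
    return Path(str(pdb_path) + ".yaml")


def save_annotations(path: str | Path,
                     segments: dict[str, tuple[int, int]],
                     refs: dict[str, int] | None = None) -> None:
    data: dict = {"segments": {k: [int(v[0]), int(v[1])] for k, v in segments.items()}}
    if refs:
        data["x50"] = {k: int(v) for k, v in refs.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def load_annotations(path: str | Path) -> tuple[dict[str, tuple[int, int]], dict[str, int]]:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    segments = {str(k): (int(v[0]), int(v[1])) for k, v in (data.get("segments") or {}).items()}
    refs = {str(k): int(v) for k, v in (data.get("x50") or {}).items()}
    return segments, refs


def write_structure(obj: Structure | Trajectory, path: str | Path,
                    annotations: bool = True) -> Path:
    """Write a structure (single model) or trajectory (MODEL/ENDMDL) PDB.

    With ``annotations=True`` the segment table and numbering references are
    written to the ``<file>.yaml`` sidecar so :func:`read_structure` can
    restore them.
    """
    path = Path(path)
    if isinstance(obj, Trajectory):
        topo = obj.topology
        stack = struc.stack([topo.atoms] * obj.n_frames)
        stack.coord = obj.frames.astype(np.float32)
        file = pdb.PDBFile()
        file.set_structure(stack)
    else:
        topo = obj
        file = pdb.PDBFile()
        file.set_structure(obj.atoms)
    file.write(str(path))
    if annotations and topo.segments:
        refs = topo.numbering.refs if topo.numbering is not None else None
        save_annotations(sidecar_path(path), topo.segments, refs)
    return path


def read_structure(path: str | Path) -> Structure | Trajectory:
    """Read a PDB file into a Structure (single model) or Trajectory.

    Any ``<file>.yaml`` sidecar is applied as segment/numbering annotation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_atom_lines(path)
    with open(path) as fh:
        text = fh.read()
    has_models = any(line.startswith("MODEL") for line in text.splitlines())
    file = pdb.PDBFile.read(str(path))
    try:
        stack = file.get_structure(extra_fields=["b_factor"])
    except Exception as exc:  # biotite raises on per-model atom-count mismatch
        raise PDBFormatError(f"{path}: inconsistent models ({exc})") from exc
    if stack.array_length() == 0:
        raise PDBFormatError(f"{path}: zero atoms")
    stack.coord = stack.coord.astype(np.float64)

    segments: dict[str, tuple[int, int]] = {}
    refs: dict[str, int] = {}
    sc = sidecar_path(path)
    if sc.exists():
        segments, refs = load_annotations(sc)

    first = stack[0] if isinstance(stack, struc.AtomArrayStack) else stack
    topo = Structure(first.copy(), segments)
    if refs:
        topo.assign_numbering(refs)

    if has_models and isinstance(stack, struc.AtomArrayStack):
        return Trajectory(topo, stack.coord.astype(np.float64))
    return topo
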