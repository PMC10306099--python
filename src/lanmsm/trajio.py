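"""Reading and writing trajectories and feature matrices.

Supported formats
-----------------
* Multi-model PDB (fixed columns, frames delimited by MODEL/ENDMDL).
* XYZ frame blocks (assumed Angstrom).
* Feature matrices as CSV (header row = feature names, values written with 12
  significant digits, optional ``# source_id=...`` comment line) or as the
  package's array container.

Array container (".fmat") byte layout
-------------------------------------
``b"FMAT01"`` magic (6 bytes), then an unsigned little-endian 32-bit header
length, then that many bytes of UTF-8 JSON with keys ``shape`` ([frames,
features]), ``feature_names``, ``source_id``, ``dtype`` (always ``"<f8"``) and
``order`` (always ``"C"``), then ``frames*features`` little-endian 64-bit
floats in row-major order. Round-trips are bitwise lossless.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np

from .containers import Atom, FeatureMatrix, Topology, Trajectory

__all__ = [
    "FormatError",
    "read_pdb_models",
    "write_pdb_models",
    "read_xyz",
    "write_feature_matrix",
    "read_feature_matrix",
]

_MAGIC = b"FMAT01"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _infer_element(name: str) -> str:
    """Element from a PDB atom-name column (peptide heuristics: first letter
    after stripping digits, so CB->C, SG->S, HG1->H, N->N)."""
    stripped = name.strip().lstrip("0123456789")
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return ""


def _parse_atom_line(line: str, lineno: int):
    name = line[12:16].strip()
    resname = line[17:20].strip()
    try:
        serial = int(line[6:11])
        resseq = int(line[22:26])
        xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
    except ValueError as exc:
        raise FormatError(f"unparsable ATOM record at line {lineno}: {exc}") from None
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = _infer_element(name)
    if not element:
        raise FormatError(f"cannot infer element for atom {name!r} at line {lineno}")
    return serial, name, element, resname, resseq, xyz


def read_pdb_models(path) -> Trajectory:
    """Read a (multi-model) PDB file into a Trajectory.

    A file without MODEL records yields a single frame. All models must have
    identical atom count and atom order.
    """
    path = Path(path)
    models: list[list] = []
    current: list | None = None
    saw_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                saw_model = True
                current = []
            elif rec == "ENDMDL":
                if current is not None:
                    models.append(current)
                current = None
            elif rec in ("ATOM  ", "HETATM"):
                if current is None:
                    if saw_model:
                        # atoms outside MODEL blocks in a multi-model file
                        continue
                    current = []
                    models.append(current)
                current.append(_parse_atom_line(line, lineno))
    if current is not None and saw_model:
        models.append(current)
    if not models or not models[0]:
        raise FormatError(f"{path}: no ATOM records found")

    first = models[0]
    residues: list[tuple[int, str]] = []
    atoms: list[Atom] = []
    for serial, name, element, resname, resseq, _ in first:
        if not residues or residues[-1][0] != resseq:
            residues.append((resseq, resname))
        atoms.append(Atom(serial, name, element, resseq))
    topology = Topology(residues, atoms)

    coords = np.empty((len(models), len(first), 3))
    for m, model in enumerate(models):
        if len(model) != len(first):
            raise FormatError(
                f"{path}: model {m + 1} has {len(model)} atoms, expected {len(first)}"
            )
        for k, entry in enumerate(model):
            if entry[1] != first[k][1]:
                raise FormatError(
                    f"{path}: model {m + 1} atom {k + 1} named {entry[1]!r}, "
                    f"expected {first[k][1]!r}"
                )
            coords[m, k] = entry[5]
    return Trajectory(topology, coords, source_id=path.stem)


def write_pdb_models(traj: Trajectory, path) -> None:
    """Write a Trajectory as a fixed-column multi-model PDB file."""
    top = traj.topology
    resname = {i: n for i, n in top.residues}
    with open(path, "w") as fh:
        for m in range(traj.n_frames):
            fh.write(f"MODEL     {m + 1:4d}\n")
            for k, atom in enumerate(top.atoms):
                x, y, z = traj.coordinates[m, k]
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                fh.write(
                    f"ATOM  {atom.serial:5d} {name}{'':1s}{resname[atom.residue_index]:>3s} "
                    f"A{atom.residue_index:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_xyz(path, topology: Topology | None = None) -> Trajectory:
    """Read XYZ frame blocks (natoms / comment / atom lines), assumed Angstrom.

    Without a topology, all atoms are placed in a single residue ``UNK 1``.
    """
    path = Path(path)
    frames = []
    elements: list[str] | None = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    lineno = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise FormatError(f"{path}: expected atom count at line {i + 1}")
        block = lines[i + 2:i + 2 + natoms]
        if len(block) < natoms:
            raise FormatError(f"{path}: truncated frame starting at line {i + 1}")
        frame = np.empty((natoms, 3))
        elems = []
        for j, line in enumerate(block):
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}: bad XYZ atom line {i + 3 + j}")
            elems.append(parts[0])
            try:
                frame[j] = [float(p) for p in parts[1:4]]
            except ValueError:
                raise FormatError(f"{path}: unparsable coordinate at line {i + 3 + j}")
        if elements is None:
            elements = elems
        elif len(elems) != len(elements):
            raise FormatError(f"{path}: inconsistent atom count across frames")
        frames.append(frame)
        i += 2 + natoms
    if not frames:
        raise FormatError(f"{path}: empty XYZ file")
    if topology is None:
        atoms = [
            Atom(k + 1, f"{el}{k + 1}", el.upper(), 1)
            for k, el in enumerate(elements)
        ]
        topology = Topology([(1, "UNK")], atoms)
    return Trajectory(topology, np.stack(frames), source_id=path.stem)


# ---------------------------------------------------------------------------
# feature-matrix persistence


def write_feature_matrix(fm: FeatureMatrix, path, format: str = "fmat") -> None:
    path = Path(path)
    if format == "fmat":
        header = json.dumps(
            {
                "shape": list(fm.values.shape),
                "feature_names": fm.feature_names,
                "source_id": fm.source_id,
                "dtype": "<f8",
                "order": "C",
            }
        ).encode()
        with open(path, "wb") as fh:
            fh.write(_MAGIC)
            fh.write(struct.pack("<I", len(header)))
            fh.write(header)
            fh.write(np.ascontiguousarray(fm.values, dtype="<f8").tobytes())
    elif format == "csv":
        with open(path, "w") as fh:
            if fm.source_id:
                fh.write(f"# source_id={fm.source_id}\n")
            fh.write(",".join(fm.feature_names) + "\n")
            for row in fm.values:
                fh.write(",".join(f"{v:.12g}" for v in row) + "\n")
    else:
        raise ValueError(f"unknown feature-matrix format {format!r}")


def read_feature_matrix(path, format: str | None = None) -> FeatureMatrix:
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "fmat"
    if format == "fmat":
        with open(path, "rb") as fh:
            magic = fh.read(len(_MAGIC))
            if magic != _MAGIC:
                raise FormatError(f"{path}: not an fmat container")
            (hlen,) = struct.unpack("<I", fh.read(4))
            header = json.loads(fh.read(hlen).decode())
            shape = tuple(header["shape"])
            data = np.frombuffer(fh.read(shape[0] * shape[1] * 8), dtype="<f8")
        names = header["feature_names"]
        if len(set(names)) != len(names):
            raise FormatError(f"{path}: duplicated feature names")
        return FeatureMatrix(
            data.reshape(shape).copy(), names, header.get("source_id", "")
        )
    if format == "csv":
        with open(path) as fh:
            source_id = ""
            line = fh.readline()
            if line.startswith("#"):
                if "source_id=" in line:
                    source_id = line.split("source_id=", 1)[1].strip()
                line = fh.readline()
            names = [c.strip() for c in line.rstrip("\n").split(",")]
            if len(set(names)) != len(names):
                raise FormatError(f"{path}: duplicated column header")
            rows = [
                [float(v) for v in ln.split(",")]
                for ln in fh
                if ln.strip()
            ]
        values = np.array(rows) if rows else np.empty((0, len(names)))
        return FeatureMatrix(values, names, source_id)
    raise ValueError(f"unknown feature-matrix format {format!r}")
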