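"""Readers/writers for PDB, GRO and XYZ structure files.

Internal positions are nm.  PDB and XYZ store Å and are converted at the
boundary; GRO is already nm.  PDB/XYZ carry a box only when a CRYST1
record (PDB) is present — otherwise the box is returned as ``None`` and
the caller must supply one.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from ..units import ANGSTROM_TO_NM, NM_TO_ANGSTROM
from .types import AtomRecord, SimulationBox

__all__ = ["read_structure", "write_structure", "StructureParseError"]


class StructureParseError(ValueError):
    pass


def read_structure(path, format: str | None = None):
    """Read a structure file.

    Parameters
    ----------
    path : path-like
    format : {'pdb', 'gro', 'xyz'} or None
        Inferred from the file suffix when None.

    Returns
    -------
    (list of AtomRecord, SimulationBox or None)
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "pdb":
        return _read_pdb(path)
    if fmt == "gro":
        return _read_gro(path)
    if fmt == "xyz":
        return _read_xyz(path)
    raise ValueError(f"unsupported structure format: {fmt!r}")


def write_structure(atoms, box, path, format: str | None = None) -> None:
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "pdb":
        path.write_text(_pdb_text(atoms, box))
    elif fmt == "gro":
        path.write_text(_gro_text(atoms, box))
    elif fmt == "xyz":
        path.write_text(_xyz_text(atoms))
    else:
        raise ValueError(f"unsupported structure format: {fmt!r}")


# ----------------------------------------------------------------------
# helpers shared with trajectory IO
# ----------------------------------------------------------------------

def atoms_positions(atoms) -> np.ndarray:
    return np.array([a.position for a in atoms], dtype=float)


def _guess_element(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    if len(stripped) >= 2 and stripped[:2].capitalize() in ("Cl", "Br", "Na"):
        return stripped[:2].capitalize()
    return stripped[0].upper()


# ----------------------------------------------------------------------
# PDB
# ----------------------------------------------------------------------

def _read_pdb(path: Path):
    atoms, box = parse_pdb_lines(path.read_text().splitlines(), label=str(path))
    if not atoms:
        raise StructureParseError(f"{path}: no ATOM/HETATM records found")
    return atoms, box


def parse_pdb_lines(lines, label="<pdb>"):
    atoms: list[AtomRecord] = []
    box = None
    mol_id = 0
    last_resid = None
    for lineno, line in enumerate(lines, start=1):
        rec = line[:6].strip()
        if rec == "CRYST1":
            try:
                a, b, c = float(line[6:15]), float(line[15:24]), float(line[24:33])
                al, be, ga = float(line[33:40]), float(line[40:47]), float(line[47:54])
            except ValueError as exc:
                raise StructureParseError(f"{label}:{lineno}: bad CRYST1 record: {exc}")
            box = SimulationBox.from_parameters(
                a * ANGSTROM_TO_NM, b * ANGSTROM_TO_NM, c * ANGSTROM_TO_NM, al, be, ga
            )
        elif rec in ("ATOM", "HETATM"):
            try:
                name = line[12:16].strip()
                resname = line[17:20].strip() or "MOL"
                resid = int(line[22:26])
                x = float(line[30:38]) * ANGSTROM_TO_NM
                y = float(line[38:46]) * ANGSTROM_TO_NM
                z = float(line[46:54]) * ANGSTROM_TO_NM
            except ValueError as exc:
                raise StructureParseError(f"{label}:{lineno}: bad ATOM record: {exc}")
            element = line[76:78].strip() or _guess_element(name)
            if last_resid is not None and resid != last_resid:
                mol_id += 1
            last_resid = resid
            atoms.append(
                AtomRecord(
                    index=len(atoms),
                    name=name,
                    element=element,
                    molecule_id=mol_id,
                    residue_name=resname,
                    position=np.array([x, y, z]),
                )
            )
    return atoms, box


def _pdb_text(atoms, box) -> str:
    lines = []
    if box is not None:
        a, b, c, al, be, ga = box.parameters
        lines.append(
            f"CRYST1{a * NM_TO_ANGSTROM:9.3f}{b * NM_TO_ANGSTROM:9.3f}"
            f"{c * NM_TO_ANGSTROM:9.3f}{al:7.2f}{be:7.2f}{ga:7.2f} P 1           1"
        )
    for a_ in atoms:
        x, y, z = a_.position * NM_TO_ANGSTROM
        serial = (a_.index + 1) % 100000
        resid = (a_.molecule_id + 1) % 10000
        name = a_.name[:4]
        namef = f" {name:<3s}" if len(name) < 4 else name
        lines.append(
            f"HETATM{serial:5d} {namef} {a_.residue_name[:3]:>3s}  {resid:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {a_.element[:2]:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


# ----------------------------------------------------------------------
# GRO
# ----------------------------------------------------------------------

def _read_gro(path: Path):
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise StructureParseError(f"{path}: truncated GRO file")
    try:
        n_atoms = int(lines[1].strip())
    except ValueError:
        raise StructureParseError(f"{path}:2: atom count line is not an integer")
    if len(lines) < n_atoms + 3:
        raise StructureParseError(f"{path}: expected {n_atoms} atom lines")
    atoms: list[AtomRecord] = []
    mol_id = 0
    last_resid = None
    for k in range(n_atoms):
        line = lines[2 + k]
        try:
            resid = int(line[0:5])
            resname = line[5:10].strip()
            name = line[10:15].strip()
            x = float(line[20:28])
            y = float(line[28:36])
            z = float(line[36:44])
        except ValueError as exc:
            raise StructureParseError(f"{path}:{3 + k}: bad GRO atom line: {exc}")
        if last_resid is not None and resid != last_resid:
            mol_id += 1
        last_resid = resid
        atoms.append(
            AtomRecord(
                index=k,
                name=name,
                element=_guess_element(name),
                molecule_id=mol_id,
                residue_name=resname,
                position=np.array([x, y, z]),
            )
        )
    box_fields = lines[2 + n_atoms].split()
    try:
        vals = [float(v) for v in box_fields]
    except ValueError as exc:
        raise StructureParseError(f"{path}: bad box line: {exc}")
    if len(vals) == 3:
        box = SimulationBox.orthorhombic(*vals)
    elif len(vals) == 9:
        # GROMACS order: xx yy zz xy xz yx yz zx zy
        xx, yy, zz, xy, xz, yx, yz, zx, zy = vals
        box = SimulationBox(np.array([[xx, xy, xz], [yx, yy, yz], [zx, zy, zz]]))
    else:
        raise StructureParseError(f"{path}: box line must have 3 or 9 fields")
    return atoms, box


def _gro_text(atoms, box, title="dispermd", velocities=None) -> str:
    if box is None:
        raise ValueError("GRO format requires a box")
    lines = [title, f"{len(atoms):5d}"]
    for k, a_ in enumerate(atoms):
        x, y, z = a_.position
        resid = (a_.molecule_id + 1) % 100000
        line = (
            f"{resid:5d}{a_.residue_name[:5]:<5s}{a_.name[:5]:>5s}"
            f"{(a_.index + 1) % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}"
        )
        if velocities is not None:
            vx, vy, vz = velocities[k]
            line += f"{vx:8.4f}{vy:8.4f}{vz:8.4f}"
        lines.append(line)
    h = box.lattice_vectors
    if box.is_orthorhombic:
        lines.append(f"{h[0, 0]:10.5f}{h[1, 1]:10.5f}{h[2, 2]:10.5f}")
    else:
        vals = [
            h[0, 0], h[1, 1], h[2, 2],
            h[0, 1], h[0, 2], h[1, 0], h[1, 2], h[2, 0], h[2, 1],
        ]
        lines.append("".join(f"{v:10.5f}" for v in vals))
    return "\n".join(lines) + "\n"


# ----------------------------------------------------------------------
# XYZ
# ----------------------------------------------------------------------

def _read_xyz(path: Path):
    with path.open() as fh:
        atoms, _ = read_xyz_block(fh, path=path)
    return atoms, None


def read_xyz_block(fh, path="<xyz>"):
    """Read one XYZ frame from an open file handle; returns (atoms, comment)."""
    header = fh.readline()
    if not header.strip():
        return None, None
    try:
        n = int(header.strip())
    except ValueError:
        raise StructureParseError(f"{path}: XYZ count line is not an integer: {header!r}")
    comment = fh.readline().rstrip("\n")
    atoms: list[AtomRecord] = []
    for k in range(n):
        line = fh.readline()
        parts = line.split()
        if len(parts) < 4:
            raise StructureParseError(f"{path}: truncated XYZ atom line {line!r}")
        el = parts[0]
        try:
            pos = np.array([float(v) for v in parts[1:4]]) * ANGSTROM_TO_NM
        except ValueError as exc:
            raise StructureParseError(f"{path}: bad XYZ coordinates {line!r}: {exc}")
        atoms.append(
            AtomRecord(
                index=k, name=el, element=el, molecule_id=0,
                residue_name="MOL", position=pos,
            )
        )
    return atoms, comment


def _xyz_text(atoms, comment="") -> str:
    lines = [str(len(atoms)), comment]
    for a_ in atoms:
        x, y, z = a_.position * NM_TO_ANGSTROM
        lines.append(f"{a_.element:<3s} {x:15.8f} {y:15.8f} {z:15.8f}")
    return "\n".join(lines) + "\n"
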