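"""Trajectory writers/readers: multi-frame XYZ, multi-model PDB, and a
documented little-endian binary format.

Binary layout (all little-endian):

========  =======  ==============================================
offset    type     meaning
========  =======  ==============================================
0         4 bytes  magic ``b"DMDT"``
4         <u4      format version (1)
8         <u4      number of atoms N
12        <u4      1 if frames carry velocities else 0
16        <u4      number of frames M
then M frame blocks, each:
          <f8      time (ps)
          9×<f8    lattice vectors, row-major (rows a, b, c), nm
          3N×<f8   positions, row-major, nm
          3N×<f8   velocities (only if the header flag is 1), nm/ps
========  =======  ==============================================
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from ..units import NM_TO_ANGSTROM
from .structure_io import (
    StructureParseError,
    _pdb_text,
    parse_pdb_lines,
    read_xyz_block,
)
from .types import AtomRecord, Frame, SimulationBox, Trajectory

__all__ = ["write_trajectory", "read_trajectory"]

_MAGIC = b"DMDT"
_VERSION = 1


def write_trajectory(traj: Trajectory, path, format: str | None = None, atoms=None):
    """Write a trajectory as ``multi_xyz``, ``multi_pdb`` or ``bin``.

    ``atoms`` (list of AtomRecord) supplies names/residues for the PDB
    writer; synthesized as generic carbons when omitted.
    """
    path = Path(path)
    fmt = format or {".xyz": "multi_xyz", ".pdb": "multi_pdb", ".bin": "bin"}.get(
        path.suffix, None
    )
    if fmt == "bin":
        _write_bin(traj, path)
    elif fmt == "multi_xyz":
        _write_multi_xyz(traj, path, atoms)
    elif fmt == "multi_pdb":
        _write_multi_pdb(traj, path, atoms)
    else:
        raise ValueError(f"unsupported trajectory format: {fmt!r}")


def read_trajectory(path, format: str | None = None) -> Trajectory:
    path = Path(path)
    fmt = format or {".xyz": "multi_xyz", ".pdb": "multi_pdb", ".bin": "bin"}.get(
        path.suffix, None
    )
    if fmt == "bin":
        return _read_bin(path)
    if fmt == "multi_xyz":
        return _read_multi_xyz(path)
    if fmt == "multi_pdb":
        return _read_multi_pdb(path)
    raise ValueError(f"unsupported trajectory format: {fmt!r}")


# ----------------------------------------------------------------------

def _default_atoms(frame: Frame):
    return [
        AtomRecord(index=i, name="C", element="C", molecule_id=0,
                   residue_name="MOL", position=p)
        for i, p in enumerate(frame.positions)
    ]


def _write_bin(traj: Trajectory, path: Path) -> None:
    n = traj.n_atoms
    has_vel = all(f.velocities is not None for f in traj.frames)
    with path.open("wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<IIII", _VERSION, n, int(has_vel), len(traj)))
        for f in traj.frames:
            if f.box is None:
                raise ValueError("binary trajectory frames require a box")
            fh.write(struct.pack("<d", f.time))
            fh.write(np.ascontiguousarray(f.box.lattice_vectors, dtype="<f8").tobytes())
            fh.write(np.ascontiguousarray(f.positions, dtype="<f8").tobytes())
            if has_vel:
                fh.write(np.ascontiguousarray(f.velocities, dtype="<f8").tobytes())


def _read_bin(path: Path) -> Trajectory:
    data = path.read_bytes()
    if data[:4] != _MAGIC:
        raise StructureParseError(f"{path}: bad magic, not a dispermd binary trajectory")
    version, n, has_vel, m = struct.unpack_from("<IIII", data, 4)
    if version != _VERSION:
        raise StructureParseError(f"{path}: unsupported binary version {version}")
    off = 20
    frames = []
    vec_bytes = n * 3 * 8
    for _ in range(m):
        (t,) = struct.unpack_from("<d", data, off)
        off += 8
        h = np.frombuffer(data, dtype="<f8", count=9, offset=off).reshape(3, 3)
        off += 72
        pos = np.frombuffer(data, dtype="<f8", count=3 * n, offset=off).reshape(n, 3)
        off += vec_bytes
        vel = None
        if has_vel:
            vel = np.frombuffer(data, dtype="<f8", count=3 * n, offset=off).reshape(n, 3)
            off += vec_bytes
        frames.append(
            Frame(time=t, positions=pos.copy(), box=SimulationBox(h.copy()),
                  velocities=None if vel is None else vel.copy())
        )
    if len(frames) != m:
        raise StructureParseError(f"{path}: truncated binary trajectory")
    return Trajectory(frames)


def _write_multi_xyz(traj: Trajectory, path: Path, atoms) -> None:
    atoms = atoms or _default_atoms(traj.frames[0])
    chunks = []
    for f in traj.frames:
        lines = [str(f.n_atoms), f"t= {f.time:.6f} ps"]
        for a_, p in zip(atoms, f.positions):
            x, y, z = p * NM_TO_ANGSTROM
            lines.append(f"{a_.element:<3s} {x:15.8f} {y:15.8f} {z:15.8f}")
        chunks.append("\n".join(lines))
    path.write_text("\n".join(chunks) + "\n")


def _read_multi_xyz(path: Path) -> Trajectory:
    frames = []
    with path.open() as fh:
        k = 0
        while True:
            atoms, comment = read_xyz_block(fh, path=path)
            if atoms is None:
                break
            t = float(k)
            if comment and "t=" in comment:
                try:
                    t = float(comment.split("t=")[1].split()[0])
                except (ValueError, IndexError):
                    pass
            frames.append(
                Frame(time=t, positions=np.array([a.position for a in atoms]))
            )
            k += 1
    if not frames:
        raise StructureParseError(f"{path}: no frames found")
    return Trajectory(frames)


def _write_multi_pdb(traj: Trajectory, path: Path, atoms) -> None:
    atoms = atoms or _default_atoms(traj.frames[0])
    chunks = []
    for k, f in enumerate(traj.frames, start=1):
        frame_atoms = [
            AtomRecord(index=a.index, name=a.name, element=a.element,
                       molecule_id=a.molecule_id, residue_name=a.residue_name,
                       position=p)
            for a, p in zip(atoms, f.positions)
        ]
        body = _pdb_text(frame_atoms, f.box).replace("END\n", "")
        chunks.append(f"MODEL     {k:4d}\nREMARK t= {f.time:.6f} ps\n{body}ENDMDL")
    path.write_text("\n".join(chunks) + "\nEND\n")


def _read_multi_pdb(path: Path) -> Trajectory:
    text = path.read_text()
    frames = []
    for k, block in enumerate(text.split("MODEL")[1:]):
        block = block.split("ENDMDL")[0]
        t = float(k)
        for line in block.splitlines():
            if line.startswith("REMARK t="):
                t = float(line.split("t=")[1].split()[0])
                break
        atoms, box = parse_pdb_lines(block.splitlines(), label=f"{path}#model{k + 1}")
        if not atoms:
            raise StructureParseError(f"{path}: MODEL {k + 1} has no atoms")
        frames.append(
            Frame(time=t, positions=np.array([a.position for a in atoms]), box=box)
        )
    if not frames:
        raise StructureParseError(f"{path}: no MODEL blocks found")
    return Trajectory(frames)
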