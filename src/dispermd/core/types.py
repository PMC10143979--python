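"""Core domain types: atoms, boxes, frames, trajectories, group selections."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AtomRecord",
    "SimulationBox",
    "Frame",
    "Trajectory",
    "GroupSelection",
]


@dataclass
class AtomRecord:
    """Identity of one atom.  Positions are in nm; ``index`` is 0-based."""

    index: int
    name: str
    element: str
    molecule_id: int
    residue_name: str
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"position must be length-3, got {self.position.shape}")
        if not self.element:
            raise ValueError(f"atom {self.index}: element must be non-empty")


class SimulationBox:
    """Periodic simulation cell.

    Stored as a 3×3 matrix of lattice vectors in nm (rows a, b, c).
    Construction from lattice parameters uses the standard crystallographic
    convention: a along x, b in the xy-plane — so the matrix is lower
    triangular and the parameter↔vector conversion is a bijection up to
    rigid rotation.
    """

    def __init__(self, lattice_vectors: np.ndarray):
        h = np.asarray(lattice_vectors, dtype=float)
        if h.shape != (3, 3):
            raise ValueError("lattice_vectors must be a 3x3 matrix")
        if not np.all(np.isfinite(h)):
            raise ValueError("lattice_vectors must be finite")
        if abs(np.linalg.det(h)) <= 0.0:
            raise ValueError("box volume must be positive")
        self.lattice_vectors = h

    # -- constructors -------------------------------------------------

    @classmethod
    def cubic(cls, edge_nm: float) -> "SimulationBox":
        return cls(np.eye(3) * float(edge_nm))

    @classmethod
    def orthorhombic(cls, lx: float, ly: float, lz: float) -> "SimulationBox":
        return cls(np.diag([float(lx), float(ly), float(lz)]))

    @classmethod
    def from_parameters(
        cls,
        a: float,
        b: float,
        c: float,
        alpha: float = 90.0,
        beta: float = 90.0,
        gamma: float = 90.0,
    ) -> "SimulationBox":
        """Build from lengths (nm) and angles (degrees)."""
        al, be, ga = (math.radians(x) for x in (alpha, beta, gamma))
        cos_al, cos_be, cos_ga = math.cos(al), math.cos(be), math.cos(ga)
        sin_ga = math.sin(ga)
        v1 = [a, 0.0, 0.0]
        v2 = [b * cos_ga, b * sin_ga, 0.0]
        cx = c * cos_be
        cy = c * (cos_al - cos_be * cos_ga) / sin_ga
        cz_sq = c * c - cx * cx - cy * cy
        if cz_sq <= 0.0:
            raise ValueError("degenerate cell: angles incompatible with positive volume")
        v3 = [cx, cy, math.sqrt(cz_sq)]
        return cls(np.array([v1, v2, v3]))

    # -- derived quantities -------------------------------------------

    @property
    def volume(self) -> float:
        """Cell volume in nm³."""
        return float(abs(np.linalg.det(self.lattice_vectors)))

    @property
    def lengths(self) -> np.ndarray:
        """Lattice lengths a, b, c in nm."""
        return np.linalg.norm(self.lattice_vectors, axis=1)

    @property
    def angles(self) -> np.ndarray:
        """Lattice angles α, β, γ in degrees."""
        va, vb, vc = self.lattice_vectors
        la, lb, lc = self.lengths

        def ang(u, v, lu, lv):
            return math.degrees(math.acos(np.clip(np.dot(u, v) / (lu * lv), -1.0, 1.0)))

        return np.array([ang(vb, vc, lb, lc), ang(va, vc, la, lc), ang(va, vb, la, lb)])

    @property
    def parameters(self) -> tuple[float, float, float, float, float, float]:
        """(a, b, c, α, β, γ) in nm / degrees."""
        la, lb, lc = self.lengths
        al, be, ga = self.angles
        return (float(la), float(lb), float(lc), float(al), float(be), float(ga))

    @property
    def is_orthorhombic(self) -> bool:
        h = self.lattice_vectors
        off = h - np.diag(np.diag(h))
        return bool(np.allclose(off, 0.0, atol=1e-12))

    def min_half_extent(self) -> float:
        """Half the smallest perpendicular width, the minimum-image radius."""
        h = self.lattice_vectors
        v = self.volume
        widths = []
        for i in range(3):
            j, k = (i + 1) % 3, (i + 2) % 3
            cross = np.cross(h[j], h[k])
            widths.append(v / np.linalg.norm(cross))
        return 0.5 * min(widths)

    # -- periodic geometry --------------------------------------------

    def minimum_image(self, dr: np.ndarray) -> np.ndarray:
        """Apply the minimum-image convention to displacement vectors."""
        dr = np.asarray(dr, dtype=float)
        h = self.lattice_vectors
        s = dr @ np.linalg.inv(h)
        s -= np.round(s)
        return s @ h

    def wrap(self, positions: np.ndarray) -> np.ndarray:
        """Wrap positions into the primary cell (fractional coords in [0,1))."""
        h = self.lattice_vectors
        s = np.asarray(positions, dtype=float) @ np.linalg.inv(h)
        s -= np.floor(s)
        return s @ h

    def scaled(self, factors) -> "SimulationBox":
        """Scale lattice vectors row-wise by (fa, fb, fc)."""
        f = np.asarray(factors, dtype=float).reshape(3, 1)
        return SimulationBox(self.lattice_vectors * f)

    def __eq__(self, other) -> bool:
        return isinstance(other, SimulationBox) and np.array_equal(
            self.lattice_vectors, other.lattice_vectors
        )

    def __repr__(self) -> str:
        a, b, c, al, be, ga = self.parameters
        return (
            f"SimulationBox(a={a:.4f}, b={b:.4f}, c={c:.4f} nm, "
            f"angles=({al:.2f}, {be:.2f}, {ga:.2f})°)"
        )


@dataclass
class Frame:
    """One snapshot: time (ps), positions (N×3 nm), optional velocities (nm/ps)."""

    time: float
    positions: np.ndarray
    box: SimulationBox | None = None
    velocities: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be N×3")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.positions.shape:
                raise ValueError("velocities must match positions shape")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "Frame":
        return Frame(
            time=self.time,
            positions=self.positions.copy(),
            box=self.box,
            velocities=None if self.velocities is None else self.velocities.copy(),
        )


class Trajectory:
    """Ordered sequence of frames with strictly increasing times."""

    def __init__(self, frames: list[Frame]):
        if not frames:
            raise ValueError("trajectory must contain at least one frame")
        n = frames[0].n_atoms
        for f in frames:
            if f.n_atoms != n:
                raise ValueError(
                    f"inconsistent atom count across frames: {f.n_atoms} != {n}"
                )
        times = [f.time for f in frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")
        self.frames = list(frames)

    @property
    def n_atoms(self) -> int:
        return self.frames[0].n_atoms

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def frame_interval(self) -> float:
        """Median spacing between consecutive frames, ps (0 for single frame)."""
        t = self.times
        if len(t) < 2:
            return 0.0
        return float(np.median(np.diff(t)))

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i) -> Frame:
        return self.frames[i]

    def window(self, t_start: float, t_end: float) -> "Trajectory":
        """Sub-trajectory with t_start ≤ t ≤ t_end (inclusive)."""
        sel = [f for f in self.frames if t_start <= f.time <= t_end]
        if not sel:
            raise ValueError(
                f"empty analysis window [{t_start}, {t_end}] ps for trajectory "
                f"spanning [{self.frames[0].time}, {self.frames[-1].time}] ps"
            )
        return Trajectory(sel)


@dataclass
class GroupSelection:
    """A named set of atoms (and the molecules they belong to)."""

    label: str
    atom_indices: frozenset[int] = field(default_factory=frozenset)
    molecule_ids: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.atom_indices = frozenset(int(i) for i in self.atom_indices)
        self.molecule_ids = frozenset(int(i) for i in self.molecule_ids)

    @property
    def indices(self) -> np.ndarray:
        """Sorted atom indices as an int array."""
        return np.array(sorted(self.atom_indices), dtype=np.intp)

    def __len__(self) -> int:
        return len(self.atom_indices)

    def isdisjoint(self, other: "GroupSelection") -> bool:
        return self.atom_indices.isdisjoint(other.atom_indices)
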