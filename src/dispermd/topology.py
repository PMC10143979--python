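"""System topology: per-atom nonbonded parameters, bonded terms, exclusions.

The text topology format is a small, documented section-based grammar
(see :func:`read_topology` / :func:`write_topology`)::

    [meta]
    name MOLNAME
    resname RES
    # optional polymerisation metadata (atom names):
    head ATOM  tail ATOM  head_cap ATOM  tail_cap ATOM

    [defaults]
    fudge_lj 0.5
    fudge_coul 0.5

    [atoms]
    ; name  element  charge(e)  sigma(nm)  epsilon(kJ/mol)  mass(amu)  [flags]
    C1  C  -0.10  0.350  0.276  12.011
    O1  O  -0.40  0.296  0.878  15.999  acceptor

    [bonds]
    ; i  j  r0(nm)  k(kJ/mol/nm^2)      (0-based indices)
    0 1 0.123 250000.0

    [angles]
    ; i  j  k  theta0(deg)  ktheta(kJ/mol/rad^2)

    [dihedrals]
    ; i  j  k  l  phi0(deg)  kphi(kJ/mol)  multiplicity

    [pairs14]
    ; i  j          (scaled 1-4 pairs)

    [coords]
    ; x y z (nm), one line per atom, same order as [atoms]

Angles are stored internally in radians; files use degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["SystemTopology", "read_topology", "write_topology", "TopologyError"]

ACCEPTOR_ELEMENTS = {"O", "N"}


class TopologyError(ValueError):
    pass


def _as2d(arr, width, dtype=float) -> np.ndarray:
    a = np.asarray(arr, dtype=dtype)
    if a.size == 0:
        return np.zeros((0, width), dtype=dtype)
    return a.reshape(-1, width)


@dataclass
class SystemTopology:
    """Full parameterization of a system (or single molecule template).

    Bonded indices are 0-based.  ``molecule_ids`` partitions atoms into
    molecules; exclusions (1-2, 1-3) are derived from the bond graph and
    1-4 pairs are scaled by ``fudge_lj`` / ``fudge_coul``.
    """

    names: list[str]
    elements: list[str]
    charges: np.ndarray          # e
    sigmas: np.ndarray           # nm
    epsilons: np.ndarray         # kJ/mol
    masses: np.ndarray           # amu
    molecule_ids: np.ndarray = None
    residue_names: list[str] = None

    bonds: np.ndarray = None         # (nb, 2) int
    bond_r0: np.ndarray = None       # nm
    bond_k: np.ndarray = None        # kJ/mol/nm^2
    angles: np.ndarray = None        # (na, 3) int
    angle_theta0: np.ndarray = None  # rad
    angle_k: np.ndarray = None       # kJ/mol/rad^2
    dihedrals: np.ndarray = None     # (nd, 4) int
    dihedral_phi0: np.ndarray = None  # rad
    dihedral_k: np.ndarray = None     # kJ/mol
    dihedral_mult: np.ndarray = None  # int
    pairs14: np.ndarray = None        # (n14, 2) int

    fudge_lj: float = 0.5
    fudge_coul: float = 0.5

    donor_flags: np.ndarray = None     # per-atom override: H atoms that donate
    acceptor_flags: np.ndarray = None  # per-atom override: acceptor heavy atoms

    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.names)
        self.charges = np.asarray(self.charges, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        self.epsilons = np.asarray(self.epsilons, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        for label, arr in (
            ("charges", self.charges),
            ("sigmas", self.sigmas),
            ("epsilons", self.epsilons),
            ("masses", self.masses),
        ):
            if arr.shape != (n,):
                raise TopologyError(f"{label} must have length {n}")
        if np.any(self.sigmas <= 0):
            raise TopologyError("all sigma values must be > 0")
        if np.any(self.epsilons < 0):
            raise TopologyError("all epsilon values must be >= 0")
        if not np.all(np.isfinite(self.charges)):
            raise TopologyError("charges must be finite")
        if len(self.elements) != n:
            raise TopologyError("elements must match atom count")
        if any(not e for e in self.elements):
            raise TopologyError("every atom needs a non-empty element")

        if self.molecule_ids is None:
            self.molecule_ids = np.zeros(n, dtype=int)
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=int)
        if self.residue_names is None:
            self.residue_names = ["MOL"] * n

        self.bonds = _as2d(self.bonds if self.bonds is not None else [], 2, int)
        self.bond_r0 = np.asarray(
            self.bond_r0 if self.bond_r0 is not None else [], dtype=float
        )
        self.bond_k = np.asarray(
            self.bond_k if self.bond_k is not None else [], dtype=float
        )
        self.angles = _as2d(self.angles if self.angles is not None else [], 3, int)
        self.angle_theta0 = np.asarray(
            self.angle_theta0 if self.angle_theta0 is not None else [], dtype=float
        )
        self.angle_k = np.asarray(
            self.angle_k if self.angle_k is not None else [], dtype=float
        )
        self.dihedrals = _as2d(
            self.dihedrals if self.dihedrals is not None else [], 4, int
        )
        self.dihedral_phi0 = np.asarray(
            self.dihedral_phi0 if self.dihedral_phi0 is not None else [], dtype=float
        )
        self.dihedral_k = np.asarray(
            self.dihedral_k if self.dihedral_k is not None else [], dtype=float
        )
        self.dihedral_mult = np.asarray(
            self.dihedral_mult if self.dihedral_mult is not None else [], dtype=int
        )
        self.pairs14 = _as2d(self.pairs14 if self.pairs14 is not None else [], 2, int)

        for idx, label in (
            (self.bonds, "bond"),
            (self.angles, "angle"),
            (self.dihedrals, "dihedral"),
            (self.pairs14, "pairs14"),
        ):
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise TopologyError(f"{label} indices out of range")
        if np.any(self.bond_r0 < 0) or np.any(self.bond_k < 0):
            raise TopologyError("bond r0 and k must be >= 0")
        if not (0.0 <= self.fudge_lj <= 1.0 and 0.0 <= self.fudge_coul <= 1.0):
            raise TopologyError("1-4 scale factors must lie in [0, 1]")

        net = float(self.charges.sum())
        if abs(net) > 1e-6:
            warnings.warn(
                f"system net charge is {net:+.4f} e (non-zero)", stacklevel=2
            )

    # ------------------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def molar_mass(self) -> float:
        """Total mass, amu (= g/mol)."""
        return float(self.masses.sum())

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())

    def bonded_neighbors(self) -> list[set[int]]:
        adj: list[set[int]] = [set() for _ in range(self.n_atoms)]
        for i, j in self.bonds:
            adj[i].add(int(j))
            adj[j].add(int(i))
        return adj

    def exclusions(self) -> set[tuple[int, int]]:
        """Symmetric 1-2 and 1-3 excluded pairs, stored as (min, max)."""
        adj = self.bonded_neighbors()
        excl: set[tuple[int, int]] = set()
        for i, j in self.bonds:
            excl.add((min(i, j), max(i, j)))
        for j, nbrs in enumerate(adj):
            for i in nbrs:
                for k in nbrs:
                    if i < k:
                        excl.add((i, k))
        return excl

    def scaled_pairs(self) -> set[tuple[int, int]]:
        """1-4 pairs as (min, max) tuples, excluding anything also 1-2/1-3."""
        excl = self.exclusions()
        return {
            (min(i, j), max(i, j))
            for i, j in self.pairs14
            if (min(i, j), max(i, j)) not in excl
        }

    def donor_hydrogens(self) -> np.ndarray:
        """Indices of hydrogens bonded to O or N (or flagged explicitly)."""
        if self.donor_flags is not None:
            return np.flatnonzero(np.asarray(self.donor_flags, dtype=bool))
        adj = self.bonded_neighbors()
        out = []
        for i, el in enumerate(self.elements):
            if el.upper() != "H":
                continue
            if any(self.elements[j].upper() in ACCEPTOR_ELEMENTS for j in adj[i]):
                out.append(i)
        return np.array(out, dtype=np.intp)

    def acceptor_atoms(self) -> np.ndarray:
        """Indices of acceptor heavy atoms (O and N, or flagged explicitly)."""
        if self.acceptor_flags is not None:
            return np.flatnonzero(np.asarray(self.acceptor_flags, dtype=bool))
        return np.array(
            [i for i, el in enumerate(self.elements) if el.upper() in ACCEPTOR_ELEMENTS],
            dtype=np.intp,
        )

    def molecule_atom_lists(self) -> dict[int, np.ndarray]:
        """Map molecule_id -> sorted atom index array."""
        out: dict[int, list[int]] = {}
        for i, m in enumerate(self.molecule_ids):
            out.setdefault(int(m), []).append(i)
        return {m: np.array(v, dtype=np.intp) for m, v in out.items()}


# ----------------------------------------------------------------------
# Text format
# ----------------------------------------------------------------------

_SECTIONS = {
    "meta", "defaults", "atoms", "bonds", "angles", "dihedrals", "pairs14",
    "molecules", "coords",
}


def read_topology(path) -> tuple[SystemTopology, np.ndarray | None]:
    """Parse a topology file.  Returns (topology, coords-or-None)."""
    path = Path(path)
    section = None
    meta: dict = {}
    defaults = {"fudge_lj": 0.5, "fudge_coul": 0.5}
    atoms: list[tuple] = []
    bonds, angles, dihedrals, pairs14, coords = [], [], [], [], []
    molecules: list[tuple[int, str]] = []

    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split(";")[0].split("#")[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1].strip().lower()
            if section not in _SECTIONS:
                raise TopologyError(f"{path}:{lineno}: unknown section [{section}]")
            continue
        try:
            if section == "meta":
                key, _, val = line.partition(" ")
                meta[key.strip()] = val.strip()
            elif section == "defaults":
                key, _, val = line.partition(" ")
                defaults[key.strip()] = float(val)
            elif section == "atoms":
                parts = line.split()
                name, element = parts[0], parts[1]
                charge, sigma, epsilon, mass = map(float, parts[2:6])
                flags = set(p.lower() for p in parts[6:])
                atoms.append((name, element, charge, sigma, epsilon, mass, flags))
            elif section == "bonds":
                i, j, r0, k = line.split()
                bonds.append((int(i), int(j), float(r0), float(k)))
            elif section == "angles":
                i, j, k, th0, kth = line.split()
                angles.append((int(i), int(j), int(k), float(th0), float(kth)))
            elif section == "dihedrals":
                i, j, k, l, ph0, kph, mult = line.split()
                dihedrals.append(
                    (int(i), int(j), int(k), int(l), float(ph0), float(kph), int(mult))
                )
            elif section == "pairs14":
                i, j = line.split()
                pairs14.append((int(i), int(j)))
            elif section == "molecules":
                mid, res = line.split()
                molecules.append((int(mid), res))
            elif section == "coords":
                x, y, z = map(float, line.split())
                coords.append((x, y, z))
            else:
                raise TopologyError("content outside any section")
        except TopologyError:
            raise
        except Exception as exc:
            raise TopologyError(f"{path}:{lineno}: malformed line {line!r}: {exc}")

    if not atoms:
        raise TopologyError(f"{path}: no [atoms] section")
    if molecules and len(molecules) != len(atoms):
        raise TopologyError(
            f"{path}: [molecules] has {len(molecules)} rows for {len(atoms)} atoms"
        )
    resname = meta.get("resname", "MOL")
    top = SystemTopology(
        names=[a[0] for a in atoms],
        elements=[a[1] for a in atoms],
        charges=[a[2] for a in atoms],
        sigmas=[a[3] for a in atoms],
        epsilons=[a[4] for a in atoms],
        masses=[a[5] for a in atoms],
        residue_names=[resname] * len(atoms),
        bonds=[b[:2] for b in bonds],
        bond_r0=[b[2] for b in bonds],
        bond_k=[b[3] for b in bonds],
        angles=[a[:3] for a in angles],
        angle_theta0=np.radians([a[3] for a in angles]),
        angle_k=[a[4] for a in angles],
        dihedrals=[d[:4] for d in dihedrals],
        dihedral_phi0=np.radians([d[4] for d in dihedrals]),
        dihedral_k=[d[5] for d in dihedrals],
        dihedral_mult=[d[6] for d in dihedrals],
        pairs14=pairs14,
        fudge_lj=defaults["fudge_lj"],
        fudge_coul=defaults["fudge_coul"],
        meta=meta,
    )
    if molecules:
        top.molecule_ids = np.array([m[0] for m in molecules], dtype=int)
        top.residue_names = [m[1] for m in molecules]
    flag_sets = [a[6] for a in atoms]
    if any("donor" in f for f in flag_sets):
        top.donor_flags = np.array(["donor" in f for f in flag_sets])
    if any("acceptor" in f for f in flag_sets):
        top.acceptor_flags = np.array(["acceptor" in f for f in flag_sets])

    xyz = np.asarray(coords, dtype=float) if coords else None
    if xyz is not None and xyz.shape != (top.n_atoms, 3):
        raise TopologyError(
            f"{path}: [coords] has {len(coords)} rows for {top.n_atoms} atoms"
        )
    return top, xyz


def write_topology(top: SystemTopology, path, coords: np.ndarray | None = None) -> None:
    lines = []
    if top.meta:
        lines.append("[meta]")
        lines += [f"{k} {v}" for k, v in top.meta.items()]
        lines.append("")
    lines += [
        "[defaults]",
        f"fudge_lj {top.fudge_lj}",
        f"fudge_coul {top.fudge_coul}",
        "",
        "[atoms]",
    ]
    for i in range(top.n_atoms):
        flags = []
        if top.donor_flags is not None and top.donor_flags[i]:
            flags.append("donor")
        if top.acceptor_flags is not None and top.acceptor_flags[i]:
            flags.append("acceptor")
        lines.append(
            f"{top.names[i]} {top.elements[i]} {top.charges[i]:.6f} "
            f"{top.sigmas[i]:.6f} {top.epsilons[i]:.6f} {top.masses[i]:.6f}"
            + ("".join(" " + f for f in flags))
        )
    lines += ["", "[bonds]"]
    for (i, j), r0, k in zip(top.bonds, top.bond_r0, top.bond_k):
        lines.append(f"{i} {j} {r0:.6f} {k:.3f}")
    lines += ["", "[angles]"]
    for (i, j, k), th0, kth in zip(top.angles, top.angle_theta0, top.angle_k):
        lines.append(f"{i} {j} {k} {np.degrees(th0):.4f} {kth:.3f}")
    lines += ["", "[dihedrals]"]
    for (i, j, k, l), ph0, kph, mult in zip(
        top.dihedrals, top.dihedral_phi0, top.dihedral_k, top.dihedral_mult
    ):
        lines.append(f"{i} {j} {k} {l} {np.degrees(ph0):.4f} {kph:.4f} {mult}")
    lines += ["", "[pairs14]"]
    for i, j in top.pairs14:
        lines.append(f"{i} {j}")
    if len(set(top.residue_names)) > 1 or len(np.unique(top.molecule_ids)) > 1:
        lines += ["", "[molecules]"]
        for mid, res in zip(top.molecule_ids, top.residue_names):
            lines.append(f"{mid} {res}")
    if coords is not None:
        lines += ["", "[coords]"]
        for x, y, z in np.asarray(coords, dtype=float):
            lines.append(f"{x:.9f} {y:.9f} {z:.9f}")
    Path(path).write_text("\n".join(lines) + "\n")
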