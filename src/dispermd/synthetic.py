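"""Synthetic toy systems: API and excipient-monomer archetypes, 10-unit
polymer chains, randomly packed mixture boxes at a target wt%, and
replicated crystal supercells.

The molecule templates are coarse, chemically plausible stand-ins — NOT
parameterizations of any real drug or polymer.  Four API archetypes are
shipped (neutral-aromatic, ion-pair with a monovalent counter-ion,
small-neutral ester, hydroxyl-donor-rich) and three excipient monomer
archetypes (hydroxyl/ester, carboxylic-acid, aromatic-ester).  Bonded
equilibrium values (r0, θ0) are taken from each template's drawn
geometry, so every template starts at its own bonded minimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core.types import Frame, SimulationBox
from .topology import SystemTopology
from .units import G_PER_MOL_PER_A3_TO_G_PER_CC

__all__ = [
    "MoleculeTemplate",
    "UnitCellSpec",
    "CellAtom",
    "get_template",
    "list_templates",
    "build_polymer_chain",
    "build_mixture_box",
    "build_supercell",
    "cell_density",
    "lj_fluid",
    "lj_fcc_cell",
    "combine_topologies",
]

# Toy atom-type library: (element, sigma nm, epsilon kJ/mol, mass amu)
ATOM_TYPES = {
    "C": ("C", 0.350, 0.276, 12.011),
    "CA": ("C", 0.355, 0.293, 12.011),
    "O": ("O", 0.296, 0.878, 15.999),   # carbonyl
    "OS": ("O", 0.300, 0.711, 15.999),  # ether / ester
    "OH": ("O", 0.312, 0.711, 15.999),  # hydroxyl
    "N": ("N", 0.325, 0.711, 14.007),
    "H": ("H", 0.242, 0.126, 1.008),    # nonpolar H
    "HO": ("H", 0.120, 0.065, 1.008),   # polar H (donor)
    "NA": ("Na", 0.333, 0.0116, 22.990),
}

BOND_K = 30_000.0    # kJ/mol/nm^2
ANGLE_K = 300.0      # kJ/mol/rad^2
JUNCTION_BOND_R0 = 0.153  # nm, C–C across monomer junctions


@dataclass
class MoleculeTemplate:
    """One molecule: topology + reference coordinates + link metadata."""

    name: str
    resname: str
    topology: SystemTopology
    coords: np.ndarray
    head: str | None = None       # atom names for polymerisation
    tail: str | None = None
    head_cap: str | None = None
    tail_cap: str | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.topology.n_atoms, 3):
            raise ValueError("coords must match topology atom count")

    @property
    def molar_mass(self) -> float:
        return self.topology.molar_mass

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    def atom_index(self, name: str) -> int:
        return self.topology.names.index(name)

    @property
    def donor_hydrogens(self) -> np.ndarray:
        return self.topology.donor_hydrogens()

    @property
    def acceptor_atoms(self) -> np.ndarray:
        return self.topology.acceptor_atoms()


# ----------------------------------------------------------------------
# Template construction helpers
# ----------------------------------------------------------------------

def _derive_bonded(names, coords, bonds):
    """Equilibrium bond lengths/angles from geometry; 1-4 pairs from the
    graph (exact distance 3)."""
    n = len(names)
    coords = np.asarray(coords, dtype=float)
    adj = [set() for _ in range(n)]
    for i, j in bonds:
        adj[i].add(j)
        adj[j].add(i)
    bond_r0 = [float(np.linalg.norm(coords[j] - coords[i])) for i, j in bonds]
    angles, theta0 = [], []
    for j in range(n):
        nbrs = sorted(adj[j])
        for x in range(len(nbrs)):
            for y in range(x + 1, len(nbrs)):
                i, k = nbrs[x], nbrs[y]
                v1 = coords[i] - coords[j]
                v2 = coords[k] - coords[j]
                cos_t = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angles.append((i, j, k))
                theta0.append(math.acos(float(np.clip(cos_t, -1, 1))))
    # graph distances for 1-4 pairs
    pairs14 = []
    for s in range(n):
        dist = {s: 0}
        frontier = [s]
        for d in (1, 2, 3):
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = d
                        nxt.append(v)
            frontier = nxt
        for v, d in dist.items():
            if d == 3 and s < v:
                pairs14.append((s, v))
    return bond_r0, angles, theta0, pairs14


def _make_template(name, resname, atom_spec, bonds, head=None, tail=None,
                   head_cap=None, tail_cap=None):
    """atom_spec: list of (atom_name, type_key, charge, (x, y, z))."""
    names = [a[0] for a in atom_spec]
    coords = np.array([a[3] for a in atom_spec], dtype=float)
    elements, sigmas, epsilons, masses = [], [], [], []
    for _, tkey, _, _ in atom_spec:
        el, sig, eps, m = ATOM_TYPES[tkey]
        elements.append(el)
        sigmas.append(sig)
        epsilons.append(eps)
        masses.append(m)
    charges = [a[2] for a in atom_spec]
    bond_r0, angles, theta0, pairs14 = _derive_bonded(names, coords, bonds)
    top = SystemTopology(
        names=names, elements=elements, charges=charges, sigmas=sigmas,
        epsilons=epsilons, masses=masses,
        residue_names=[resname] * len(names),
        bonds=bonds, bond_r0=bond_r0, bond_k=[BOND_K] * len(bonds),
        angles=angles, angle_theta0=theta0, angle_k=[ANGLE_K] * len(angles),
        pairs14=pairs14,
        meta={"name": name, "resname": resname},
    )
    if head:
        top.meta.update(head=head, tail=tail, head_cap=head_cap, tail_cap=tail_cap)
    return MoleculeTemplate(
        name=name, resname=resname, topology=top, coords=coords,
        head=head, tail=tail, head_cap=head_cap, tail_cap=tail_cap,
    )


def _api_small_neutral():
    # symmetric diester: two -C(=O)-O-C groups on an unsaturated C2 core
    spec = [
        ("C3", "C", 0.00, (0.00, 0.00, 0.00)),
        ("C4", "C", 0.00, (0.14, 0.00, 0.00)),
        ("C1", "C", 0.45, (-0.09, 0.12, 0.00)),
        ("O1", "O", -0.40, (-0.04, 0.23, 0.03)),
        ("O2", "OS", -0.33, (-0.23, 0.12, -0.03)),
        ("C2", "C", 0.28, (-0.31, 0.24, -0.03)),
        ("C5", "C", 0.45, (0.23, -0.12, 0.00)),
        ("O3", "O", -0.40, (0.18, -0.23, -0.03)),
        ("O4", "OS", -0.33, (0.37, -0.12, 0.03)),
        ("C6", "C", 0.28, (0.45, -0.24, 0.03)),
    ]
    bonds = [(0, 1), (0, 2), (2, 3), (2, 4), (4, 5), (1, 6), (6, 7), (6, 8), (8, 9)]
    return _make_template("api_small_neutral", "SMN", spec, bonds)


def _api_neutral_aromatic():
    ring = []
    for k in range(6):
        ang = math.radians(60 * k)
        ring.append((f"CA{k + 1}", "CA", 0.0,
                     (0.14 * math.cos(ang), 0.14 * math.sin(ang), 0.0)))
    spec = ring + [
        ("O5", "OS", -0.285, (0.27, 0.00, 0.02)),
        ("C7", "C", 0.285, (0.34, 0.12, 0.02)),
        ("C8", "C", 0.52, (-0.28, 0.00, 0.00)),
        ("O6", "O", -0.44, (-0.33, 0.115, 0.00)),
        ("O7", "OH", -0.53, (-0.36, -0.11, 0.00)),
        ("H8", "HO", 0.45, (-0.46, -0.10, 0.00)),
    ]
    bonds = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 0),
             (0, 6), (6, 7), (3, 8), (8, 9), (8, 10), (10, 11)]
    return _make_template("api_neutral_aromatic", "ARO", spec, bonds)


def _api_ion_pair():
    # carboxylate anion with an amine donor, plus an unbonded +1 counter-ion
    spec = [
        ("C1", "C", 0.00, (0.00, 0.00, 0.00)),
        ("C2", "C", 0.00, (0.15, 0.00, 0.00)),
        ("C3", "C", 0.00, (0.30, 0.00, 0.00)),
        ("N1", "N", -0.90, (-0.09, 0.11, 0.00)),
        ("H1", "HO", 0.40, (-0.19, 0.07, 0.00)),
        ("C4", "C", 0.90, (0.41, 0.10, 0.00)),
        ("O1", "O", -0.70, (0.40, 0.22, 0.03)),
        ("O2", "O", -0.70, (0.52, 0.05, -0.03)),
        ("NA", "NA", 1.00, (0.68, 0.16, 0.00)),
    ]
    bonds = [(0, 1), (1, 2), (2, 5), (5, 6), (5, 7), (0, 3), (3, 4)]
    return _make_template("api_ion_pair", "IOP", spec, bonds)


def _api_donor_rich():
    spec = [
        ("C0", "C", 0.00, (-0.15, -0.05, 0.00)),
        ("C1", "C", 0.15, (0.00, 0.00, 0.00)),
        ("C2", "C", 0.15, (0.15, -0.05, 0.03)),
        ("C3", "C", 0.15, (0.30, 0.00, 0.00)),
        ("O1", "OH", -0.58, (0.00, 0.14, 0.03)),
        ("H1", "HO", 0.43, (0.08, 0.19, 0.00)),
        ("O2", "OH", -0.58, (0.15, -0.19, -0.03)),
        ("H2", "HO", 0.43, (0.24, -0.23, 0.00)),
        ("O3", "OH", -0.58, (0.30, 0.14, 0.03)),
        ("H3", "HO", 0.43, (0.39, 0.19, 0.00)),
    ]
    bonds = [(0, 1), (1, 2), (2, 3), (1, 4), (4, 5), (2, 6), (6, 7), (3, 8), (8, 9)]
    return _make_template("api_donor_rich", "DNR", spec, bonds)


def _exc_ester():
    spec = [
        ("C1", "C", 0.15, (0.00, 0.00, 0.00)),
        ("C2", "C", 0.00, (0.15, 0.00, 0.00)),
        ("O3", "OH", -0.58, (0.00, 0.13, 0.05)),
        ("H1", "HO", 0.43, (0.08, 0.19, 0.05)),
        ("C3", "C", 0.45, (0.15, -0.14, 0.00)),
        ("O1", "O", -0.40, (0.05, -0.21, 0.00)),
        ("O2", "OS", -0.33, (0.27, -0.20, 0.00)),
        ("C4", "C", 0.28, (0.27, -0.34, 0.00)),
        ("HH", "H", 0.00, (-0.10, -0.04, -0.03)),
        ("HT", "H", 0.00, (0.25, 0.04, 0.06)),
    ]
    bonds = [(0, 1), (0, 2), (2, 3), (1, 4), (4, 5), (4, 6), (6, 7), (0, 8), (1, 9)]
    return _make_template("exc_ester", "EPE", spec, bonds,
                          head="C1", tail="C2", head_cap="HH", tail_cap="HT")


def _exc_acid():
    spec = [
        ("C1", "C", 0.00, (0.00, 0.00, 0.00)),
        ("C2", "C", 0.00, (0.15, 0.00, 0.00)),
        ("C3", "C", 0.00, (0.00, 0.14, -0.05)),
        ("C4", "C", 0.52, (0.15, -0.14, 0.00)),
        ("O1", "O", -0.44, (0.05, -0.22, 0.00)),
        ("O2", "OH", -0.53, (0.27, -0.21, 0.00)),
        ("H1", "HO", 0.45, (0.27, -0.31, 0.00)),
        ("HH", "H", 0.00, (-0.10, -0.04, 0.03)),
        ("HT", "H", 0.00, (0.25, 0.05, 0.03)),
    ]
    bonds = [(0, 1), (0, 2), (1, 3), (3, 4), (3, 5), (5, 6), (0, 7), (1, 8)]
    return _make_template("exc_acid", "EAC", spec, bonds,
                          head="C1", tail="C2", head_cap="HH", tail_cap="HT")


def _exc_aromatic():
    ring = []
    cx, cy = 0.25, -0.45
    for k in range(6):
        ang = math.radians(90 + 60 * k)
        ring.append((f"CA{k + 1}", "CA", 0.0,
                     (cx + 0.14 * math.cos(ang), cy + 0.14 * math.sin(ang), 0.0)))
    spec = [
        ("C1", "C", 0.00, (0.00, 0.00, 0.00)),
        ("C2", "C", 0.28, (0.15, 0.00, 0.00)),
        ("O2", "OS", -0.33, (0.15, -0.13, 0.00)),
        ("C3", "C", 0.45, (0.25, -0.21, 0.00)),
        ("O1", "O", -0.40, (0.37, -0.17, 0.00)),
    ] + ring + [
        ("C10", "C", 0.52, (0.25, -0.73, 0.00)),
        ("O3", "O", -0.44, (0.14, -0.80, 0.00)),
        ("O4", "OH", -0.53, (0.36, -0.79, 0.00)),
        ("H2", "HO", 0.45, (0.36, -0.89, 0.00)),
        ("HH", "H", 0.00, (-0.10, -0.04, 0.03)),
        ("HT", "H", 0.00, (0.25, 0.05, 0.03)),
    ]
    # ring atoms are indices 5..10; CA1 (index 5) sits at the ring top
    bonds = [(0, 1), (1, 2), (2, 3), (3, 4), (3, 5),
             (5, 6), (6, 7), (7, 8), (8, 9), (9, 10), (10, 5),
             (8, 11), (11, 12), (11, 13), (13, 14), (0, 15), (1, 16)]
    return _make_template("exc_aromatic", "EAR", spec, bonds,
                          head="C1", tail="C2", head_cap="HH", tail_cap="HT")


_TEMPLATE_BUILDERS = {
    "api_small_neutral": _api_small_neutral,
    "api_neutral_aromatic": _api_neutral_aromatic,
    "api_ion_pair": _api_ion_pair,
    "api_donor_rich": _api_donor_rich,
    "exc_ester": _exc_ester,
    "exc_acid": _exc_acid,
    "exc_aromatic": _exc_aromatic,
}


def list_templates() -> list[str]:
    return sorted(_TEMPLATE_BUILDERS)


def get_template(name: str) -> MoleculeTemplate:
    try:
        return _TEMPLATE_BUILDERS[name]()
    except KeyError:
        raise KeyError(
            f"unknown template {name!r}; available: {', '.join(list_templates())}"
        )


# ----------------------------------------------------------------------
# Polymerisation
# ----------------------------------------------------------------------

def build_polymer_chain(monomer: MoleculeTemplate, n_units: int) -> MoleculeTemplate:
    """Link ``n_units`` copies of a monomer head-to-tail.

    At each junction the left unit's tail cap and the right unit's head
    cap are removed and a C–C bond is formed; the chain molar mass is
    n·M_monomer − (n−1)·(m_head_cap + m_tail_cap).
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    if n_units == 1:
        return monomer
    for attr in ("head", "tail", "head_cap", "tail_cap"):
        if getattr(monomer, attr) is None:
            raise ValueError(f"monomer {monomer.name} lacks {attr} link metadata")

    mt = monomer.topology
    i_head = monomer.atom_index(monomer.head)
    i_tail = monomer.atom_index(monomer.tail)
    i_hcap = monomer.atom_index(monomer.head_cap)
    i_tcap = monomer.atom_index(monomer.tail_cap)

    names, elements, charges, sigmas, epsilons, masses = [], [], [], [], [], []
    coords_out, bonds, bond_r0 = [], [], []
    index_map: list[dict[int, int]] = []

    offset = np.zeros(3)
    tail_dir = monomer.coords[i_tcap] - monomer.coords[i_tail]
    tail_dir /= np.linalg.norm(tail_dir)

    for u in range(n_units):
        drop = set()
        if u > 0:
            drop.add(i_hcap)
        if u < n_units - 1:
            drop.add(i_tcap)
        local: dict[int, int] = {}
        for a in range(mt.n_atoms):
            if a in drop:
                continue
            local[a] = len(names)
            names.append(f"{mt.names[a]}{u + 1}")
            elements.append(mt.elements[a])
            charges.append(mt.charges[a])
            sigmas.append(mt.sigmas[a])
            epsilons.append(mt.epsilons[a])
            masses.append(mt.masses[a])
            coords_out.append(monomer.coords[a] + offset)
        index_map.append(local)
        for (i, j), r0 in zip(mt.bonds, mt.bond_r0):
            if i in drop or j in drop:
                continue
            bonds.append((local[i], local[j]))
            bond_r0.append(r0)
        if u > 0:
            prev = index_map[u - 1]
            bonds.append((prev[i_tail], local[i_head]))
            bond_r0.append(JUNCTION_BOND_R0)
        # place the next unit's head where this unit's extended tail points
        next_head_pos = (
            monomer.coords[i_tail] + offset + JUNCTION_BOND_R0 * tail_dir
        )
        offset = next_head_pos - monomer.coords[i_head]

    coords_out = np.asarray(coords_out)
    _, angles, theta0, pairs14 = _derive_bonded(
        names, coords_out, [tuple(b) for b in bonds]
    )
    top = SystemTopology(
        names=names, elements=elements, charges=charges, sigmas=sigmas,
        epsilons=epsilons, masses=masses,
        residue_names=[monomer.resname] * len(names),
        bonds=list(bonds), bond_r0=bond_r0, bond_k=[BOND_K] * len(bonds),
        angles=angles, angle_theta0=theta0, angle_k=[ANGLE_K] * len(angles),
        pairs14=pairs14,
        meta={"name": f"{monomer.name}_x{n_units}", "resname": monomer.resname},
    )
    return MoleculeTemplate(
        name=f"{monomer.name}_x{n_units}", resname=monomer.resname,
        topology=top, coords=coords_out,
    )


# ----------------------------------------------------------------------
# Topology concatenation & mixture packing
# ----------------------------------------------------------------------

def combine_topologies(parts: list[tuple[SystemTopology, np.ndarray]]):
    """Concatenate (topology, coords) parts into one system.

    Each part becomes one molecule (sequential molecule ids).
    Returns (SystemTopology, coords).
    """
    names, elements, charges, sigmas, epsilons, masses = [], [], [], [], [], []
    residues, mol_ids, coords = [], [], []
    bonds, bond_r0, bond_k = [], [], []
    angles, angle_theta0, angle_k = [], [], []
    dihedrals, dihedral_phi0, dihedral_k, dihedral_mult = [], [], [], []
    pairs14 = []
    donor_any, acceptor_any = [], []
    off = 0
    for mol_id, (t, xyz) in enumerate(parts):
        names += t.names
        elements += t.elements
        charges += list(t.charges)
        sigmas += list(t.sigmas)
        epsilons += list(t.epsilons)
        masses += list(t.masses)
        residues += t.residue_names
        mol_ids += [mol_id] * t.n_atoms
        coords.append(np.asarray(xyz, dtype=float))
        bonds += [(i + off, j + off) for i, j in t.bonds]
        bond_r0 += list(t.bond_r0)
        bond_k += list(t.bond_k)
        angles += [(i + off, j + off, k + off) for i, j, k in t.angles]
        angle_theta0 += list(t.angle_theta0)
        angle_k += list(t.angle_k)
        dihedrals += [(i + off, j + off, k + off, l + off) for i, j, k, l in t.dihedrals]
        dihedral_phi0 += list(t.dihedral_phi0)
        dihedral_k += list(t.dihedral_k)
        dihedral_mult += list(t.dihedral_mult)
        pairs14 += [(i + off, j + off) for i, j in t.pairs14]
        d = t.donor_flags if t.donor_flags is not None else np.zeros(t.n_atoms, bool)
        a = (t.acceptor_flags if t.acceptor_flags is not None
             else np.zeros(t.n_atoms, bool))
        donor_any += list(np.asarray(d, bool))
        acceptor_any += list(np.asarray(a, bool))
        off += t.n_atoms
    top = SystemTopology(
        names=names, elements=elements, charges=charges, sigmas=sigmas,
        epsilons=epsilons, masses=masses, molecule_ids=mol_ids,
        residue_names=residues,
        bonds=bonds, bond_r0=bond_r0, bond_k=bond_k,
        angles=angles, angle_theta0=angle_theta0, angle_k=angle_k,
        dihedrals=dihedrals, dihedral_phi0=dihedral_phi0,
        dihedral_k=dihedral_k, dihedral_mult=dihedral_mult,
        pairs14=pairs14,
    )
    if any(donor_any):
        top.donor_flags = np.array(donor_any)
    if any(acceptor_any):
        top.acceptor_flags = np.array(acceptor_any)
    return top, np.vstack(coords)


def polymer_chain_count(n_api: int, m_api: float, m_chain: float,
                        target_wt_percent: float) -> int:
    """Chains needed so that API mass fraction ≈ target:
    round(n_api·M_api·(100 − w) / (w·M_chain))."""
    if not (0 < target_wt_percent < 100):
        raise ValueError("target_wt_percent must be in (0, 100)")
    n = int(round(n_api * m_api * (100.0 - target_wt_percent)
                  / (target_wt_percent * m_chain)))
    if n < 1:
        raise ValueError(
            f"target {target_wt_percent} wt% unreachable: chain count rounds to 0"
        )
    return n


def _random_rotation(rng) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def build_mixture_box(
    api: MoleculeTemplate,
    n_api: int,
    polymer: MoleculeTemplate,
    target_wt_percent: float,
    box_edge: float | None = None,
    density: float | None = None,
    seed: int = 0,
    clash_distance: float = 0.2,
    max_tries: int = 5000,
):
    """Randomly pack ``n_api`` APIs plus enough polymer chains for the
    target wt% into a cubic box.

    Either ``box_edge`` (nm) or a target mass ``density`` (g/cc) must be
    given.  Insertion is seeded rejection sampling: random rotation +
    translation, rejected if any heavy-atom pair comes within
    ``clash_distance`` (nm, default 2 Å) of an already-placed atom under
    the minimum image.  Returns (topology, frame, info dict).
    """
    n_chains = polymer_chain_count(
        n_api, api.molar_mass, polymer.molar_mass, target_wt_percent
    )
    total_mass = n_api * api.molar_mass + n_chains * polymer.molar_mass
    if box_edge is None:
        if density is None:
            raise ValueError("give either box_edge or density")
        volume = (total_mass / 602.214076) / density  # nm^3
        box_edge = volume ** (1.0 / 3.0)
    box = SimulationBox.cubic(box_edge)

    rng = np.random.default_rng(seed)
    placed_heavy: list[np.ndarray] = []
    parts = []

    def try_insert(tmpl: MoleculeTemplate):
        heavy = np.array(
            [e.upper() != "H" for e in tmpl.topology.elements], dtype=bool
        )
        centered = tmpl.coords - tmpl.coords.mean(axis=0)
        for _ in range(max_tries):
            rot = _random_rotation(rng)
            shift = rng.uniform(0.0, box_edge, 3)
            xyz = centered @ rot.T + shift
            hv = xyz[heavy]
            ok = True
            for other in placed_heavy:
                dr = hv[:, None, :] - other[None, :, :]
                dr -= box_edge * np.round(dr / box_edge)
                if np.min(np.einsum("ijk,ijk->ij", dr, dr)) < clash_distance**2:
                    ok = False
                    break
            if ok:
                placed_heavy.append(hv)
                parts.append((tmpl.topology, xyz))
                return
        raise RuntimeError(
            f"could not insert {tmpl.name} after {max_tries} tries; "
            f"box {box_edge:.2f} nm is too dense"
        )

    # big molecules first for packing success; APIs afterwards
    for _ in range(n_chains):
        try_insert(polymer)
    for _ in range(n_api):
        try_insert(api)

    top, coords = combine_topologies(parts)
    frame = Frame(0.0, coords, box=box)
    achieved = 100.0 * n_api * api.molar_mass / total_mass
    info = {
        "n_api": n_api,
        "n_chains": n_chains,
        "box_edge": box_edge,
        "target_wt_percent": target_wt_percent,
        "achieved_wt_percent": achieved,
        "total_mass": total_mass,
        "seed": seed,
    }
    return top, frame, info


# ----------------------------------------------------------------------
# Crystals
# ----------------------------------------------------------------------

@dataclass
class CellAtom:
    name: str
    element: str
    frac: tuple[float, float, float]
    mass: float
    charge: float = 0.0
    sigma: float = 0.3
    epsilon: float = 0.0


@dataclass
class UnitCellSpec:
    """Crystallographic unit cell: lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float
    z: int
    molar_mass: float
    atoms: list[CellAtom] = field(default_factory=list)
    name: str = "cell"

    def __post_init__(self) -> None:
        if self.z < 1:
            raise ValueError("Z must be >= 1")
        if self.volume_A3 <= 0:
            raise ValueError("degenerate cell: volume must be > 0")

    @property
    def volume_A3(self) -> float:
        """Triclinic cell volume, Å³:
        V = abc·√(1 − cos²α − cos²β − cos²γ + 2·cosα·cosβ·cosγ)."""
        ca = math.cos(math.radians(self.alpha))
        cb = math.cos(math.radians(self.beta))
        cg = math.cos(math.radians(self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if arg <= 0:
            return -1.0
        return self.a * self.b * self.c * math.sqrt(arg)

    def box(self) -> SimulationBox:
        return SimulationBox.from_parameters(
            self.a * 0.1, self.b * 0.1, self.c * 0.1,
            self.alpha, self.beta, self.gamma,
        )


def cell_density(cell: UnitCellSpec) -> float:
    """Crystal density ρ = Z·M/(N_A·V), g/cc."""
    return cell.z * cell.molar_mass * G_PER_MOL_PER_A3_TO_G_PER_CC / cell.volume_A3


def build_supercell(cell: UnitCellSpec, nx: int, ny: int, nz: int):
    """Replicate a unit cell nx×ny×nz.  Returns (topology, frame)."""
    if min(nx, ny, nz) < 1:
        raise ValueError("replication factors must be >= 1")
    if not cell.atoms:
        raise ValueError(f"cell {cell.name!r} has no atom contents")
    unit_box = cell.box()
    h = unit_box.lattice_vectors
    frac = np.array([a.frac for a in cell.atoms], dtype=float)
    base = frac @ h

    coords = []
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                shift = ix * h[0] + iy * h[1] + iz * h[2]
                coords.append(base + shift)
    coords = np.vstack(coords)
    n_cells = nx * ny * nz
    n_per = len(cell.atoms)

    names = [a.name for a in cell.atoms] * n_cells
    top = SystemTopology(
        names=[f"{nm}" for nm in names],
        elements=[a.element for a in cell.atoms] * n_cells,
        charges=[a.charge for a in cell.atoms] * n_cells,
        sigmas=[a.sigma for a in cell.atoms] * n_cells,
        epsilons=[a.epsilon for a in cell.atoms] * n_cells,
        masses=[a.mass for a in cell.atoms] * n_cells,
        molecule_ids=np.repeat(np.arange(n_cells), n_per),
        residue_names=["CRY"] * (n_cells * n_per),
    )
    box = unit_box.scaled((nx, ny, nz))
    return top, Frame(0.0, coords, box=box)


def lj_fcc_cell(a_angstrom: float, sigma: float = 0.34, epsilon: float = 1.0,
                mass: float = 39.95) -> UnitCellSpec:
    """Cubic FCC Lennard-Jones cell (4 atoms), the packaged toy crystal."""
    basis = [(0, 0, 0), (0.5, 0.5, 0), (0.5, 0, 0.5), (0, 0.5, 0.5)]
    atoms = [
        CellAtom(name=f"AR{k + 1}", element="Ar", frac=f, mass=mass,
                 sigma=sigma, epsilon=epsilon)
        for k, f in enumerate(basis)
    ]
    return UnitCellSpec(
        a=a_angstrom, b=a_angstrom, c=a_angstrom,
        alpha=90.0, beta=90.0, gamma=90.0,
        z=4, molar_mass=mass, atoms=atoms, name="lj_fcc",
    )


# ----------------------------------------------------------------------
# Simple fluid fixture
# ----------------------------------------------------------------------

def lj_fluid(n: int, box_edge: float, sigma: float = 0.34, epsilon: float = 1.0,
             mass: float = 39.95, charge: float = 0.0, seed: int = 0):
    """Monatomic LJ fluid on a jittered lattice (no overlaps).

    Returns (topology, frame)."""
    top = SystemTopology(
        names=[f"AR{i + 1}" for i in range(n)],
        elements=["Ar"] * n,
        charges=np.full(n, charge),
        sigmas=np.full(n, sigma),
        epsilons=np.full(n, epsilon),
        masses=np.full(n, mass),
        molecule_ids=np.arange(n),
        residue_names=["LJF"] * n,
    )
    rng = np.random.default_rng(seed)
    per_side = int(math.ceil(n ** (1.0 / 3.0)))
    spacing = box_edge / per_side
    pts = []
    for ix in range(per_side):
        for iy in range(per_side):
            for iz in range(per_side):
                pts.append((ix * spacing, iy * spacing, iz * spacing))
    pts = np.array(pts[:n], dtype=float)
    pts += rng.uniform(-0.05, 0.05, pts.shape) * spacing
    return top, Frame(0.0, pts, box=SimulationBox.cubic(box_edge))


# ----------------------------------------------------------------------
# Packaged template files
# ----------------------------------------------------------------------

_DATA_DIR = Path(__file__).parent / "data"


def load_template(name: str) -> MoleculeTemplate:
    """Load a template from the packaged topology files (exercises the
    text-format parser; equivalent to :func:`get_template`)."""
    from .topology import read_topology

    path = _DATA_DIR / f"{name}.top"
    if not path.exists():
        raise FileNotFoundError(f"no packaged template file {path}")
    top, coords = read_topology(path)
    if coords is None:
        raise ValueError(f"{path}: template file lacks [coords]")
    return MoleculeTemplate(
        name=top.meta.get("name", name),
        resname=top.meta.get("resname", "MOL"),
        topology=top, coords=coords,
        head=top.meta.get("head"), tail=top.meta.get("tail"),
        head_cap=top.meta.get("head_cap"), tail_cap=top.meta.get("tail_cap"),
    )


def dump_templates(directory=None) -> list[Path]:
    """Write all built-in templates as topology files (used to generate
    the packaged data directory)."""
    from .topology import write_topology

    directory = Path(directory) if directory else _DATA_DIR
    directory.mkdir(parents=True, exist_ok=True)
    out = []
    for name in list_templates():
        t = get_template(name)
        p = directory / f"{name}.top"
        write_topology(t.topology, p, coords=t.coords)
        out.append(p)
    return out
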