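"""Structural statistics: radial distribution function, geometric
hydrogen-bond detection, and crystal density/lattice validation.

The RDF is normalized as g_ij(r) = N_ij(r, r+Δr)·V / (4πr²Δr·N_i·N_j),
with N_ij the count of j atoms in the shell around i (summed over i,
frame-averaged).  Profiles use Å on the r axis (the conventional unit
for these plots); internal math is nm.

Hydrogen bonds use two geometric criteria, boundaries inclusive:
donor–acceptor distance ≤ d_max (default 3.5 Å) and the
hydrogen–donor–acceptor angle α ≤ alpha_max (default 30°).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from ..core.types import GroupSelection, Trajectory
from ..engine import RunResult
from ..synthetic import UnitCellSpec, cell_density
from ..topology import SystemTopology
from ..units import AMU_PER_NM3_TO_G_PER_CC, NM_TO_ANGSTROM

__all__ = [
    "RdfProfile",
    "HBondCriteria",
    "HBondResult",
    "CrystalMetrics",
    "rdf",
    "detect_hbonds",
    "crystal_metrics",
]


@dataclass
class RdfProfile:
    r: np.ndarray          # bin centers, Å
    g: np.ndarray
    dr: float              # bin width, Å
    group_i: str
    group_j: str
    n_frames: int
    pair_counts: np.ndarray = field(repr=False, default=None)  # mean per bin

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"r_angstrom": self.r, "g": self.g})


def rdf(
    traj: Trajectory,
    top: SystemTopology,
    group_i: GroupSelection,
    group_j: GroupSelection,
    r_max: float,
    dr: float = 0.02,
    include_intramolecular: bool = True,
    window: tuple[float, float] | None = None,
) -> RdfProfile:
    """Radial distribution function between two groups.

    ``r_max`` and ``dr`` are in Å.  ``r_max`` must not exceed half the
    smallest box extent.  By default all pairs contribute (bonded-peak
    region included); ``include_intramolecular=False`` drops
    same-molecule pairs.
    """
    sub = traj.window(*window) if window is not None else traj
    r_max_nm = r_max / NM_TO_ANGSTROM
    dr_nm = dr / NM_TO_ANGSTROM
    box0 = sub[0].box
    if box0 is None:
        raise ValueError("RDF requires a periodic box")
    if r_max_nm > box0.min_half_extent() + 1e-12:
        raise ValueError(
            f"r_max {r_max} Å exceeds half the smallest box extent "
            f"({box0.min_half_extent() * NM_TO_ANGSTROM:.2f} Å)"
        )
    ia, ja = group_i.indices, group_j.indices
    n_i, n_j = len(ia), len(ja)
    iu, ju = np.meshgrid(ia, ja, indexing="ij")
    iu, ju = iu.ravel(), ju.ravel()
    keep = iu != ju
    iu, ju = iu[keep], ju[keep]
    if not include_intramolecular:
        mol = top.molecule_ids
        keep = mol[iu] != mol[ju]
        iu, ju = iu[keep], ju[keep]

    n_bins = int(round(r_max_nm / dr_nm))
    edges = np.linspace(0.0, n_bins * dr_nm, n_bins + 1)
    hist = np.zeros(n_bins)
    vol = 0.0
    for fr in sub:
        d = fr.box.minimum_image(fr.positions[ju] - fr.positions[iu])
        r = np.sqrt(np.einsum("ij,ij->i", d, d))
        hist += np.histogram(r, bins=edges)[0]
        vol += fr.box.volume
    hist /= len(sub)
    vol /= len(sub)

    centers = 0.5 * (edges[:-1] + edges[1:])
    shell = 4.0 * math.pi * centers**2 * dr_nm
    with np.errstate(divide="ignore", invalid="ignore"):
        g = hist * vol / (shell * n_i * n_j)
    g[shell == 0] = 0.0
    return RdfProfile(
        r=centers * NM_TO_ANGSTROM, g=g, dr=dr,
        group_i=group_i.label, group_j=group_j.label,
        n_frames=len(sub), pair_counts=hist,
    )


# ----------------------------------------------------------------------
# Hydrogen bonds
# ----------------------------------------------------------------------

@dataclass
class HBondCriteria:
    d_max: float = 3.5        # donor–acceptor distance, Å
    alpha_max: float = 30.0   # hydrogen–donor–acceptor angle, degrees

    def __post_init__(self) -> None:
        if self.d_max <= 0:
            raise ValueError("d_max must be > 0")
        if not (0 < self.alpha_max <= 180):
            raise ValueError("alpha_max must be in (0, 180]")


@dataclass
class HBondResult:
    per_frame_counts: np.ndarray
    bonds_last_frame: list[tuple[int, int, int]]   # (donor, H, acceptor)
    n_reference_molecules: int

    @property
    def mean_count(self) -> float:
        return float(self.per_frame_counts.mean())

    @property
    def count_per_molecule(self) -> float:
        return self.mean_count / self.n_reference_molecules


def detect_hbonds(
    traj: Trajectory,
    top: SystemTopology,
    criteria: HBondCriteria = HBondCriteria(),
    group_a: GroupSelection | None = None,
    group_b: GroupSelection | None = None,
    window: tuple[float, float] | None = None,
) -> HBondResult:
    """Count hydrogen bonds between two groups (donor in either group,
    acceptor in the other; both directions).  With no groups given, all
    donor/acceptor pairs in different molecules are considered.

    A bond is counted iff d(D, A) ≤ d_max AND angle(H–D–A) ≤ alpha_max,
    both boundaries inclusive.
    """
    sub = traj.window(*window) if window is not None else traj
    donors_h = top.donor_hydrogens()
    acceptors = top.acceptor_atoms()
    adj = top.bonded_neighbors()
    heavy_of = {}
    for h_idx in donors_h:
        parents = [j for j in adj[h_idx]
                   if top.elements[j].upper() in ("O", "N")]
        if parents:
            heavy_of[int(h_idx)] = parents[0]

    def directed(sel_d, sel_a):
        """(H, D, A) candidate arrays with D in sel_d, A in sel_a."""
        hs, ds, as_ = [], [], []
        a_set = sel_a if sel_a is not None else None
        for h_idx, d_idx in heavy_of.items():
            if sel_d is not None and d_idx not in sel_d:
                continue
            for a_idx in acceptors:
                a_idx = int(a_idx)
                if a_idx == d_idx:
                    continue
                if a_set is not None:
                    if a_idx not in a_set:
                        continue
                elif top.molecule_ids[a_idx] == top.molecule_ids[d_idx]:
                    continue  # ungrouped mode: intermolecular only
                hs.append(h_idx)
                ds.append(d_idx)
                as_.append(a_idx)
        return (np.array(hs, dtype=np.intp), np.array(ds, dtype=np.intp),
                np.array(as_, dtype=np.intp))

    if group_a is not None and group_b is not None:
        cand = [directed(group_a.atom_indices, group_b.atom_indices),
                directed(group_b.atom_indices, group_a.atom_indices)]
        n_ref = max(len(group_a.molecule_ids), 1)
    else:
        cand = [directed(None, None)]
        n_ref = len(set(int(m) for m in top.molecule_ids))

    if all(len(c[0]) == 0 for c in cand):
        warnings.warn("no donor/acceptor candidates in the given groups",
                      stacklevel=2)
        return HBondResult(
            per_frame_counts=np.zeros(len(sub)), bonds_last_frame=[],
            n_reference_molecules=n_ref,
        )

    d_max_nm = criteria.d_max / NM_TO_ANGSTROM
    cos_min = math.cos(math.radians(criteria.alpha_max))
    counts = np.zeros(len(sub))
    last_bonds: list[tuple[int, int, int]] = []
    for k, fr in enumerate(sub):
        frame_bonds = []
        for hs, ds, as_ in cand:
            if len(hs) == 0:
                continue
            pos = fr.positions
            v_da = fr.box.minimum_image(pos[as_] - pos[ds])
            r_da = np.sqrt(np.einsum("ij,ij->i", v_da, v_da))
            close = r_da <= d_max_nm + 1e-12
            if not np.any(close):
                continue
            v_dh = fr.box.minimum_image(pos[hs[close]] - pos[ds[close]])
            da = v_da[close]
            dh_norm = np.linalg.norm(v_dh, axis=1)
            da_norm = r_da[close]
            cos_a = np.einsum("ij,ij->i", v_dh, da) / (dh_norm * da_norm)
            # inclusive boundary: α ≤ alpha_max  <=>  cos α ≥ cos(alpha_max)
            ok = cos_a >= cos_min - 1e-12
            idx = np.flatnonzero(close)[ok]
            for t in idx:
                frame_bonds.append((int(ds[t]), int(hs[t]), int(as_[t])))
        counts[k] = len(frame_bonds)
        if k == len(sub) - 1:
            last_bonds = frame_bonds
    return HBondResult(
        per_frame_counts=counts, bonds_last_frame=last_bonds,
        n_reference_molecules=n_ref,
    )


# ----------------------------------------------------------------------
# Crystal validation
# ----------------------------------------------------------------------

@dataclass
class CrystalMetrics:
    density: float                      # g/cc, time-averaged
    a: float                            # Å (unit-cell, recovered)
    b: float
    c: float
    alpha: float                        # degrees
    beta: float
    gamma: float
    deviations_percent: dict[str, float]
    passes_3_percent: bool

    def max_abs_deviation(self) -> float:
        return max(abs(v) for v in self.deviations_percent.values())


def crystal_metrics(
    run: RunResult,
    top: SystemTopology,
    reference: UnitCellSpec,
    replication: tuple[int, int, int],
    window: tuple[float, float] | None = None,
) -> CrystalMetrics:
    """Time-averaged density and unit-cell parameters of a crystal run,
    with percent deviation 100·(sim − ref)/ref against the reference
    cell.  ``replication`` is the supercell factor used to build the
    system, so unit-cell lengths are recovered by division.
    """
    frames = run.trajectory.frames
    if window is not None:
        frames = [f for f in frames if window[0] <= f.time <= window[1]]
        if not frames:
            raise ValueError("empty crystal-metrics window")
    if any(f.box is None for f in frames):
        raise ValueError("crystal metrics require a recorded box series")
    nx, ny, nz = replication
    total_mass = top.molar_mass
    vols = np.array([f.box.volume for f in frames])
    density = float(total_mass / vols.mean() * AMU_PER_NM3_TO_G_PER_CC)
    params = np.array([f.box.parameters for f in frames])
    mean = params.mean(axis=0)
    a = mean[0] / nx * NM_TO_ANGSTROM
    b = mean[1] / ny * NM_TO_ANGSTROM
    c = mean[2] / nz * NM_TO_ANGSTROM
    alpha, beta, gamma = mean[3:6]

    ref_density = cell_density(reference)
    sim = {"density": density, "a": a, "b": b, "c": c,
           "alpha": alpha, "beta": beta, "gamma": gamma}
    ref = {"density": ref_density, "a": reference.a, "b": reference.b,
           "c": reference.c, "alpha": reference.alpha, "beta": reference.beta,
           "gamma": reference.gamma}
    dev = {k: 100.0 * (sim[k] - ref[k]) / ref[k] for k in sim}
    return CrystalMetrics(
        density=density, a=a, b=b, c=c, alpha=alpha, beta=beta, gamma=gamma,
        deviations_percent=dev,
        passes_3_percent=all(abs(v) < 3.0 for v in dev.values()),
    )
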