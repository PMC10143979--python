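"""OPLS-style potential: LJ + Coulomb nonbonded terms with geometric
combining rules, 1-2/1-3 exclusions and scaled 1-4 pairs, plus harmonic
bonds/angles and cosine dihedrals.

Electrostatics are real-space pairwise within a cutoff.  By default the
Coulomb term is energy-shifted to vanish at the cutoff (the shift moves
energies, not forces); the LJ term uses a plain truncation.  Pairs at
exactly r = r_c are *included* (closed interval).  An optional plain
Ewald sum (no mesh) is provided for small systems as a diagnostic.

Two evaluation backends produce identical physics: a vectorized numpy
path (reference, used by analyses) and numba kernels (used by the MD
engine; brute-force double loop or cell list, bit-identical to each
other by construction of the accumulation order).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core.types import Frame, SimulationBox
from .topology import SystemTopology
from .units import F_COUL

try:
    from . import _kernels

    HAVE_NUMBA = _kernels.HAVE_NUMBA
except ImportError:  # pragma: no cover - numba always present in practice
    _kernels = None
    HAVE_NUMBA = False

__all__ = [
    "Cutoffs",
    "EnergyBreakdown",
    "lj_pair_energy",
    "coulomb_pair_energy",
    "combine_params",
    "system_potential",
    "compute_forces",
]


@dataclass(frozen=True)
class Cutoffs:
    """Nonbonded cutoff scheme (nm).  ``shift_coul`` subtracts the value
    of the Coulomb term at r_c; ``shift_lj`` likewise for LJ.
    ``lj_tail`` adds the analytic long-range dispersion correction to the
    LJ energy (energy only, off by default)."""

    r_lj: float = 1.4
    r_coul: float = 1.4
    shift_coul: bool = True
    shift_lj: bool = False
    lj_tail: bool = False

    @property
    def r_max(self) -> float:
        return max(self.r_lj, self.r_coul)


@dataclass
class EnergyBreakdown:
    """Potential-energy decomposition, kJ/mol."""

    e_coul: float = 0.0
    e_lj: float = 0.0
    e_bonded: float = 0.0

    @property
    def e_total(self) -> float:
        return self.e_coul + self.e_lj + self.e_bonded

    @property
    def e_nonbonded(self) -> float:
        return self.e_coul + self.e_lj


# ----------------------------------------------------------------------
# Pair kernels
# ----------------------------------------------------------------------

def lj_pair_energy(r, sigma, epsilon):
    """Lennard-Jones pair energy 4ε[(σ/r)¹² − (σ/r)⁶], kJ/mol."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("LJ energy undefined for r <= 0")
    sr6 = (np.asarray(sigma, dtype=float) / r) ** 6
    out = 4.0 * np.asarray(epsilon, dtype=float) * (sr6 * sr6 - sr6)
    return float(out) if out.ndim == 0 else out


def coulomb_pair_energy(r, qi, qj):
    """Coulomb pair energy f·qi·qj/r with f = 138.935458 kJ·mol⁻¹·nm·e⁻²."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("Coulomb energy undefined for r <= 0")
    out = F_COUL * np.asarray(qi, dtype=float) * np.asarray(qj, dtype=float) / r
    return float(out) if out.ndim == 0 else out


def combine_params(sigma_i, epsilon_i, sigma_j, epsilon_j):
    """OPLS geometric combining rules: σij = √(σiσj), εij = √(εiεj)."""
    return (
        math.sqrt(sigma_i * sigma_j),
        math.sqrt(epsilon_i * epsilon_j),
    )


# ----------------------------------------------------------------------
# Exclusion bookkeeping
# ----------------------------------------------------------------------

class PairScales:
    """Per-topology cache of exclusion / 1-4 structures in CSR-ish form."""

    def __init__(self, top: SystemTopology):
        n = top.n_atoms
        excl = top.exclusions()
        s14 = top.scaled_pairs()

        def csr(pairs):
            per = [[] for _ in range(n)]
            for i, j in pairs:
                per[i].append(j)
                per[j].append(i)
            ptr = np.zeros(n + 1, dtype=np.int64)
            flat = []
            for i in range(n):
                per[i].sort()
                flat.extend(per[i])
                ptr[i + 1] = len(flat)
            return ptr, np.array(flat, dtype=np.int64)

        self.excl_ptr, self.excl_idx = csr(excl)
        self.s14_ptr, self.s14_idx = csr(s14)
        self.excl_set = excl
        self.s14_set = s14


def _pair_scales(top: SystemTopology) -> PairScales:
    cache = getattr(top, "_pair_scales_cache", None)
    if cache is None:
        cache = PairScales(top)
        top._pair_scales_cache = cache
    return cache


# ----------------------------------------------------------------------
# System potential
# ----------------------------------------------------------------------

def _check_box(box: SimulationBox, cutoffs: Cutoffs) -> None:
    if box.min_half_extent() < cutoffs.r_max:
        raise ValueError(
            f"box too small for minimum-image convention: half-extent "
            f"{box.min_half_extent():.3f} nm < cutoff {cutoffs.r_max:.3f} nm"
        )


def system_potential(
    frame: Frame,
    top: SystemTopology,
    cutoffs: Cutoffs = Cutoffs(),
    include_bonded: bool = True,
    backend: str = "auto",
    neighbor: str = "brute",
):
    """Total potential energy breakdown of a configuration.

    Returns :class:`EnergyBreakdown`.  Use :func:`compute_forces` when
    forces and the virial are needed as well.
    """
    e, _, _ = compute_forces(
        frame, top, cutoffs, include_bonded=include_bonded,
        backend=backend, neighbor=neighbor,
    )
    return e


def compute_forces(
    frame: Frame,
    top: SystemTopology,
    cutoffs: Cutoffs = Cutoffs(),
    include_bonded: bool = True,
    backend: str = "auto",
    neighbor: str = "brute",
):
    """Energies, forces (kJ/mol/nm) and scalar virial of a configuration.

    ``backend='auto'`` uses the numba kernels when available.
    ``neighbor`` selects brute-force pairs or a cell list (numba only);
    both produce bit-identical results.
    """
    if frame.box is None:
        raise ValueError("frame has no box; nonbonded evaluation requires one")
    _check_box(frame.box, cutoffs)
    if backend == "auto":
        backend = "numba" if HAVE_NUMBA else "numpy"

    pos = np.ascontiguousarray(frame.positions, dtype=float)
    h = frame.box.lattice_vectors
    scales = _pair_scales(top)

    if backend == "numba":
        if not HAVE_NUMBA:
            raise RuntimeError("numba backend requested but numba is unavailable")
        e_lj, e_coul, forces, virial = _kernels.nonbonded(
            pos, h, top.charges, top.sigmas, top.epsilons,
            scales.excl_ptr, scales.excl_idx, scales.s14_ptr, scales.s14_idx,
            top.fudge_lj, top.fudge_coul,
            cutoffs.r_lj, cutoffs.r_coul,
            cutoffs.shift_lj, cutoffs.shift_coul,
            use_cells=(neighbor == "cell"),
        )
    elif backend == "numpy":
        e_lj, e_coul, forces, virial = _nonbonded_numpy(pos, h, top, cutoffs, scales)
    else:
        raise ValueError(f"unknown backend {backend!r}")

    if cutoffs.lj_tail:
        e_lj += lj_tail_correction(top, frame.box, cutoffs.r_lj)
    breakdown = EnergyBreakdown(e_coul=float(e_coul), e_lj=float(e_lj))
    if include_bonded:
        e_b, f_b, w_b = _bonded(pos, frame.box, top)
        breakdown.e_bonded = float(e_b)
        forces = forces + f_b
        virial += w_b
    if not np.all(np.isfinite(forces)):
        raise FloatingPointError(
            "non-finite forces encountered (overlapping atoms?)"
        )
    return breakdown, forces, float(virial)


def _nonbonded_numpy(pos, h, top, cutoffs, scales):
    n = pos.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    dr = pos[ju] - pos[iu]
    hinv = np.linalg.inv(h)
    s = dr @ hinv
    s -= np.round(s)
    dr = s @ h
    r2 = np.einsum("ij,ij->i", dr, dr)

    lj_scale = np.ones(len(iu))
    coul_scale = np.ones(len(iu))
    if scales.excl_set or scales.s14_set:
        keys = iu.astype(np.int64) * n + ju
        if scales.excl_set:
            excl_keys = np.array(
                sorted(i * n + j for i, j in scales.excl_set), dtype=np.int64
            )
            excluded = np.isin(keys, excl_keys)
            lj_scale[excluded] = 0.0
            coul_scale[excluded] = 0.0
        if scales.s14_set:
            s14_keys = np.array(
                sorted(i * n + j for i, j in scales.s14_set), dtype=np.int64
            )
            scaled = np.isin(keys, s14_keys)
            lj_scale[scaled] = top.fudge_lj
            coul_scale[scaled] = top.fudge_coul

    r = np.sqrt(r2)
    if np.any((r < 1e-12) & ((lj_scale > 0) | (coul_scale > 0))):
        raise FloatingPointError("coincident interacting atoms (r = 0)")
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_r = np.where(r > 0, 1.0 / r, 0.0)

    sig = np.sqrt(top.sigmas[iu] * top.sigmas[ju])
    eps = np.sqrt(top.epsilons[iu] * top.epsilons[ju]) * lj_scale
    qq = top.charges[iu] * top.charges[ju] * coul_scale

    in_lj = r <= cutoffs.r_lj
    sr6 = np.where(in_lj, (sig * inv_r) ** 6, 0.0)
    e_lj_pair = 4.0 * eps * (sr6 * sr6 - sr6)
    if cutoffs.shift_lj:
        src6 = (sig / cutoffs.r_lj) ** 6
        e_lj_pair -= np.where(in_lj & (eps != 0), 4.0 * eps * (src6 * src6 - src6), 0.0)
    # dU/dr · (1/r) for force: F = -dU/dr * rhat
    f_lj_over_r = np.where(in_lj, 24.0 * eps * (2.0 * sr6 * sr6 - sr6) * inv_r**2, 0.0)

    in_coul = r <= cutoffs.r_coul
    e_coul_pair = np.where(in_coul, F_COUL * qq * inv_r, 0.0)
    if cutoffs.shift_coul:
        e_coul_pair -= np.where(in_coul & (qq != 0), F_COUL * qq / cutoffs.r_coul, 0.0)
    f_coul_over_r = np.where(in_coul, F_COUL * qq * inv_r**3, 0.0)

    f_over_r = f_lj_over_r + f_coul_over_r
    fvec = dr * f_over_r[:, None]
    forces = np.zeros_like(pos)
    for d in range(3):
        forces[:, d] += np.bincount(ju, weights=fvec[:, d], minlength=n)
        forces[:, d] -= np.bincount(iu, weights=fvec[:, d], minlength=n)
    virial = float(np.sum(f_over_r * r2))
    return float(np.sum(e_lj_pair)), float(np.sum(e_coul_pair)), forces, virial


def lj_tail_correction(top: SystemTopology, box: SimulationBox,
                       r_lj: float) -> float:
    """Analytic LJ energy correction for the truncated r > r_c region,
    assuming g(r) = 1 beyond the cutoff (kJ/mol).

    For geometric combining rules the double pair sum factorizes:
    Σ_{i<j} √(εiεj)(σiσj)^a = (S_a² − Q_a)/2 with S_a = Σ √εi σi^(2a),
    so the correction is O(N).  Exclusions are ignored (their tail
    contribution is negligible); energy only, no virial term.
    """
    s3 = np.sqrt(top.epsilons) * top.sigmas**3
    s6 = np.sqrt(top.epsilons) * top.sigmas**6
    sum6 = 0.5 * (s3.sum() ** 2 - (s3**2).sum())    # Σ_{i<j} εij σij⁶
    sum12 = 0.5 * (s6.sum() ** 2 - (s6**2).sum())   # Σ_{i<j} εij σij¹²
    v = box.volume
    return float(
        (16.0 * math.pi / v)
        * (sum12 / (9.0 * r_lj**9) - sum6 / (3.0 * r_lj**3))
    )


# ----------------------------------------------------------------------
# Bonded terms
# ----------------------------------------------------------------------

def _scatter(forces, idx, fvec):
    n = forces.shape[0]
    for d in range(3):
        forces[:, d] += np.bincount(idx, weights=fvec[:, d], minlength=n)


def _bonded(pos, box: SimulationBox, top: SystemTopology):
    """Harmonic bonds/angles + cosine dihedrals (vectorized):
    energy, forces, virial."""
    e = 0.0
    forces = np.zeros_like(pos)
    virial = 0.0

    if len(top.bonds):
        i, j = top.bonds[:, 0], top.bonds[:, 1]
        dr = box.minimum_image(pos[j] - pos[i])
        r = np.linalg.norm(dr, axis=1)
        dev = r - top.bond_r0
        e += float(np.sum(0.5 * top.bond_k * dev**2))
        # F_j = -k (r - r0) rhat
        with np.errstate(invalid="ignore", divide="ignore"):
            f_over_r = np.where(r > 0, -top.bond_k * dev / r, 0.0)
        fvec = dr * f_over_r[:, None]
        _scatter(forces, j, fvec)
        _scatter(forces, i, -fvec)
        virial += float(np.sum(f_over_r * r * r))

    if len(top.angles):
        ia, ja, ka = top.angles[:, 0], top.angles[:, 1], top.angles[:, 2]
        rij = box.minimum_image(pos[ia] - pos[ja])
        rkj = box.minimum_image(pos[ka] - pos[ja])
        lij = np.linalg.norm(rij, axis=1)
        lkj = np.linalg.norm(rkj, axis=1)
        cos_t = np.clip(
            np.einsum("ij,ij->i", rij, rkj) / (lij * lkj), -1.0, 1.0
        )
        theta = np.arccos(cos_t)
        dev = theta - top.angle_theta0
        e += float(np.sum(0.5 * top.angle_k * dev**2))
        sin_t = np.sqrt(np.maximum(1.0 - cos_t**2, 1e-12))
        coef = (top.angle_k * dev / sin_t)[:, None]
        fi = coef * (rkj / (lij * lkj)[:, None] - cos_t[:, None] * rij / (lij**2)[:, None])
        fk = coef * (rij / (lij * lkj)[:, None] - cos_t[:, None] * rkj / (lkj**2)[:, None])
        fj = -(fi + fk)
        _scatter(forces, ia, fi)
        _scatter(forces, ja, fj)
        _scatter(forces, ka, fk)
        virial += float(np.einsum("ij,ij->", fi, rij) + np.einsum("ij,ij->", fk, rkj))

    if len(top.dihedrals):
        i0, j0, k0, l0 = (top.dihedrals[:, c] for c in range(4))
        b1 = box.minimum_image(pos[j0] - pos[i0])
        b2 = box.minimum_image(pos[k0] - pos[j0])
        b3 = box.minimum_image(pos[l0] - pos[k0])
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        b2n = np.linalg.norm(b2, axis=1)
        x = np.einsum("ij,ij->i", n1, n2)
        y = np.einsum("ij,ij->i", np.cross(n1, n2), b2) / b2n
        phi = np.arctan2(y, x)
        mult = top.dihedral_mult.astype(float)
        e += float(np.sum(top.dihedral_k * (1.0 + np.cos(mult * phi - top.dihedral_phi0))))
        dV = -top.dihedral_k * mult * np.sin(mult * phi - top.dihedral_phi0)
        n1_sq = np.maximum(np.einsum("ij,ij->i", n1, n1), 1e-12)
        n2_sq = np.maximum(np.einsum("ij,ij->i", n2, n2), 1e-12)
        fi = (dV * b2n / n1_sq)[:, None] * n1
        fl = (-dV * b2n / n2_sq)[:, None] * n2
        t1 = (np.einsum("ij,ij->i", b1, b2) / b2n**2)[:, None]
        t3 = (np.einsum("ij,ij->i", b3, b2) / b2n**2)[:, None]
        sv = -t1 * fi + t3 * fl
        fj = -fi + sv
        fk = -fl - sv
        _scatter(forces, i0, fi)
        _scatter(forces, j0, fj)
        _scatter(forces, k0, fk)
        _scatter(forces, l0, fl)
        # local coordinates relative to atom j for the virial
        virial += float(
            np.einsum("ij,ij->", fi, -b1)
            + np.einsum("ij,ij->", fk, b2)
            + np.einsum("ij,ij->", fl, b2 + b3)
        )

    return e, forces, virial


# ----------------------------------------------------------------------
# Optional plain Ewald (energy only; diagnostic for small systems)
# ----------------------------------------------------------------------

def ewald_energy(
    frame: Frame,
    top: SystemTopology,
    alpha: float | None = None,
    r_cut: float = 1.2,
    k_max: int = 8,
) -> float:
    """Coulomb energy by a plain (non-mesh) Ewald sum, kJ/mol.

    Orthorhombic boxes only; intended for systems ≤ ~3000 atoms as a
    cross-check of the cutoff electrostatics.  Exclusions are honored by
    subtracting the erf-complement of excluded pairs.
    """
    box = frame.box
    if box is None or not box.is_orthorhombic:
        raise ValueError("plain Ewald requires an orthorhombic box")
    q = top.charges
    if np.allclose(q, 0.0):
        return 0.0
    L = np.diag(box.lattice_vectors).copy()
    V = box.volume
    if alpha is None:
        alpha = 3.0 / r_cut
    pos = frame.positions
    n = len(q)
    from scipy.special import erfc

    # real space over all pairs within r_cut (minimum image)
    iu, ju = np.triu_indices(n, k=1)
    dr = box.minimum_image(pos[ju] - pos[iu])
    r = np.linalg.norm(dr, axis=1)
    mask = (r <= r_cut) & (r > 0)
    e_real = F_COUL * np.sum(q[iu[mask]] * q[ju[mask]] * erfc(alpha * r[mask]) / r[mask])

    # reciprocal space
    mx = np.arange(-k_max, k_max + 1)
    kx, ky, kz = np.meshgrid(mx, mx, mx, indexing="ij")
    kvecs = np.stack(
        [2 * np.pi * kx / L[0], 2 * np.pi * ky / L[1], 2 * np.pi * kz / L[2]], axis=-1
    ).reshape(-1, 3)
    k2 = np.einsum("ij,ij->i", kvecs, kvecs)
    sel = k2 > 1e-12
    kvecs, k2 = kvecs[sel], k2[sel]
    phases = pos @ kvecs.T
    sk = np.abs(
        np.sum(q[:, None] * np.exp(1j * phases), axis=0)
    ) ** 2
    e_rec = (
        F_COUL * (2 * np.pi / V)
        * np.sum(np.exp(-k2 / (4 * alpha**2)) / k2 * sk)
    )

    e_self = -F_COUL * alpha / math.sqrt(math.pi) * np.sum(q**2)

    # excluded intramolecular pairs: remove their full Coulomb interaction
    scales = _pair_scales(top)
    e_excl = 0.0
    from scipy.special import erf

    for i, j in scales.excl_set:
        d = np.linalg.norm(box.minimum_image(pos[j] - pos[i]))
        if d > 0:
            e_excl -= F_COUL * q[i] * q[j] * erf(alpha * d) / d
    for i, j in scales.s14_set:
        d = np.linalg.norm(box.minimum_image(pos[j] - pos[i]))
        if d > 0:
            # the scaled 1-4 keeps fudge_coul of the direct term
            e_excl -= F_COUL * q[i] * q[j] * erf(alpha * d) / d
            e_excl -= (1.0 - top.fudge_coul) * F_COUL * q[i] * q[j] * erfc(alpha * d) / d

    return float(e_real + e_rec + e_self + e_excl)
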