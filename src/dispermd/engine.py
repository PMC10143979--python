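"""Minimal MD engine: steepest-descent minimization, Maxwell–Boltzmann
velocity initialization, leap-frog integration with a stochastic
velocity-rescale thermostat (NVT), an NVE validation mode, and an
isotropic weak-coupling barostat (NPT).

Conventions: positions are integrated unwrapped (interactions use the
minimum image, so wrapping is cosmetic and applied only on file output);
centre-of-mass motion is removed every step in thermostatted runs and
once at start in NVE; N_df = 3N − 3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core.types import Frame, Trajectory
from .forcefield import Cutoffs, compute_forces
from .topology import SystemTopology
from .units import KB, bar_to_internal, internal_to_bar

__all__ = [
    "IntegratorConfig",
    "ThermostatConfig",
    "BarostatConfig",
    "MinimizerConfig",
    "MinimizeResult",
    "RunResult",
    "minimize_steepest_descent",
    "init_velocities_mb",
    "integrate_nvt",
    "integrate_nve",
    "integrate_npt",
]


@dataclass
class IntegratorConfig:
    dt: float = 0.002          # ps (2 fs)
    n_steps: int = 1000
    save_interval: int = 500   # steps between saved frames (default 1 ps)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.save_interval < 1:
            raise ValueError("save_interval must be >= 1")


@dataclass
class ThermostatConfig:
    target_T: float = 300.0    # K
    tau: float = 0.1           # ps
    enabled: bool = True
    mode: str = "vrescale"     # 'vrescale' (stochastic) or 'berendsen'

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("thermostat relaxation time must be > 0")
        if self.mode not in ("vrescale", "berendsen"):
            raise ValueError(f"unknown thermostat mode {self.mode!r}")


@dataclass
class BarostatConfig:
    target_P: float = 1.0          # bar
    tau_P: float = 1.0             # ps
    compressibility: float = 4.5e-5  # bar^-1
    enabled: bool = True


@dataclass
class MinimizerConfig:
    max_force_tol: float = 1000.0  # kJ/mol/nm
    max_steps: int = 5000
    initial_step: float = 0.01     # nm

    def __post_init__(self) -> None:
        if self.max_force_tol <= 0:
            raise ValueError("force tolerance must be > 0")


@dataclass
class MinimizeResult:
    frame: Frame
    converged: bool
    max_force: float
    n_steps: int
    potential_energy: float


@dataclass
class RunResult:
    """Per-run observables.  Energies are kJ/mol, temperatures K."""

    trajectory: Trajectory
    times: np.ndarray
    e_kinetic: np.ndarray
    e_potential: np.ndarray
    e_coul: np.ndarray
    e_lj: np.ndarray
    e_bonded: np.ndarray
    temperature: np.ndarray
    volume: np.ndarray
    pressure: np.ndarray | None = None
    config: dict = field(default_factory=dict)

    @property
    def e_total(self) -> np.ndarray:
        return self.e_kinetic + self.e_potential

    @property
    def mean_temperature(self) -> float:
        return float(np.mean(self.temperature[1:])) if len(self.temperature) > 1 \
            else float(self.temperature[0])

    @property
    def final_frame(self) -> Frame:
        return self.trajectory[-1]

    def thermostat_on_target(self, target_T: float, n_sigma: float = 3.0) -> bool:
        """Mean kinetic temperature within n_sigma of the canonical
        single-sample fluctuation σ = T·√(2/N_df)."""
        n_df = 3 * self.trajectory.n_atoms - 3
        sigma = target_T * math.sqrt(2.0 / n_df)
        return abs(self.mean_temperature - target_T) <= n_sigma * sigma


# ----------------------------------------------------------------------
# Minimization
# ----------------------------------------------------------------------

def minimize_steepest_descent(
    frame: Frame,
    top: SystemTopology,
    cfg: MinimizerConfig = MinimizerConfig(),
    cutoffs: Cutoffs = Cutoffs(),
    backend: str = "auto",
) -> MinimizeResult:
    """Steepest descent with adaptive step; energy never increases across
    accepted steps.  Stops at ``max_force_tol`` (kJ/mol/nm) or
    ``max_steps``."""
    pos = frame.positions.copy()
    try:
        e, f, _ = compute_forces(Frame(frame.time, pos, box=frame.box), top,
                                 cutoffs, backend=backend)
    except FloatingPointError as exc:
        raise FloatingPointError(
            f"non-finite energy at minimization start ({exc}); "
            "check for overlapping atoms"
        )
    if not math.isfinite(e.e_total):
        raise FloatingPointError(
            "non-finite energy at minimization start; check for overlapping atoms"
        )
    e_cur = e.e_total
    step = cfg.initial_step
    fmax = float(np.max(np.abs(f)))
    n = 0
    while fmax > cfg.max_force_tol and n < cfg.max_steps and step > 1e-10:
        trial = pos + step * f / fmax
        try:
            e_t, f_t, _ = compute_forces(Frame(frame.time, trial, box=frame.box),
                                         top, cutoffs, backend=backend)
            ok = math.isfinite(e_t.e_total) and e_t.e_total <= e_cur
        except FloatingPointError:
            ok = False
        if ok:
            pos, e_cur, f = trial, e_t.e_total, f_t
            fmax = float(np.max(np.abs(f)))
            step *= 1.2
        else:
            step *= 0.5
        n += 1
    out = Frame(frame.time, pos, box=frame.box, velocities=frame.velocities)
    return MinimizeResult(
        frame=out, converged=fmax <= cfg.max_force_tol,
        max_force=fmax, n_steps=n, potential_energy=e_cur,
    )


# ----------------------------------------------------------------------
# Velocities
# ----------------------------------------------------------------------

def _kinetic(vel: np.ndarray, masses: np.ndarray) -> float:
    return 0.5 * float(np.sum(masses[:, None] * vel**2))


def _temperature(ke: float, n_df: int) -> float:
    return 2.0 * ke / (n_df * KB) if n_df > 0 else 0.0


def _remove_com_velocity(vel: np.ndarray, masses: np.ndarray) -> None:
    p = masses @ vel
    vel -= p / masses.sum()


def init_velocities_mb(
    frame: Frame, top: SystemTopology, temperature: float, seed: int = 0
) -> Frame:
    """Maxwell–Boltzmann velocities: components ~ N(0, k_B·T/m), COM
    momentum removed, then rescaled exactly to the target temperature."""
    if temperature < 0:
        raise ValueError("temperature must be >= 0")
    if np.any(top.masses <= 0):
        raise ValueError("all masses must be > 0")
    n = frame.n_atoms
    if temperature == 0:
        vel = np.zeros((n, 3))
    else:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(KB * temperature / top.masses)
        vel = rng.standard_normal((n, 3)) * sigma[:, None]
        _remove_com_velocity(vel, top.masses)
        n_df = 3 * n - 3
        t_inst = _temperature(_kinetic(vel, top.masses), n_df)
        if t_inst > 0:
            vel *= math.sqrt(temperature / t_inst)
    return Frame(frame.time, frame.positions.copy(), box=frame.box, velocities=vel)


# ----------------------------------------------------------------------
# Thermostats
# ----------------------------------------------------------------------

def _vrescale_factor(ke, ke_target, n_df, c, rng) -> float:
    """Stochastic velocity-rescale (canonical sampling) scaling factor²
    for one step; c = exp(-dt/tau)."""
    if ke <= 0:
        return 1.0
    r1 = rng.standard_normal()
    s = rng.chisquare(n_df - 1) if n_df > 1 else 0.0
    kt = ke_target / n_df
    a2 = (
        c
        + (1.0 - c) * kt * (r1 * r1 + s) / ke
        + 2.0 * r1 * math.sqrt(c * (1.0 - c) * kt / ke)
    )
    return math.sqrt(max(a2, 0.0))


# ----------------------------------------------------------------------
# Leap-frog integration
# ----------------------------------------------------------------------

def _integrate(
    frame: Frame,
    top: SystemTopology,
    icfg: IntegratorConfig,
    tcfg: ThermostatConfig | None,
    pcfg: BarostatConfig | None,
    cutoffs: Cutoffs,
    backend: str = "auto",
    neighbor: str = "brute",
    remove_com: bool | None = None,
) -> RunResult:
    if frame.velocities is None:
        raise ValueError("integration requires initialized velocities")
    if frame.box is None:
        raise ValueError("integration requires a periodic box")
    masses = top.masses
    n = frame.n_atoms
    n_df = 3 * n - 3
    dt = icfg.dt
    rng = np.random.default_rng(icfg.seed)
    thermostatted = tcfg is not None and tcfg.enabled
    barostatted = pcfg is not None and pcfg.enabled and math.isfinite(pcfg.tau_P)
    if remove_com is None:
        remove_com = thermostatted

    pos = frame.positions.copy()
    box = frame.box
    vel = frame.velocities.copy()  # on-step velocity v(t)
    if not thermostatted and n > 1:
        # one-time drift removal; skipped for a single free particle
        _remove_com_velocity(vel, masses)

    e, forces, virial = compute_forces(Frame(frame.time, pos, box=box), top,
                                       cutoffs, backend=backend, neighbor=neighbor)

    # half-step kick to obtain v(t - dt/2) convention start
    vel_half = vel + 0.5 * dt * forces / masses[:, None]

    times, ekins, epots, ecouls, eljs, ebondeds, temps, vols, press = (
        [] for _ in range(9)
    )
    frames = []

    def record(t, ke, e_brk, v_on, p_internal):
        times.append(t)
        ekins.append(ke)
        epots.append(e_brk.e_total)
        ecouls.append(e_brk.e_coul)
        eljs.append(e_brk.e_lj)
        ebondeds.append(e_brk.e_bonded)
        temps.append(_temperature(ke, n_df))
        vols.append(box.volume)
        press.append(internal_to_bar(p_internal))
        frames.append(Frame(t, pos.copy(), box=box, velocities=v_on.copy()))

    ke0 = _kinetic(vel, masses)
    p0 = (2.0 * ke0 + virial) / (3.0 * box.volume)
    record(frame.time, ke0, e, vel, p0)

    for step in range(1, icfg.n_steps + 1):
        t = frame.time + step * dt
        pos = pos + dt * vel_half
        e, forces, virial = compute_forces(Frame(t, pos, box=box), top, cutoffs,
                                           backend=backend, neighbor=neighbor)
        if abs(e.e_total) > 1e6 * n:
            raise FloatingPointError(
                f"energy diverged at t={t:.4f} ps: {e.e_total:.3e} kJ/mol "
                f"({e.e_total / n:.3e} per atom); reduce dt or re-minimize"
            )
        vel_new_half = vel_half + dt * forces / masses[:, None]
        vel_on = 0.5 * (vel_half + vel_new_half)
        if remove_com:
            _remove_com_velocity(vel_on, masses)
            _remove_com_velocity(vel_new_half, masses)
        ke = _kinetic(vel_on, masses)

        if thermostatted:
            if tcfg.mode == "vrescale":
                ke_target = 0.5 * n_df * KB * tcfg.target_T
                c = math.exp(-dt / tcfg.tau)
                lam = _vrescale_factor(ke, ke_target, n_df, c, rng)
            else:  # berendsen
                t_inst = _temperature(ke, n_df)
                lam = math.sqrt(
                    1.0 + (dt / tcfg.tau) * (tcfg.target_T / max(t_inst, 1e-10) - 1.0)
                ) if t_inst > 0 else 1.0
            vel_new_half *= lam
            vel_on *= lam
            ke = _kinetic(vel_on, masses)

        p_internal = (2.0 * ke + virial) / (3.0 * box.volume)
        if barostatted:
            dp = bar_to_internal(pcfg.target_P) - p_internal
            beta = pcfg.compressibility / bar_to_internal(1.0)  # (kJ/mol/nm^3)^-1
            mu3 = 1.0 - (beta * dt / pcfg.tau_P) * dp
            if mu3 <= 0:
                raise FloatingPointError("barostat drove the box to zero volume")
            mu = mu3 ** (1.0 / 3.0)
            from .core.types import SimulationBox

            box = SimulationBox(box.lattice_vectors * mu)
            pos = pos * mu

        vel_half = vel_new_half
        if step % icfg.save_interval == 0 or step == icfg.n_steps:
            record(t, ke, e, vel_on, p_internal)

    return RunResult(
        trajectory=Trajectory(frames),
        times=np.array(times),
        e_kinetic=np.array(ekins),
        e_potential=np.array(epots),
        e_coul=np.array(ecouls),
        e_lj=np.array(eljs),
        e_bonded=np.array(ebondeds),
        temperature=np.array(temps),
        volume=np.array(vols),
        pressure=np.array(press),
        config={
            "dt": dt, "n_steps": icfg.n_steps, "seed": icfg.seed,
            "save_interval": icfg.save_interval,
            "ensemble": "npt" if barostatted else ("nvt" if thermostatted else "nve"),
            "target_T": tcfg.target_T if thermostatted else None,
            "target_P": pcfg.target_P if barostatted else None,
        },
    )


def integrate_nvt(
    frame: Frame,
    top: SystemTopology,
    icfg: IntegratorConfig,
    tcfg: ThermostatConfig,
    cutoffs: Cutoffs = Cutoffs(),
    backend: str = "auto",
    neighbor: str = "brute",
) -> RunResult:
    """Leap-frog NVT with a stochastic velocity-rescale thermostat."""
    return _integrate(frame, top, icfg, tcfg, None, cutoffs, backend, neighbor)


def integrate_nve(
    frame: Frame,
    top: SystemTopology,
    icfg: IntegratorConfig,
    cutoffs: Cutoffs = Cutoffs(),
    backend: str = "auto",
    neighbor: str = "brute",
) -> RunResult:
    """Leap-frog NVE (no thermostat); validation mode for the integrator."""
    return _integrate(frame, top, icfg, None, None, cutoffs, backend, neighbor,
                      remove_com=False)


def integrate_npt(
    frame: Frame,
    top: SystemTopology,
    icfg: IntegratorConfig,
    tcfg: ThermostatConfig,
    pcfg: BarostatConfig,
    cutoffs: Cutoffs = Cutoffs(),
    backend: str = "auto",
    neighbor: str = "brute",
) -> RunResult:
    """NVT plus an isotropic weak-coupling barostat.  With
    ``pcfg.enabled=False`` or infinite tau_P this reduces to NVT."""
    return _integrate(frame, top, icfg, tcfg, pcfg, cutoffs, backend, neighbor)
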