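"""Mobility statistics: trajectory unwrapping, mean-squared displacement
of molecular centres of mass, and an Einstein-relation diffusion fit.

MSD(t) = (1/N) Σ_i ⟨|r_i(t) − r_i(0)|²⟩ over the N molecules of the
selected group, on unwrapped coordinates.  ⟨·⟩ is an average over
sliding time origins in ``multi`` mode (default) or the literal
single-origin displacement from the window start in ``single`` mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core.types import Frame, GroupSelection, Trajectory
from ..topology import SystemTopology

__all__ = [
    "MsdProfile",
    "DiffusionResult",
    "unwrap_trajectory",
    "msd",
    "diffusion_coefficient",
]


def unwrap_trajectory(traj: Trajectory, max_jump_fraction: float = 0.49):
    """Remove periodic jumps so coordinates are continuous in time.

    Frame-to-frame displacements are taken through the minimum image; a
    displacement whose fractional magnitude reaches ``max_jump_fraction``
    of the box is ambiguous (the atom may have crossed more than half a
    box between saves) and raises, advising denser trajectory saving.
    Re-wrapping the result modulo the box recovers the input.
    """
    frames = [traj[0].copy()]
    prev_raw = traj[0].positions
    prev_unwrapped = frames[0].positions
    for fr in traj.frames[1:]:
        if fr.box is None:
            raise ValueError("unwrap requires boxes on every frame")
        h = fr.box.lattice_vectors
        hinv = np.linalg.inv(h)
        ds = (fr.positions - prev_raw) @ hinv
        ds -= np.round(ds)
        if np.any(np.abs(ds) >= max_jump_fraction):
            raise ValueError(
                f"frame at t={fr.time} ps: displacement of "
                f"{np.max(np.abs(ds)):.2f} box fractions between saved frames; "
                "save the trajectory more densely before unwrapping"
            )
        unwrapped = prev_unwrapped + ds @ h
        frames.append(Frame(fr.time, unwrapped, box=fr.box,
                            velocities=fr.velocities))
        prev_raw = fr.positions
        prev_unwrapped = unwrapped
    return Trajectory(frames)


@dataclass
class MsdProfile:
    lag_times: np.ndarray   # ps
    msd: np.ndarray         # nm^2
    n_molecules: int
    origin_mode: str
    window: tuple[float, float]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"lag_ps": self.lag_times, "msd_nm2": self.msd})


def _molecule_coms(traj: Trajectory, top: SystemTopology,
                   group: GroupSelection) -> tuple[np.ndarray, np.ndarray]:
    """(n_frames, n_molecules, 3) COM array for the group's molecules."""
    mols = sorted(group.molecule_ids)
    idx_by_mol = []
    for m in mols:
        idx = np.array(
            [i for i in range(top.n_atoms)
             if top.molecule_ids[i] == m and i in group.atom_indices],
            dtype=np.intp,
        )
        if idx.size == 0:
            raise ValueError(f"molecule {m} contributes no atoms to the group")
        idx_by_mol.append(idx)
    coms = np.empty((len(traj), len(mols), 3))
    for k, fr in enumerate(traj):
        for m, idx in enumerate(idx_by_mol):
            w = top.masses[idx]
            coms[k, m] = (w[:, None] * fr.positions[idx]).sum(axis=0) / w.sum()
    return coms, np.array([f.time for f in traj])


def msd(
    traj: Trajectory,
    top: SystemTopology,
    group: GroupSelection,
    window: tuple[float, float] | None = None,
    origin_mode: str = "multi",
) -> MsdProfile:
    """MSD of the group's molecular centres of mass.

    The trajectory must already be unwrapped (see
    :func:`unwrap_trajectory`)."""
    if origin_mode not in ("multi", "single"):
        raise ValueError("origin_mode must be 'multi' or 'single'")
    sub = traj.window(*window) if window is not None else traj
    coms, times = _molecule_coms(sub, top, group)
    n_frames, n_mol, _ = coms.shape
    lags = times - times[0]
    if origin_mode == "single":
        disp = coms - coms[0]
        vals = np.einsum("kmj,kmj->k", disp, disp) / n_mol
    else:
        vals = np.zeros(n_frames)
        counts = np.zeros(n_frames)
        for lag in range(n_frames):
            d = coms[lag:] - coms[: n_frames - lag]
            vals[lag] = np.einsum("kmj,kmj->", d, d) / (n_mol * d.shape[0])
            counts[lag] = d.shape[0]
    return MsdProfile(
        lag_times=lags, msd=vals, n_molecules=n_mol,
        origin_mode=origin_mode,
        window=(float(times[0]), float(times[-1])),
    )


@dataclass
class DiffusionResult:
    d: float          # nm^2/ps
    r_squared: float
    slope: float
    intercept: float
    ballistic_flag: bool

    def __float__(self) -> float:
        return self.d


def diffusion_coefficient(
    profile: MsdProfile,
    fit_range: tuple[float, float] | None = None,
    r2_threshold: float = 0.98,
) -> DiffusionResult:
    """Einstein-relation estimate D = slope/6 from a least-squares line
    through MSD(t) over ``fit_range`` (ps).  Poor linearity (R² below
    the threshold, e.g. a ballistic t² regime) is flagged."""
    t, y = profile.lag_times, profile.msd
    if fit_range is not None:
        m = (t >= fit_range[0]) & (t <= fit_range[1])
        t, y = t[m], y[m]
    if len(t) < 5:
        raise ValueError("diffusion fit needs at least 5 points in range")
    if np.ptp(t) == 0:
        raise ValueError("degenerate fit range")
    slope, intercept = np.polyfit(t, y, 1)
    pred = slope * t + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return DiffusionResult(
        d=float(slope / 6.0), r_squared=r2, slope=float(slope),
        intercept=float(intercept), ballistic_flag=r2 < r2_threshold,
    )
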