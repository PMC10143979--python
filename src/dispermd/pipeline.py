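"""End-to-end orchestration at toy scale: the screening matrix
(APIs × excipients), the loading comparison, and the temperature sweep.

Every run is fully specified by the plan plus its seed: mixture packing,
velocity generation and the thermostat all derive their randomness from
the plan seeds, so any report is regenerable from plan + seeds alone.
Each stage of a system that fails is caught; the system is marked
incomplete and the rest of the matrix continues.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .analysis.dynamics import diffusion_coefficient, msd, unwrap_trajectory
from .analysis.energy import (
    ExcipientRecord,
    energy_ratio,
    group_interaction_energy,
    rank_excipients,
)
from .analysis.structure import HBondCriteria, detect_hbonds
from .core.selection import select_group
from .engine import (
    IntegratorConfig,
    MinimizerConfig,
    ThermostatConfig,
    init_velocities_mb,
    integrate_nvt,
    minimize_steepest_descent,
)
from .forcefield import Cutoffs
from .synthetic import build_mixture_box, build_polymer_chain, get_template

logger = logging.getLogger("dispermd.pipeline")

__all__ = [
    "ExperimentPlan",
    "run_system",
    "run_screening_matrix",
    "run_loading_study",
    "run_temperature_study",
]


@dataclass
class ExperimentPlan:
    """Declarative description of a study; serializable to/from dict."""

    apis: list[str] = field(default_factory=lambda: ["api_small_neutral"])
    excipients: list[str] = field(default_factory=lambda: ["exc_ester", "exc_acid"])
    wt_levels: list[float] = field(default_factory=lambda: [5.0])
    temperatures: list[float] = field(default_factory=lambda: [300.0])
    seeds: list[int] = field(default_factory=lambda: [1])
    n_monomers: int = 10
    n_api_by_wt: dict = field(default_factory=lambda: {5.0: 3, 50.0: 12})
    density: float = 0.65            # g/cc packing target
    dt: float = 0.002                # ps
    equil_ps: float = 2.0
    production_ps: float = 8.0
    save_interval_ps: float = 0.1
    cutoff_nm: float = 0.9
    hbond_d_max: float = 3.5         # Å
    hbond_alpha_max: float = 30.0    # degrees

    def n_api(self, wt: float) -> int:
        return int(self.n_api_by_wt.get(wt, self.n_api_by_wt.get(str(wt), 3)))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n_api_by_wt"] = {str(k): v for k, v in self.n_api_by_wt.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentPlan":
        d = dict(d)
        if "n_api_by_wt" in d:
            d["n_api_by_wt"] = {float(k): int(v) for k, v in d["n_api_by_wt"].items()}
        return cls(**d)

    @classmethod
    def from_config(cls, path) -> "ExperimentPlan":
        from .core.config import load_config

        cfg = load_config(path)
        return cls.from_dict(cfg.get("plan", cfg))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _system_seed(base_seed: int, label: str) -> int:
    """Stable per-system sub-seed derived from the base seed and label."""
    return (base_seed * 1_000_003 + zlib.crc32(label.encode())) % (2**31)


def run_system(
    plan: ExperimentPlan,
    api_name: str,
    excipient_name: str,
    wt: float,
    temperature: float,
    seed: int,
) -> dict:
    """Build → minimize → thermalize → NVT → analyze one system.

    The first 20% of the run is treated as equilibration; all analyses
    use the remaining window.  Returns a flat record dict.
    """
    label = f"{api_name}|{excipient_name}|{wt}wt|{temperature}K|{seed}"
    sseed = _system_seed(seed, label)
    api = get_template(api_name)
    chain = build_polymer_chain(get_template(excipient_name), plan.n_monomers)
    top, frame, info = build_mixture_box(
        api, plan.n_api(wt), chain, wt, density=plan.density, seed=sseed,
    )
    cut = Cutoffs(r_lj=plan.cutoff_nm, r_coul=plan.cutoff_nm)
    mres = minimize_steepest_descent(frame, top, MinimizerConfig(), cut)
    f0 = init_velocities_mb(mres.frame, top, temperature, seed=sseed + 1)
    total_ps = plan.equil_ps + plan.production_ps
    icfg = IntegratorConfig(
        dt=plan.dt,
        n_steps=int(round(total_ps / plan.dt)),
        save_interval=max(1, int(round(plan.save_interval_ps / plan.dt))),
        seed=sseed + 2,
    )
    run = integrate_nvt(f0, top, icfg, ThermostatConfig(target_T=temperature), cut)

    t_end = run.times[-1]
    window = (0.2 * t_end, t_end)
    g_api = select_group(top, f"resname {api.resname}", label="API")
    g_pol = select_group(top, f"resname {chain.resname}", label="polymer")
    e_ab = group_interaction_energy(run.trajectory, top, g_api, g_pol,
                                    window=window)
    e_aa = group_interaction_energy(run.trajectory, top, g_api, g_api,
                                    window=window)
    ratio = energy_ratio(e_ab, e_aa)
    hb = detect_hbonds(
        run.trajectory, top,
        HBondCriteria(plan.hbond_d_max, plan.hbond_alpha_max),
        g_api, g_pol, window=window,
    )
    unwrapped = unwrap_trajectory(run.trajectory)
    prof = msd(unwrapped, top, g_api, window=window, origin_mode="multi")
    msd_final = float(prof.msd[-1])
    try:
        fit_lo = 0.2 * prof.lag_times[-1]
        dcoef = diffusion_coefficient(prof, (fit_lo, prof.lag_times[-1])).d
    except ValueError:
        dcoef = float("nan")

    return {
        "label": label,
        "api": api_name,
        "excipient": excipient_name,
        "wt_percent": wt,
        "achieved_wt_percent": info["achieved_wt_percent"],
        "temperature": temperature,
        "seed": seed,
        "system_seed": sseed,
        "n_atoms": top.n_atoms,
        "mean_temperature": run.mean_temperature,
        "e_coul": e_ab.e_coul,
        "e_lj": e_ab.e_lj,
        "e_total": e_ab.e_total,
        "e_total_per_api": e_ab.e_total_per_molecule_a,
        "e_coul_per_api": e_ab.e_coul / e_ab.n_molecules_a,
        "e_lj_per_api": e_ab.e_lj / e_ab.n_molecules_a,
        "e_api_api": e_aa.e_total,
        "energy_ratio": ratio.ratio if ratio.valid else None,
        "ratio_valid": ratio.valid,
        "hbond_count": hb.mean_count,
        "hbond_per_api": hb.count_per_molecule,
        "msd_final_nm2": msd_final,
        "diffusion_nm2_per_ps": dcoef,
        "energy_result": e_ab,
        "self_energy_result": e_aa,
        "ratio_result": ratio,
    }


def _safe_run(plan, api, exc, wt, temp, seed):
    try:
        rec = run_system(plan, api, exc, wt, temp, seed)
        rec["status"] = "ok"
        return rec
    except Exception as exc_info:  # noqa: BLE001 - matrix must continue
        logger.error("system %s/%s failed: %s", api, exc, exc_info)
        return {
            "label": f"{api}|{exc}|{wt}wt|{temp}K|{seed}",
            "api": api, "excipient": exc, "wt_percent": wt,
            "temperature": temp, "seed": seed,
            "status": "failed", "error": str(exc_info),
        }


def run_screening_matrix(plan: ExperimentPlan) -> dict:
    """Run every API × excipient combination and rank excipients per API."""
    wt = plan.wt_levels[0]
    temp = plan.temperatures[0]
    seed = plan.seeds[0]
    systems = []
    reports = {}
    for api in plan.apis:
        records = []
        for exc in plan.excipients:
            rec = _safe_run(plan, api, exc, wt, temp, seed)
            systems.append(rec)
            if rec["status"] == "ok":
                records.append(
                    ExcipientRecord(
                        excipient=exc,
                        energy=rec["energy_result"],
                        ratio=rec["ratio_result"],
                        hbond_count=rec["hbond_per_api"],
                    )
                )
        if len(records) >= 2:
            reports[api] = rank_excipients(api, records)
    return {
        "kind": "screening",
        "plan_hash": plan.config_hash(),
        "plan": plan.to_dict(),
        "systems": systems,
        "reports": reports,
        "complete": all(s["status"] == "ok" for s in systems),
    }


def run_loading_study(plan: ExperimentPlan) -> dict:
    """Compare the first API–excipient pair across wt% levels and seeds.

    Reports per-API energies, energy ratios and MSD, plus deltas of
    seed-means between consecutive loadings."""
    api, exc = plan.apis[0], plan.excipients[0]
    temp = plan.temperatures[0]
    systems = []
    by_wt: dict[float, list[dict]] = {w: [] for w in plan.wt_levels}
    for wt in plan.wt_levels:
        for seed in plan.seeds:
            rec = _safe_run(plan, api, exc, wt, temp, seed)
            systems.append(rec)
            if rec["status"] == "ok":
                by_wt[wt].append(rec)

    def seed_mean(rows, key):
        vals = [r[key] for r in rows if r.get(key) is not None]
        return float(np.mean(vals)) if vals else None

    summary = {
        wt: {
            "n_ok": len(rows),
            "e_total_per_api": seed_mean(rows, "e_total_per_api"),
            "energy_ratio": seed_mean(rows, "energy_ratio"),
            "msd_final_nm2": seed_mean(rows, "msd_final_nm2"),
            "hbond_per_api": seed_mean(rows, "hbond_per_api"),
        }
        for wt, rows in by_wt.items()
    }
    deltas = {}
    levels = sorted(plan.wt_levels)
    for lo, hi in zip(levels, levels[1:]):
        key = f"{lo}->{hi}"
        deltas[key] = {
            stat: (
                summary[hi][stat] - summary[lo][stat]
                if summary[hi][stat] is not None and summary[lo][stat] is not None
                else None
            )
            for stat in ("e_total_per_api", "energy_ratio", "msd_final_nm2")
        }
    return {
        "kind": "loading",
        "plan_hash": plan.config_hash(),
        "plan": plan.to_dict(),
        "api": api,
        "excipient": exc,
        "systems": systems,
        "summary": summary,
        "deltas": deltas,
        "complete": all(s["status"] == "ok" for s in systems),
    }


def run_temperature_study(plan: ExperimentPlan) -> dict:
    """Sweep the first API–excipient pair across temperatures and seeds."""
    api, exc = plan.apis[0], plan.excipients[0]
    wt = plan.wt_levels[0]
    systems = []
    by_t: dict[float, list[dict]] = {t: [] for t in plan.temperatures}
    for temp in plan.temperatures:
        for seed in plan.seeds:
            rec = _safe_run(plan, api, exc, wt, temp, seed)
            systems.append(rec)
            if rec["status"] == "ok":
                by_t[temp].append(rec)

    def seed_mean(rows, key):
        vals = [r[key] for r in rows if r.get(key) is not None]
        return float(np.mean(vals)) if vals else None

    summary = {
        t: {
            "n_ok": len(rows),
            "e_total_per_api": seed_mean(rows, "e_total_per_api"),
            "energy_ratio": seed_mean(rows, "energy_ratio"),
            "msd_final_nm2": seed_mean(rows, "msd_final_nm2"),
        }
        for t, rows in by_t.items()
    }
    return {
        "kind": "temperature",
        "plan_hash": plan.config_hash(),
        "plan": plan.to_dict(),
        "api": api,
        "excipient": exc,
        "systems": systems,
        "summary": summary,
        "complete": all(s["status"] == "ok" for s in systems),
    }


# ----------------------------------------------------------------------
# Report output
# ----------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()
                if not hasattr(v, "per_frame_total") and k not in
                ("energy_result", "self_energy_result", "ratio_result", "reports")}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_report(report: dict, out_dir, name: str) -> dict[str, Path]:
    """Write a study report as JSON (+ per-system CSV + Markdown)."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    clean = _jsonable(report)
    if "reports" in report:
        clean["reports"] = {k: v.to_dict() for k, v in report["reports"].items()}
    jp = out_dir / f"{name}.json"
    jp.write_text(json.dumps(clean, indent=2, sort_keys=True))
    paths["json"] = jp

    rows = [
        {k: v for k, v in s.items()
         if k not in ("energy_result", "self_energy_result", "ratio_result")}
        for s in report.get("systems", [])
    ]
    if rows:
        cp = out_dir / f"{name}.csv"
        pd.DataFrame(rows).to_csv(cp, index=False)
        paths["csv"] = cp

    md = [f"# {report['kind']} study", "",
          f"plan hash: `{report['plan_hash']}`",
          f"complete: {report.get('complete')}", ""]
    if "reports" in report:
        for rep in report["reports"].values():
            md.append(rep.to_markdown())
            md.append("")
    if "summary" in report:
        md.append("## Summary (seed means)")
        for key, stats in report["summary"].items():
            md.append(f"- **{key}**: " + ", ".join(
                f"{k}={v:.4g}" if isinstance(v, float) else f"{k}={v}"
                for k, v in stats.items()))
    mp = out_dir / f"{name}.md"
    mp.write_text("\n".join(md) + "\n")
    paths["md"] = mp
    return paths
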