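"""Group–group interaction energies, the energy ratio, and excipient
ranking — the screening statistics.

Interaction energies are real-space pairwise LJ + Coulomb sums within
the cutoff (no reciprocal-space term, no energy shift by default),
computed per frame over the analysis window and averaged.  Attractive
interactions are negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..core.types import GroupSelection, Trajectory
from ..forcefield import Cutoffs, _pair_scales
from ..topology import SystemTopology
from ..units import F_COUL

__all__ = [
    "InteractionEnergyResult",
    "EnergyRatioResult",
    "ScreeningReport",
    "group_interaction_energy",
    "energy_ratio",
    "rank_excipients",
]

ANALYSIS_CUTOFFS = Cutoffs(r_lj=1.4, r_coul=1.4, shift_coul=False, shift_lj=False)


@dataclass
class InteractionEnergyResult:
    """Time-averaged nonbonded interaction energy between two groups."""

    group_a: str
    group_b: str
    e_coul: float
    e_lj: float
    n_frames: int
    std_error: float
    n_molecules_a: int
    n_molecules_b: int
    per_frame_total: np.ndarray = field(repr=False, default=None)

    @property
    def e_total(self) -> float:
        return self.e_coul + self.e_lj

    @property
    def e_total_per_molecule_a(self) -> float:
        """Total divided by the molecule count of group a (per-API view)."""
        return self.e_total / self.n_molecules_a

    def to_dict(self) -> dict:
        return {
            "group_a": self.group_a,
            "group_b": self.group_b,
            "e_coul": self.e_coul,
            "e_lj": self.e_lj,
            "e_total": self.e_total,
            "e_total_per_molecule_a": self.e_total_per_molecule_a,
            "n_frames": self.n_frames,
            "std_error": self.std_error,
        }


@dataclass
class EnergyRatioResult:
    """E_total(a–b) / E_total(a–a); valid only when both are attractive
    and the denominator is above the noise floor."""

    ratio: float
    numerator: float
    denominator: float
    valid: bool
    reason: str = ""

    def to_dict(self) -> dict:
        return {
            "ratio": self.ratio if self.valid else None,
            "numerator": self.numerator,
            "denominator": self.denominator,
            "valid": self.valid,
            "reason": self.reason,
        }


def _pair_arrays(top: SystemTopology, group_a: GroupSelection,
                 group_b: GroupSelection):
    """Static pair index/scale arrays between two groups.

    Same-group mode (identical atom sets) pairs atoms of *different*
    molecules only.  Exclusions and 1-4 scaling are honored.
    """
    ia = group_a.indices
    ib = group_b.indices
    same = group_a.atom_indices == group_b.atom_indices
    if not same and not group_a.isdisjoint(group_b):
        raise ValueError(
            f"groups {group_a.label!r} and {group_b.label!r} share atoms; "
            "interaction energy requires disjoint groups (or identical for "
            "self-interaction)"
        )
    if same:
        iu, ju = np.meshgrid(ia, ib, indexing="ij")
        iu, ju = iu.ravel(), ju.ravel()
        keep = iu < ju
        iu, ju = iu[keep], ju[keep]
        mol = top.molecule_ids
        keep = mol[iu] != mol[ju]
        iu, ju = iu[keep], ju[keep]
    else:
        iu, ju = np.meshgrid(ia, ib, indexing="ij")
        iu, ju = iu.ravel(), ju.ravel()

    lj_scale = np.ones(len(iu))
    coul_scale = np.ones(len(iu))
    scales = _pair_scales(top)
    if scales.excl_set or scales.s14_set:
        n = top.n_atoms
        lo = np.minimum(iu, ju).astype(np.int64)
        hi = np.maximum(iu, ju).astype(np.int64)
        keys = lo * n + hi
        if scales.excl_set:
            ek = np.array(sorted(i * n + j for i, j in scales.excl_set), dtype=np.int64)
            m = np.isin(keys, ek)
            lj_scale[m] = 0.0
            coul_scale[m] = 0.0
        if scales.s14_set:
            sk = np.array(sorted(i * n + j for i, j in scales.s14_set), dtype=np.int64)
            m = np.isin(keys, sk)
            lj_scale[m] = top.fudge_lj
            coul_scale[m] = top.fudge_coul
    return iu, ju, lj_scale, coul_scale


def group_interaction_energy(
    traj: Trajectory,
    top: SystemTopology,
    group_a: GroupSelection,
    group_b: GroupSelection,
    cutoffs: Cutoffs = ANALYSIS_CUTOFFS,
    window: tuple[float, float] | None = None,
    n_blocks: int = 5,
) -> InteractionEnergyResult:
    """Mean E_coul/E_LJ/E_total between two groups over a time window.

    Per frame, pairwise terms are summed over (i ∈ a, j ∈ b) within the
    cutoff under the minimum image; for a == b (identical selections)
    intramolecular pairs are excluded and each intermolecular pair is
    counted once.  The standard error is from block averaging.
    """
    sub = traj.window(*window) if window is not None else traj
    iu, ju, lj_scale, coul_scale = _pair_arrays(top, group_a, group_b)

    sig = np.sqrt(top.sigmas[iu] * top.sigmas[ju])
    eps = np.sqrt(top.epsilons[iu] * top.epsilons[ju]) * lj_scale
    qq = top.charges[iu] * top.charges[ju] * coul_scale

    e_coul_frames = np.empty(len(sub))
    e_lj_frames = np.empty(len(sub))
    for k, fr in enumerate(sub):
        if fr.box is None:
            raise ValueError("interaction energy requires a periodic box")
        dr = fr.box.minimum_image(fr.positions[ju] - fr.positions[iu])
        r = np.sqrt(np.einsum("ij,ij->i", dr, dr))
        with np.errstate(divide="ignore"):
            inv_r = np.where(r > 0, 1.0 / r, 0.0)
        in_lj = r <= cutoffs.r_lj
        sr6 = np.where(in_lj, (sig * inv_r) ** 6, 0.0)
        e_lj_pair = 4.0 * eps * (sr6 * sr6 - sr6)
        if cutoffs.shift_lj:
            src6 = (sig / cutoffs.r_lj) ** 6
            e_lj_pair -= np.where(in_lj, 4.0 * eps * (src6 * src6 - src6), 0.0)
        in_coul = r <= cutoffs.r_coul
        e_coul_pair = np.where(in_coul, F_COUL * qq * inv_r, 0.0)
        if cutoffs.shift_coul:
            e_coul_pair -= np.where(in_coul, F_COUL * qq / cutoffs.r_coul, 0.0)
        e_lj_frames[k] = e_lj_pair.sum()
        e_coul_frames[k] = e_coul_pair.sum()

    total = e_lj_frames + e_coul_frames
    nb = min(n_blocks, len(sub))
    blocks = np.array_split(total, nb)
    block_means = np.array([b.mean() for b in blocks])
    se = float(block_means.std(ddof=1) / np.sqrt(nb)) if nb > 1 else 0.0
    return InteractionEnergyResult(
        group_a=group_a.label,
        group_b=group_b.label,
        e_coul=float(e_coul_frames.mean()),
        e_lj=float(e_lj_frames.mean()),
        n_frames=len(sub),
        std_error=se,
        n_molecules_a=len(group_a.molecule_ids),
        n_molecules_b=len(group_b.molecule_ids),
        per_frame_total=total,
    )


def energy_ratio(
    e_ab: InteractionEnergyResult,
    e_aa: InteractionEnergyResult,
    denominator_floor: float = 1.0,
) -> EnergyRatioResult:
    """Relative-affinity statistic E_total(a–b)/E_total(a–a).

    Defined (valid) when the denominator is attractive and above the
    floor and the numerator is not repulsive; then the ratio is ≥ 0.
    """
    num, den = e_ab.e_total, e_aa.e_total
    if abs(den) < denominator_floor:
        return EnergyRatioResult(
            ratio=float("nan"), numerator=num, denominator=den, valid=False,
            reason=f"|denominator| < {denominator_floor} kJ/mol",
        )
    if den > 0:
        return EnergyRatioResult(
            ratio=float("nan"), numerator=num, denominator=den, valid=False,
            reason="self-interaction is repulsive",
        )
    if num > 0:
        return EnergyRatioResult(
            ratio=float("nan"), numerator=num, denominator=den, valid=False,
            reason="cross-interaction is repulsive",
        )
    return EnergyRatioResult(
        ratio=num / den, numerator=num, denominator=den, valid=True
    )


@dataclass
class ExcipientRecord:
    excipient: str
    energy: InteractionEnergyResult
    ratio: EnergyRatioResult
    hbond_count: float = 0.0


@dataclass
class ScreeningReport:
    """Per-API ranking of excipients by E_total (most negative first);
    ties broken by larger energy ratio, then by H-bond count."""

    api: str
    records: list[ExcipientRecord]

    @property
    def ranking(self) -> list[ExcipientRecord]:
        def key(r: ExcipientRecord):
            ratio = r.ratio.ratio if r.ratio.valid else float("-inf")
            return (r.energy.e_total, -ratio, -r.hbond_count)

        return sorted(self.records, key=key)

    @property
    def best(self) -> ExcipientRecord:
        return self.ranking[0]

    def to_dict(self) -> dict:
        return {
            "api": self.api,
            "best_excipient": self.best.excipient,
            "ranking": [
                {
                    "excipient": r.excipient,
                    "e_total": r.energy.e_total,
                    "e_coul": r.energy.e_coul,
                    "e_lj": r.energy.e_lj,
                    "energy_ratio": r.ratio.ratio if r.ratio.valid else None,
                    "hbond_count": r.hbond_count,
                }
                for r in self.ranking
            ],
        }

    def to_markdown(self) -> str:
        lines = [
            f"## Screening report: {self.api}",
            "",
            "| rank | excipient | E_total | E_coul | E_LJ | ratio | H-bonds |",
            "|------|-----------|---------|--------|------|-------|---------|",
        ]
        for k, r in enumerate(self.ranking, start=1):
            ratio = f"{r.ratio.ratio:.3f}" if r.ratio.valid else "n/a"
            lines.append(
                f"| {k} | {r.excipient} | {r.energy.e_total:.2f} | "
                f"{r.energy.e_coul:.2f} | {r.energy.e_lj:.2f} | {ratio} | "
                f"{r.hbond_count:.2f} |"
            )
        lines.append("")
        lines.append(f"Selected pair: {self.api}–{self.best.excipient}")
        return "\n".join(lines)


def rank_excipients(api: str, records: list[ExcipientRecord]) -> ScreeningReport:
    """Rank ≥2 candidate excipients for one API."""
    if len(records) < 2:
        raise ValueError("ranking requires at least two excipients")
    return ScreeningReport(api=api, records=list(records))
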