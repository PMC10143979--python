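import numpy as np
import pytest

from dispermd.analysis.energy import (
    ExcipientRecord,
    EnergyRatioResult,
    InteractionEnergyResult,
    energy_ratio,
    group_interaction_energy,
    rank_excipients,
)
from dispermd.core.selection import select_group
from dispermd.core.types import Frame, GroupSelection, SimulationBox, Trajectory
from dispermd.forcefield import Cutoffs, system_potential
from dispermd.topology import SystemTopology
from dispermd.units import F_COUL

from conftest import make_lj_topology


def ion_pair_system(r=0.5):
    top = SystemTopology(
        names=["NA", "CL"], elements=["Na", "Cl"],
        charges=[1.0, -1.0], sigmas=[0.33, 0.44], epsilons=[0.012, 0.42],
        masses=[22.99, 35.45], molecule_ids=[0, 1],
        residue_names=["CAT", "ANI"],
    )
    pos = np.array([[1.5, 1.5, 1.5], [1.5 + r, 1.5, 1.5]])
    traj = Trajectory([Frame(0.0, pos, box=SimulationBox.cubic(3.0))])
    return top, traj


class TestGroupInteractionEnergy:
    def test_ion_pair_closed_form(self):
        """+1/−1 at 0.5 nm, one frame: E_coul = −2f exactly."""
        top, traj = ion_pair_system(0.5)
        ga = select_group(top, "resname CAT", label="cation")
        gb = select_group(top, "resname ANI", label="anion")
        res = group_interaction_energy(traj, top, ga, gb)
        assert res.e_coul == pytest.approx(-2.0 * F_COUL, rel=1e-12)
        sig = np.sqrt(0.33 * 0.44)
        eps = np.sqrt(0.012 * 0.42)
        sr6 = (sig / 0.5) ** 6
        assert res.e_lj == pytest.approx(4 * eps * (sr6**2 - sr6), rel=1e-12)
        assert res.e_total == res.e_coul + res.e_lj

    def test_beyond_cutoff_zero(self):
        top = make_lj_topology(2)
        top.residue_names = ["A", "B"]
        top.molecule_ids = np.array([0, 1])
        pos = np.array([[0.2, 0.2, 0.2], [1.9, 0.2, 0.2]])  # min-img r = 1.7
        traj = Trajectory([Frame(float(t), pos, box=SimulationBox.cubic(3.6))
                           for t in range(3)])
        ga = select_group(top, "resname A")
        gb = select_group(top, "resname B")
        res = group_interaction_energy(traj, top, ga, gb,
                                       Cutoffs(1.4, 1.4, shift_coul=False))
        assert res.e_total == 0.0

    def test_matches_brute_force_over_frames(self, tiny_mixture, rng):
        """Equals an independent per-frame double loop to 1e-9."""
        top, frame, _ = tiny_mixture
        frames = []
        for k in range(5):
            jitter = rng.normal(0, 0.01, frame.positions.shape)
            frames.append(Frame(float(k), frame.positions + jitter,
                                box=frame.box))
        traj = Trajectory(frames)
        ga = select_group(top, "resname SMN", label="api")
        gb = select_group(top, "resname EPE", label="pol")
        cut = Cutoffs(r_lj=0.8, r_coul=0.8, shift_coul=False)
        res = group_interaction_energy(traj, top, ga, gb, cut)

        # oracle: python double loop over group pairs, each frame
        excl = top.exclusions()
        edge = frame.box.lattice_vectors[0, 0]
        e_lj_frames, e_coul_frames = [], []
        for fr in frames:
            e_lj = e_coul = 0.0
            for i in sorted(ga.atom_indices):
                for j in sorted(gb.atom_indices):
                    if (min(i, j), max(i, j)) in excl:
                        continue
                    dr = fr.positions[j] - fr.positions[i]
                    dr -= edge * np.round(dr / edge)
                    r = np.linalg.norm(dr)
                    if r <= 0.8:
                        sig = np.sqrt(top.sigmas[i] * top.sigmas[j])
                        eps = np.sqrt(top.epsilons[i] * top.epsilons[j])
                        sr6 = (sig / r) ** 6
                        e_lj += 4 * eps * (sr6 * sr6 - sr6)
                        e_coul += F_COUL * top.charges[i] * top.charges[j] / r
            e_lj_frames.append(e_lj)
            e_coul_frames.append(e_coul)
        assert res.e_lj == pytest.approx(np.mean(e_lj_frames), rel=1e-9)
        assert res.e_coul == pytest.approx(np.mean(e_coul_frames), rel=1e-9)

    def test_self_interaction_excludes_intramolecular(self, tiny_mixture):
        top, frame, info = tiny_mixture
        traj = Trajectory([frame])
        ga = select_group(top, "resname SMN", label="api")
        res = group_interaction_energy(traj, top, ga, ga,
                                       Cutoffs(0.8, 0.8, shift_coul=False))
        # oracle: only pairs across different API molecules
        edge = frame.box.lattice_vectors[0, 0]
        idx = sorted(ga.atom_indices)
        e = 0.0
        for x, i in enumerate(idx):
            for j in idx[x + 1:]:
                if top.molecule_ids[i] == top.molecule_ids[j]:
                    continue
                dr = frame.positions[j] - frame.positions[i]
                dr -= edge * np.round(dr / edge)
                r = np.linalg.norm(dr)
                if r <= 0.8:
                    sig = np.sqrt(top.sigmas[i] * top.sigmas[j])
                    eps = np.sqrt(top.epsilons[i] * top.epsilons[j])
                    sr6 = (sig / r) ** 6
                    e += 4 * eps * (sr6 * sr6 - sr6)
                    e += F_COUL * top.charges[i] * top.charges[j] / r
        assert res.e_total == pytest.approx(e, rel=1e-9, abs=1e-12)

    def test_overlapping_groups_rejected(self, tiny_mixture):
        top, frame, _ = tiny_mixture
        traj = Trajectory([frame])
        ga = select_group(top, "resname SMN", label="a")
        gb = GroupSelection("b", ga.atom_indices | {200}, frozenset({0}))
        with pytest.raises(ValueError, match="share atoms"):
            group_interaction_energy(traj, top, ga, gb)

    def test_empty_window_rejected(self, tiny_mixture):
        top, frame, _ = tiny_mixture
        traj = Trajectory([frame])
        ga = select_group(top, "resname SMN")
        gb = select_group(top, "resname EPE")
        with pytest.raises(ValueError, match="empty"):
            group_interaction_energy(traj, top, ga, gb, window=(5.0, 9.0))

    def test_label_swap_symmetry(self, tiny_mixture):
        top, frame, _ = tiny_mixture
        traj = Trajectory([frame])
        ga = select_group(top, "resname SMN", label="a")
        gb = select_group(top, "resname EPE", label="b")
        cut = Cutoffs(0.8, 0.8, shift_coul=False)
        r_ab = group_interaction_energy(traj, top, ga, gb, cut)
        r_ba = group_interaction_energy(traj, top, gb, ga, cut)
        assert r_ab.e_total == pytest.approx(r_ba.e_total, rel=1e-12)

    def test_partition_decomposition(self, tiny_mixture):
        """within(a) + within(b) + between(a,b) = system nonbonded."""
        top, frame, _ = tiny_mixture
        traj = Trajectory([frame])
        cut = Cutoffs(r_lj=0.8, r_coul=0.8, shift_coul=False)
        ga = select_group(top, "resname SMN", label="a")
        gb = select_group(top, "resname EPE", label="b")
        e_ab = group_interaction_energy(traj, top, ga, gb, cut)
        e_aa = group_interaction_energy(traj, top, ga, ga, cut)
        e_bb = group_interaction_energy(traj, top, gb, gb, cut)
        # intramolecular (within single molecules) remainder
        whole = system_potential(frame, top, cut, include_bonded=False)
        g_all = select_group(top, "resname SMN EPE", label="all")
        e_intra_inter = group_interaction_energy(traj, top, g_all, g_all, cut)
        # e_intra_inter covers all intermolecular pairs: aa + bb + ab
        assert e_intra_inter.e_total == pytest.approx(
            e_aa.e_total + e_bb.e_total + e_ab.e_total, rel=1e-9
        )
        # whole system adds the intramolecular nonbonded part
        intra = whole.e_nonbonded - e_intra_inter.e_total
        # recompute intramolecular by brute force to close the loop
        edge = frame.box.lattice_vectors[0, 0]
        excl = top.exclusions()
        s14 = top.scaled_pairs()
        e_intra = 0.0
        for i in range(top.n_atoms):
            for j in range(i + 1, top.n_atoms):
                if top.molecule_ids[i] != top.molecule_ids[j]:
                    continue
                if (i, j) in excl:
                    continue
                scale = top.fudge_lj if (i, j) in s14 else 1.0
                scale_c = top.fudge_coul if (i, j) in s14 else 1.0
                dr = frame.positions[j] - frame.positions[i]
                dr -= edge * np.round(dr / edge)
                r = np.linalg.norm(dr)
                if r <= 0.8:
                    sig = np.sqrt(top.sigmas[i] * top.sigmas[j])
                    eps = np.sqrt(top.epsilons[i] * top.epsilons[j]) * scale
                    sr6 = (sig / r) ** 6
                    e_intra += 4 * eps * (sr6 * sr6 - sr6)
                    e_intra += F_COUL * top.charges[i] * top.charges[j] * scale_c / r
        assert intra == pytest.approx(e_intra, rel=1e-9, abs=1e-9)


class TestEnergyRatio:
    def r(self, e_total):
        return InteractionEnergyResult(
            group_a="a", group_b="b", e_coul=e_total, e_lj=0.0,
            n_frames=10, std_error=0.0, n_molecules_a=1, n_molecules_b=1,
        )

    def test_basic(self):
        out = energy_ratio(self.r(-100.0), self.r(-50.0))
        assert out.valid
        assert out.ratio == pytest.approx(2.0)

    def test_zero_numerator(self):
        out = energy_ratio(self.r(0.0), self.r(-50.0))
        assert out.valid
        assert out.ratio == 0.0

    def test_small_denominator_flagged(self):
        out = energy_ratio(self.r(-100.0), self.r(-0.5))
        assert not out.valid
        assert "denominator" in out.reason

    def test_repulsive_denominator_flagged(self):
        out = energy_ratio(self.r(-100.0), self.r(50.0))
        assert not out.valid

    def test_ratio_recomputation_consistency(self, tiny_mixture):
        """Ratio from averaged energies equals ratio recomputed from the
        raw per-frame sums."""
        top, frame, _ = tiny_mixture
        traj = Trajectory([frame])
        cut = Cutoffs(0.8, 0.8, shift_coul=False)
        ga = select_group(top, "resname SMN", label="a")
        gb = select_group(top, "resname EPE", label="b")
        e_ab = group_interaction_energy(traj, top, ga, gb, cut)
        e_aa = group_interaction_energy(traj, top, ga, ga, cut)
        out = energy_ratio(e_ab, e_aa)
        if out.valid:
            raw = float(np.mean(e_ab.per_frame_total)) / float(
                np.mean(e_aa.per_frame_total)
            )
            assert out.ratio == pytest.approx(raw, rel=1e-12)


class TestRanking:
    def rec(self, name, e_total, ratio=1.0, hb=0.0):
        energy = InteractionEnergyResult(
            group_a="api", group_b=name, e_coul=e_total, e_lj=0.0,
            n_frames=1, std_error=0.0, n_molecules_a=1, n_molecules_b=1,
        )
        r = EnergyRatioResult(ratio=ratio, numerator=e_total,
                              denominator=e_total / ratio if ratio else -1,
                              valid=True)
        return ExcipientRecord(name, energy, r, hb)

    def test_most_negative_first(self):
        rep = rank_excipients("api", [
            self.rec("X", -10.0), self.rec("Y", -20.0), self.rec("Z", -30.0),
        ])
        assert [r.excipient for r in rep.ranking] == ["Z", "Y", "X"]
        assert rep.best.excipient == "Z"
        assert rep.best.energy.e_total == -30.0

    def test_tie_broken_by_ratio(self):
        rep = rank_excipients("api", [
            self.rec("X", -10.0, ratio=0.5), self.rec("Y", -10.0, ratio=1.5),
        ])
        assert rep.best.excipient == "Y"

    def test_tie_broken_by_hbonds_last(self):
        rep = rank_excipients("api", [
            self.rec("X", -10.0, ratio=1.0, hb=0.2),
            self.rec("Y", -10.0, ratio=1.0, hb=2.0),
        ])
        assert rep.best.excipient == "Y"

    def test_planted_winner_fixture(self):
        """Constructed 3-excipient fixture where B dominates."""
        rep = rank_excipients("api", [
            self.rec("A", -55.0, 0.8, 1.0),
            self.rec("B", -120.0, 1.9, 3.0),
            self.rec("C", -80.0, 1.2, 2.0),
        ])
        assert rep.best.excipient == "B"
        assert "B" in rep.to_markdown()
        assert rep.to_dict()["best_excipient"] == "B"

    def test_requires_two(self):
        with pytest.raises(ValueError):
            rank_excipients("api", [self.rec("X", -1.0)])
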