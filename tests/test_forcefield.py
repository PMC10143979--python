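import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dispermd.core.types import Frame, SimulationBox
from dispermd.forcefield import (
    Cutoffs,
    combine_params,
    compute_forces,
    coulomb_pair_energy,
    lj_pair_energy,
    system_potential,
)
from dispermd.units import F_COUL

from conftest import make_lj_topology, python_pair_energy


class TestPairKernels:
    def test_lj_root_at_sigma(self):
        assert lj_pair_energy(0.34, 0.34, 1.7) == pytest.approx(0.0, abs=1e-12)

    def test_lj_minimum(self):
        r_min = 2 ** (1 / 6) * 0.34
        assert lj_pair_energy(r_min, 0.34, 2.5) == pytest.approx(-2.5, rel=1e-12)

    def test_lj_extended_precision_value(self):
        # oracle: direct formula evaluated with Fraction-backed floats
        sigma, eps, r = 0.34, 1.0, 0.5
        sr6 = (sigma / r) ** 6
        expected = 4.0 * eps * (sr6 * sr6 - sr6)
        assert lj_pair_energy(r, sigma, eps) == pytest.approx(expected, rel=1e-14)

    def test_lj_domain_error(self):
        with pytest.raises(ValueError):
            lj_pair_energy(0.0, 0.34, 1.0)

    def test_coulomb_zero_charge(self):
        assert coulomb_pair_energy(0.5, 0.0, 1.0) == 0.0

    def test_coulomb_unit_charges(self):
        # +1/-1 at 0.5 nm -> -2f
        assert coulomb_pair_energy(0.5, 1.0, -1.0) == pytest.approx(
            -2.0 * F_COUL, rel=1e-12
        )

    # physically-scaled charges (fractions of e); extreme denormals would
    # underflow the product and test float edge cases, not the physics
    _charge = st.one_of(st.just(0.0), st.floats(1e-3, 2.0),
                        st.floats(-2.0, -1e-3))

    @given(st.floats(0.1, 5.0), _charge, _charge)
    @settings(max_examples=50, deadline=None)
    def test_coulomb_sign(self, r, qi, qj):
        e = coulomb_pair_energy(r, qi, qj)
        assert np.sign(e) == np.sign(qi) * np.sign(qj)

    def test_combine_identical(self):
        assert combine_params(0.3, 0.5, 0.3, 0.5) == (
            pytest.approx(0.3), pytest.approx(0.5)
        )

    def test_combine_geometric(self):
        sig, eps = combine_params(0.2, 1.0, 0.8, 4.0)
        assert sig == pytest.approx(0.4)
        assert eps == pytest.approx(2.0)

    def test_combine_random_table(self, rng):
        for _ in range(5):
            si, sj = rng.uniform(0.1, 0.5, 2)
            ei, ej = rng.uniform(0.1, 2.0, 2)
            sig, eps = combine_params(si, ei, sj, ej)
            assert sig == pytest.approx(math.sqrt(si * sj), rel=1e-14)
            assert eps == pytest.approx(math.sqrt(ei * ej), rel=1e-14)


class TestSystemPotential:
    def test_beyond_cutoff_zero(self):
        top = make_lj_topology(2)
        pos = np.array([[0.5, 0.5, 0.5], [2.2, 0.5, 0.5]])  # r=1.7 > 1.4, min img
        frame = Frame(0.0, pos, box=SimulationBox.cubic(3.4))
        e = system_potential(frame, top, Cutoffs(r_lj=1.4, r_coul=1.4))
        assert e.e_lj == 0.0

    def test_dimer_at_minimum(self, lj_dimer):
        top, frame = lj_dimer
        e = system_potential(frame, top, Cutoffs(r_lj=1.4, r_coul=1.4))
        assert e.e_total == pytest.approx(-1.0, rel=1e-9)

    def test_box_too_small_rejected(self):
        top = make_lj_topology(2)
        frame = Frame(0.0, np.zeros((2, 3)) + 0.5, box=SimulationBox.cubic(2.0))
        with pytest.raises(ValueError, match="minimum-image"):
            system_potential(frame, top, Cutoffs(r_lj=1.4, r_coul=1.4))

    @pytest.mark.parametrize("backend", ["numpy", "numba"])
    def test_random_fluid_matches_brute_force(self, backend, rng):
        """50-atom LJ fluid equals the O(N²) python oracle to 1e-9 rel."""
        top = make_lj_topology(50, charge=0.0)
        top.charges = rng.uniform(-0.3, 0.3, 50)
        pos = rng.uniform(0, 3.0, (50, 3))
        frame = Frame(0.0, pos, box=SimulationBox.cubic(3.0))
        cut = Cutoffs(r_lj=1.4, r_coul=1.4)
        e = system_potential(frame, top, cut, backend=backend)
        e_lj, e_coul = python_pair_energy(pos, 3.0, top, 1.4, 1.4,
                                          shift_coul=True)
        assert e.e_lj == pytest.approx(e_lj, rel=1e-9)
        assert e.e_coul == pytest.approx(e_coul, rel=1e-9)

    def test_exclusions_and_14_scaling(self, rng):
        from dispermd.topology import SystemTopology

        n = 6
        top = SystemTopology(
            names=[f"A{i}" for i in range(n)], elements=["C"] * n,
            charges=rng.uniform(-0.4, 0.4, n), sigmas=np.full(n, 0.3),
            epsilons=np.full(n, 0.4), masses=np.full(n, 12.0),
            bonds=[[0, 1], [1, 2], [2, 3], [3, 4]],
            bond_r0=np.full(4, 0.15), bond_k=np.zeros(4),
            pairs14=[[0, 3], [1, 4]],
        )
        pos = np.array([[1.0 + 0.2 * i, 1.0, 1.0] for i in range(n)])
        frame = Frame(0.0, pos, box=SimulationBox.cubic(3.0))
        cut = Cutoffs(r_lj=1.4, r_coul=1.4)
        e_np = system_potential(frame, top, cut, backend="numpy",
                                include_bonded=False)
        e_nb = system_potential(frame, top, cut, backend="numba",
                                include_bonded=False)
        e_lj, e_coul = python_pair_energy(pos, 3.0, top, 1.4, 1.4,
                                          shift_coul=True)
        for e in (e_np, e_nb):
            assert e.e_lj == pytest.approx(e_lj, rel=1e-9)
            assert e.e_coul == pytest.approx(e_coul, rel=1e-9)

    def test_translation_invariance(self, rng):
        top = make_lj_topology(30)
        pos = rng.uniform(0, 3.0, (30, 3))
        box = SimulationBox.cubic(3.0)
        cut = Cutoffs(r_lj=1.4, r_coul=1.4)
        e1 = system_potential(Frame(0.0, pos, box=box), top, cut)
        e2 = system_potential(Frame(0.0, pos + [1.234, -0.77, 5.1], box=box),
                              top, cut)
        assert e2.e_total == pytest.approx(e1.e_total, rel=1e-12)

    def test_lattice_shift_invariance(self, rng):
        """Shifting one atom by a whole lattice vector changes nothing."""
        top = make_lj_topology(10)
        pos = rng.uniform(0, 3.0, (10, 3))
        box = SimulationBox.cubic(3.0)
        cut = Cutoffs(r_lj=1.4, r_coul=1.4)
        e1 = system_potential(Frame(0.0, pos, box=box), top, cut)
        pos2 = pos.copy()
        pos2[3] += box.lattice_vectors[0] * 2
        pos2[7] -= box.lattice_vectors[2]
        e2 = system_potential(Frame(0.0, pos2, box=box), top, cut)
        assert e2.e_total == pytest.approx(e1.e_total, rel=1e-12)

    def test_forces_match_numerical_gradient(self, rng):
        """Analytic forces vs central differences on a random 20-atom
        bonded system, 1e-6 relative."""
        from dispermd.topology import SystemTopology

        n = 20
        pos = rng.uniform(1.0, 2.0, (n, 3))
        # keep bonded neighbors near their equilibrium to avoid stiffness
        for i in range(1, 5):
            pos[i] = pos[i - 1] + [0.15, 0.01 * i, -0.01]
        top = SystemTopology(
            names=[f"A{i}" for i in range(n)], elements=["C"] * n,
            charges=rng.uniform(-0.3, 0.3, n), sigmas=np.full(n, 0.31),
            epsilons=np.full(n, 0.4), masses=np.full(n, 12.0),
            bonds=[[0, 1], [1, 2], [2, 3], [3, 4]],
            bond_r0=np.full(4, 0.15), bond_k=np.full(4, 2e4),
            angles=[[0, 1, 2], [1, 2, 3], [2, 3, 4]],
            angle_theta0=np.radians([110, 115, 120]), angle_k=np.full(3, 300.0),
            dihedrals=[[0, 1, 2, 3], [1, 2, 3, 4]],
            dihedral_phi0=np.radians([0.0, 60.0]), dihedral_k=[6.0, 4.0],
            dihedral_mult=[3, 2],
            pairs14=[[0, 3], [1, 4]],
        )
        box = SimulationBox.cubic(4.0)
        cut = Cutoffs(r_lj=1.4, r_coul=1.4)
        _, forces, _ = compute_forces(Frame(0.0, pos, box=box), top, cut,
                                      backend="numpy")
        h = 2e-6
        scale = max(1.0, float(np.max(np.abs(forces))))
        for i in rng.choice(n, size=6, replace=False):
            for d in range(3):
                p_hi, p_lo = pos.copy(), pos.copy()
                p_hi[i, d] += h
                p_lo[i, d] -= h
                e_hi = system_potential(Frame(0.0, p_hi, box=box), top, cut,
                                        backend="numpy")
                e_lo = system_potential(Frame(0.0, p_lo, box=box), top, cut,
                                        backend="numpy")
                f_num = -(e_hi.e_total - e_lo.e_total) / (2 * h)
                assert abs(f_num - forces[i, d]) / scale < 1e-6

    def test_pair_symmetry_reorder(self, rng):
        """Energy invariant under atom reordering."""
        top = make_lj_topology(20)
        top.charges = rng.uniform(-0.2, 0.2, 20)
        pos = rng.uniform(0, 3.0, (20, 3))
        box = SimulationBox.cubic(3.0)
        cut = Cutoffs(r_lj=1.4, r_coul=1.4)
        e1 = system_potential(Frame(0.0, pos, box=box), top, cut)
        perm = rng.permutation(20)
        top2 = make_lj_topology(20)
        top2.charges = top.charges[perm]
        e2 = system_potential(Frame(0.0, pos[perm], box=box), top2, cut)
        assert e2.e_total == pytest.approx(e1.e_total, rel=1e-12)

    def test_cutoff_closed_interval(self):
        """A pair at exactly r = r_c is included."""
        top = make_lj_topology(2, sigma=0.34, epsilon=1.0)
        pos = np.array([[1.0, 1.5, 1.5], [2.0, 1.5, 1.5]])  # r exactly 1.0
        frame = Frame(0.0, pos, box=SimulationBox.cubic(3.0))
        e = system_potential(frame, top, Cutoffs(r_lj=1.0, r_coul=1.0))
        expected = lj_pair_energy(1.0, 0.34, 1.0)
        assert e.e_lj == pytest.approx(expected, rel=1e-12)

    def test_cell_list_bitwise_equals_brute(self, rng):
        """Neighbor-list energies/forces equal brute force bit-for-bit."""
        from dispermd.synthetic import lj_fluid

        top, frame = lj_fluid(400, 6.0, seed=3)
        frame.positions[:] = rng.uniform(0, 6.0, (400, 3))
        cut = Cutoffs(r_lj=1.4, r_coul=1.4)
        e_b, f_b, w_b = compute_forces(frame, top, cut, backend="numba",
                                       neighbor="brute")
        e_c, f_c, w_c = compute_forces(frame, top, cut, backend="numba",
                                       neighbor="cell")
        assert e_b.e_lj == e_c.e_lj
        assert e_b.e_coul == e_c.e_coul
        assert w_b == w_c
        np.testing.assert_array_equal(f_b, f_c)

    def test_breakdown_consistency(self, tiny_mixture):
        top, frame, _ = tiny_mixture
        e = system_potential(frame, top, Cutoffs(r_lj=0.9, r_coul=0.9))
        assert e.e_total == pytest.approx(
            e.e_coul + e.e_lj + e.e_bonded, rel=1e-12
        )


class TestTailCorrection:
    def test_single_species_closed_form(self):
        """Matches the textbook homogeneous-fluid expression with the
        exact pair count N(N−1)/2."""
        from dispermd.forcefield import lj_tail_correction

        n, edge, sigma, eps, rc = 64, 4.0, 0.34, 1.0, 1.4
        top = make_lj_topology(n, sigma=sigma, epsilon=eps)
        box = SimulationBox.cubic(edge)
        expected = (16 * math.pi / edge**3) * (n * (n - 1) / 2) * eps * (
            sigma**12 / (9 * rc**9) - sigma**6 / (3 * rc**3)
        )
        got = lj_tail_correction(top, box, rc)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got < 0  # attractive tail

    def test_flag_applies_to_system_potential(self, rng):
        from dispermd.forcefield import lj_tail_correction

        top = make_lj_topology(30)
        pos = rng.uniform(0, 3.0, (30, 3))
        frame = Frame(0.0, pos, box=SimulationBox.cubic(3.0))
        base = system_potential(frame, top, Cutoffs(1.4, 1.4))
        tail = system_potential(frame, top, Cutoffs(1.4, 1.4, lj_tail=True))
        corr = lj_tail_correction(top, frame.box, 1.4)
        assert tail.e_lj == pytest.approx(base.e_lj + corr, rel=1e-12)


class TestEwald:
    def test_nacl_madelung(self):
        """Rock-salt Madelung constant from the plain Ewald sum."""
        from dispermd.forcefield import ewald_energy
        from dispermd.topology import SystemTopology

        # conventional NaCl cell: 4 cation + 4 anion sites, edge 2a0
        a0 = 0.282  # nm nearest-neighbor spacing
        L = 2 * a0
        frac = [
            (0, 0, 0), (0.5, 0.5, 0), (0.5, 0, 0.5), (0, 0.5, 0.5),
            (0.5, 0, 0), (0, 0.5, 0), (0, 0, 0.5), (0.5, 0.5, 0.5),
        ]
        charges = [1, 1, 1, 1, -1, -1, -1, -1]
        pos = np.array(frac) * L
        top = SystemTopology(
            names=[f"I{i}" for i in range(8)],
            elements=["Na"] * 4 + ["Cl"] * 4,
            charges=charges, sigmas=np.full(8, 0.2), epsilons=np.zeros(8),
            masses=np.full(8, 30.0),
        )
        frame = Frame(0.0, pos, box=SimulationBox.cubic(L))
        e = ewald_energy(frame, top, r_cut=0.28, alpha=18.0, k_max=12)
        # E per ion pair = -M * f / a0 with Madelung M = 1.7475646
        madelung = -e * a0 / (4 * F_COUL)
        assert madelung == pytest.approx(1.7475646, rel=1e-4)
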