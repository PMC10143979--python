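"""Shared fixtures.  All test inputs are generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from dispermd.core.types import Frame, SimulationBox
from dispermd.forcefield import Cutoffs
from dispermd.synthetic import (
    build_mixture_box,
    build_polymer_chain,
    get_template,
    lj_fluid,
)
from dispermd.topology import SystemTopology


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


def make_lj_topology(n, sigma=0.34, epsilon=1.0, mass=39.95, charge=0.0):
    return SystemTopology(
        names=[f"A{i}" for i in range(n)],
        elements=["Ar"] * n,
        charges=np.full(n, charge),
        sigmas=np.full(n, sigma),
        epsilons=np.full(n, epsilon),
        masses=np.full(n, mass),
        molecule_ids=np.arange(n),
        residue_names=["LJF"] * n,
    )


@pytest.fixture()
def lj_dimer():
    """Two LJ atoms at the potential minimum separation."""
    top = make_lj_topology(2)
    r_min = 2.0 ** (1.0 / 6.0) * 0.34
    pos = np.array([[1.5, 1.5, 1.5], [1.5 + r_min, 1.5, 1.5]])
    return top, Frame(0.0, pos, box=SimulationBox.cubic(3.0))


@pytest.fixture(scope="session")
def lj_fluid_200():
    """200-atom LJ fluid fixture (3 nm box)."""
    return lj_fluid(200, 3.0, seed=7)


@pytest.fixture(scope="session")
def small_cutoffs():
    return Cutoffs(r_lj=0.9, r_coul=0.9)


@pytest.fixture(scope="session")
def tiny_mixture():
    """A small API/polymer mixture box shared across analysis tests."""
    chain = build_polymer_chain(get_template("exc_ester"), 4)
    api = get_template("api_small_neutral")
    top, frame, info = build_mixture_box(
        api, 4, chain, 25.0, density=0.45, seed=11
    )
    return top, frame, info


def python_pair_energy(pos, box_edge, top, rc_lj, rc_coul,
                       shift_lj=False, shift_coul=True):
    """Slow, independent O(N²) double-loop oracle (cubic box only)."""
    from dispermd.units import F_COUL

    excl = top.exclusions()
    s14 = top.scaled_pairs()
    n = len(pos)
    e_lj = e_coul = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            key = (i, j)
            if key in excl:
                continue
            f_lj = top.fudge_lj if key in s14 else 1.0
            f_cl = top.fudge_coul if key in s14 else 1.0
            dr = pos[j] - pos[i]
            dr = dr - box_edge * np.round(dr / box_edge)
            r = float(np.linalg.norm(dr))
            if r <= rc_lj and top.epsilons[i] * top.epsilons[j] > 0:
                sig = np.sqrt(top.sigmas[i] * top.sigmas[j])
                eps = np.sqrt(top.epsilons[i] * top.epsilons[j]) * f_lj
                sr6 = (sig / r) ** 6
                e_lj += 4 * eps * (sr6 * sr6 - sr6)
                if shift_lj:
                    sc6 = (sig / rc_lj) ** 6
                    e_lj -= 4 * eps * (sc6 * sc6 - sc6)
            qq = top.charges[i] * top.charges[j] * f_cl
            if r <= rc_coul and qq != 0.0:
                e_coul += F_COUL * qq / r
                if shift_coul:
                    e_coul -= F_COUL * qq / rc_coul
    return e_lj, e_coul
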