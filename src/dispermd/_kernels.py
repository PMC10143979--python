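"""Numba-compiled nonbonded kernels.

Two pair-iteration strategies evaluate the same inner-pair physics
(kept textually identical in both loops — edit together):

* brute force: for each i, all j > i in ascending order;
* cell list: for each i, candidate j > i gathered from the 27 neighbor
  cells and sorted ascending before evaluation.

Because skipped (out-of-cutoff) pairs contribute exactly 0.0 and both
paths visit contributing pairs in the same (i, ascending-j) order, the
two strategies accumulate floating-point sums identically and are
bit-for-bit equal.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return deco


F_COUL = 138.935458


@njit(cache=True, fastmath=False, inline="always")
def _pair_scale(i, j, excl_ptr, excl_idx, s14_ptr, s14_idx):
    """0 = excluded, 1 = full, 2 = scaled 1-4 (binary search per atom)."""
    lo, hi = excl_ptr[i], excl_ptr[i + 1]
    while lo < hi:
        mid = (lo + hi) // 2
        v = excl_idx[mid]
        if v == j:
            return 0
        elif v < j:
            lo = mid + 1
        else:
            hi = mid
    lo, hi = s14_ptr[i], s14_ptr[i + 1]
    while lo < hi:
        mid = (lo + hi) // 2
        v = s14_idx[mid]
        if v == j:
            return 2
        elif v < j:
            lo = mid + 1
        else:
            hi = mid
    return 1


@njit(cache=True, fastmath=False)
def _nonbonded_brute(
    pos, h, hinv, charges, sigma, eps,
    excl_ptr, excl_idx, s14_ptr, s14_idx,
    fudge_lj, fudge_coul, rc_lj, rc_coul, shift_lj, shift_coul,
):
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    e_lj = 0.0
    e_coul = 0.0
    virial = 0.0
    rc_lj2 = rc_lj * rc_lj
    rc_coul2 = rc_coul * rc_coul
    for i in range(n):
        for j in range(i + 1, n):
            sc = _pair_scale(i, j, excl_ptr, excl_idx, s14_ptr, s14_idx)
            if sc == 0:
                continue
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            sx = dx * hinv[0, 0] + dy * hinv[1, 0] + dz * hinv[2, 0]
            sy = dx * hinv[0, 1] + dy * hinv[1, 1] + dz * hinv[2, 1]
            sz = dx * hinv[0, 2] + dy * hinv[1, 2] + dz * hinv[2, 2]
            sx -= np.floor(sx + 0.5)
            sy -= np.floor(sy + 0.5)
            sz -= np.floor(sz + 0.5)
            dx = sx * h[0, 0] + sy * h[1, 0] + sz * h[2, 0]
            dy = sx * h[0, 1] + sy * h[1, 1] + sz * h[2, 1]
            dz = sx * h[0, 2] + sy * h[1, 2] + sz * h[2, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 > rc_lj2 and r2 > rc_coul2:
                continue
            f_lj = fudge_lj if sc == 2 else 1.0
            f_cl = fudge_coul if sc == 2 else 1.0
            inv_r2 = 1.0 / r2
            f_over_r = 0.0
            if r2 <= rc_lj2:
                e = eps[i] * eps[j]
                if e > 0.0:
                    epsij = np.sqrt(e) * f_lj
                    sig2 = sigma[i] * sigma[j] * inv_r2
                    sr6 = sig2 * sig2 * sig2
                    e_lj += 4.0 * epsij * (sr6 * sr6 - sr6)
                    if shift_lj:
                        sc2 = sigma[i] * sigma[j] / rc_lj2
                        src6 = sc2 * sc2 * sc2
                        e_lj -= 4.0 * epsij * (src6 * src6 - src6)
                    f_over_r += 24.0 * epsij * (2.0 * sr6 * sr6 - sr6) * inv_r2
            if r2 <= rc_coul2:
                qq = charges[i] * charges[j] * f_cl
                if qq != 0.0:
                    inv_r = np.sqrt(inv_r2)
                    e_coul += F_COUL * qq * inv_r
                    if shift_coul:
                        e_coul -= F_COUL * qq / rc_coul
                    f_over_r += F_COUL * qq * inv_r * inv_r2
            if f_over_r != 0.0:
                fx = f_over_r * dx
                fy = f_over_r * dy
                fz = f_over_r * dz
                forces[j, 0] += fx
                forces[j, 1] += fy
                forces[j, 2] += fz
                forces[i, 0] -= fx
                forces[i, 1] -= fy
                forces[i, 2] -= fz
                virial += f_over_r * r2
    return e_lj, e_coul, forces, virial


@njit(cache=True, fastmath=False)
def _nonbonded_cells(
    pos, h, hinv, charges, sigma, eps,
    excl_ptr, excl_idx, s14_ptr, s14_idx,
    fudge_lj, fudge_coul, rc_lj, rc_coul, shift_lj, shift_coul,
    skin,
):
    """Cell-list pair search; falls back to brute force when fewer than
    3 cells fit along any axis."""
    n = pos.shape[0]
    rc = max(rc_lj, rc_coul) + skin
    frac = np.empty((n, 3))
    for i in range(n):
        for d in range(3):
            frac[i, d] = (
                pos[i, 0] * hinv[0, d] + pos[i, 1] * hinv[1, d] + pos[i, 2] * hinv[2, d]
            )
            frac[i, d] -= np.floor(frac[i, d])
    # perpendicular width of the box along each fractional axis
    ncell = np.empty(3, dtype=np.int64)
    vol = np.abs(np.linalg.det(h))
    for d in range(3):
        a = h[(d + 1) % 3]
        b = h[(d + 2) % 3]
        cx = a[1] * b[2] - a[2] * b[1]
        cy = a[2] * b[0] - a[0] * b[2]
        cz = a[0] * b[1] - a[1] * b[0]
        width = vol / np.sqrt(cx * cx + cy * cy + cz * cz)
        ncell[d] = max(1, int(width / rc))
    if ncell[0] < 3 or ncell[1] < 3 or ncell[2] < 3:
        return _nonbonded_brute(
            pos, h, hinv, charges, sigma, eps,
            excl_ptr, excl_idx, s14_ptr, s14_idx,
            fudge_lj, fudge_coul, rc_lj, rc_coul, shift_lj, shift_coul,
        )
    ntot = ncell[0] * ncell[1] * ncell[2]
    cell_of = np.empty(n, dtype=np.int64)
    count = np.zeros(ntot, dtype=np.int64)
    for i in range(n):
        cx = min(int(frac[i, 0] * ncell[0]), ncell[0] - 1)
        cy = min(int(frac[i, 1] * ncell[1]), ncell[1] - 1)
        cz = min(int(frac[i, 2] * ncell[2]), ncell[2] - 1)
        c = (cx * ncell[1] + cy) * ncell[2] + cz
        cell_of[i] = c
        count[c] += 1
    start = np.zeros(ntot + 1, dtype=np.int64)
    for c in range(ntot):
        start[c + 1] = start[c] + count[c]
    fill = start[:-1].copy()
    members = np.empty(n, dtype=np.int64)
    for i in range(n):
        members[fill[cell_of[i]]] = i
        fill[cell_of[i]] += 1

    forces = np.zeros((n, 3))
    e_lj = 0.0
    e_coul = 0.0
    virial = 0.0
    rc_lj2 = rc_lj * rc_lj
    rc_coul2 = rc_coul * rc_coul
    buf = np.empty(n, dtype=np.int64)
    for i in range(n):
        c = cell_of[i]
        cz0 = c % ncell[2]
        cy0 = (c // ncell[2]) % ncell[1]
        cx0 = c // (ncell[1] * ncell[2])
        m = 0
        for ox in range(-1, 2):
            ccx = (cx0 + ox) % ncell[0]
            for oy in range(-1, 2):
                ccy = (cy0 + oy) % ncell[1]
                for oz in range(-1, 2):
                    ccz = (cz0 + oz) % ncell[2]
                    cc = (ccx * ncell[1] + ccy) * ncell[2] + ccz
                    for p in range(start[cc], start[cc + 1]):
                        jj = members[p]
                        if jj > i:
                            buf[m] = jj
                            m += 1
        cand = np.sort(buf[:m])
        for p in range(m):
            j = cand[p]
            # --- identical pair physics to _nonbonded_brute ---
            sc = _pair_scale(i, j, excl_ptr, excl_idx, s14_ptr, s14_idx)
            if sc == 0:
                continue
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            sx = dx * hinv[0, 0] + dy * hinv[1, 0] + dz * hinv[2, 0]
            sy = dx * hinv[0, 1] + dy * hinv[1, 1] + dz * hinv[2, 1]
            sz = dx * hinv[0, 2] + dy * hinv[1, 2] + dz * hinv[2, 2]
            sx -= np.floor(sx + 0.5)
            sy -= np.floor(sy + 0.5)
            sz -= np.floor(sz + 0.5)
            dx = sx * h[0, 0] + sy * h[1, 0] + sz * h[2, 0]
            dy = sx * h[0, 1] + sy * h[1, 1] + sz * h[2, 1]
            dz = sx * h[0, 2] + sy * h[1, 2] + sz * h[2, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 > rc_lj2 and r2 > rc_coul2:
                continue
            f_lj = fudge_lj if sc == 2 else 1.0
            f_cl = fudge_coul if sc == 2 else 1.0
            inv_r2 = 1.0 / r2
            f_over_r = 0.0
            if r2 <= rc_lj2:
                e = eps[i] * eps[j]
                if e > 0.0:
                    epsij = np.sqrt(e) * f_lj
                    sig2 = sigma[i] * sigma[j] * inv_r2
                    sr6 = sig2 * sig2 * sig2
                    e_lj += 4.0 * epsij * (sr6 * sr6 - sr6)
                    if shift_lj:
                        sc2 = sigma[i] * sigma[j] / rc_lj2
                        src6 = sc2 * sc2 * sc2
                        e_lj -= 4.0 * epsij * (src6 * src6 - src6)
                    f_over_r += 24.0 * epsij * (2.0 * sr6 * sr6 - sr6) * inv_r2
            if r2 <= rc_coul2:
                qq = charges[i] * charges[j] * f_cl
                if qq != 0.0:
                    inv_r = np.sqrt(inv_r2)
                    e_coul += F_COUL * qq * inv_r
                    if shift_coul:
                        e_coul -= F_COUL * qq / rc_coul
                    f_over_r += F_COUL * qq * inv_r * inv_r2
            if f_over_r != 0.0:
                fx = f_over_r * dx
                fy = f_over_r * dy
                fz = f_over_r * dz
                forces[j, 0] += fx
                forces[j, 1] += fy
                forces[j, 2] += fz
                forces[i, 0] -= fx
                forces[i, 1] -= fy
                forces[i, 2] -= fz
                virial += f_over_r * r2
    return e_lj, e_coul, forces, virial


def nonbonded(
    pos, h, charges, sigma, eps,
    excl_ptr, excl_idx, s14_ptr, s14_idx,
    fudge_lj, fudge_coul, rc_lj, rc_coul, shift_lj, shift_coul,
    use_cells=False,
):
    """Dispatch wrapper returning (e_lj, e_coul, forces, virial)."""
    hinv = np.ascontiguousarray(np.linalg.inv(h))
    h = np.ascontiguousarray(h, dtype=np.float64)
    args = (
        np.ascontiguousarray(pos), h, hinv,
        np.ascontiguousarray(charges, dtype=np.float64),
        np.ascontiguousarray(sigma, dtype=np.float64),
        np.ascontiguousarray(eps, dtype=np.float64),
        excl_ptr, excl_idx, s14_ptr, s14_idx,
        float(fudge_lj), float(fudge_coul),
        float(rc_lj), float(rc_coul), bool(shift_lj), bool(shift_coul),
    )
    if use_cells:
        e_lj, e_coul, forces, w = _nonbonded_cells(*args, 0.0)
    else:
        e_lj, e_coul, forces, w = _nonbonded_brute(*args)
    return e_lj, e_coul, forces, w
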