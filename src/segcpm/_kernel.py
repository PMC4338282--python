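"""Compiled Monte Carlo core.

One Monte Carlo step (MCS) performs as many copy attempts as there are
lattice sites: each attempt draws a uniform random target site and a uniform
random Moore-8 neighbour as source; if the two identities differ and neither
site is wall, the energy change of copying the source identity into the
target site is computed incrementally and the copy is accepted with the
Metropolis probability ``1`` if ``dH <= 0`` else ``exp(-dH / T)``.

Randomness comes from an inlined xorshift64* generator so that trajectories
are bit-reproducible for a given seed, independent of NumPy/Numba internals.

The kernel is specialised per J-modification mechanism (codes: 0 none,
1 graded, 2 axial, 3 opposing gradients): the effective-J function is baked
in as a compile-time constant, which lets LLVM strip the unused mechanism
code from the hot loop (a runtime mechanism switch in the pair-energy
function costs ~5x in throughput).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

WALL = -1

MECH_NONE = 0
MECH_GRADED = 1
MECH_AXIAL = 2
MECH_GRADIENT = 3

# Moore-8 offsets; the neighbour index is drawn as (rng & 7)
_DX = np.array([-1, 0, 1, -1, 1, -1, 0, 1], dtype=np.int64)
_DY = np.array([-1, -1, -1, 0, 0, 1, 1, 1], dtype=np.int64)

_INV_2_53 = 1.0 / 9007199254740992.0  # 2^-53
_XS_MULT = np.uint64(2685821657736338717)


def seed_rng_state(seed: int) -> np.ndarray:
    """Derive a non-zero xorshift64* state from an integer seed (splitmix64)."""
    z = (int(seed) + 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
    z = z ^ (z >> 31)
    return np.array([z or 1], dtype=np.uint64)


@njit(inline="always")
def _rng_next(rng_state):
    s = rng_state[0]
    s ^= s >> np.uint64(12)
    s ^= s << np.uint64(25)
    s ^= s >> np.uint64(27)
    rng_state[0] = s
    return s * _XS_MULT


# ---------------------------------------------------------------------------
# effective pair energies (one variant per mechanism)
#
# signature: (sa, sb, x, y, Jtab, ctype, area, sum_x, sum_y, conc_b,
#             gauss_col, beta, mm) -> float
# Mechanisms modify cell-cell contacts only, never cell-medium.

@njit(inline="always")
def _pair_j_none(sa, sb, x, y, Jtab, ctype, area, sum_x, sum_y, conc_b,
                 gauss_col, beta, mm):
    return Jtab[ctype[sa], ctype[sb]]


@njit(inline="always")
def _pair_j_graded(sa, sb, x, y, Jtab, ctype, area, sum_x, sum_y, conc_b,
                   gauss_col, beta, mm):
    J = Jtab[ctype[sa], ctype[sb]]
    if sa != 0 and sb != 0:
        J -= gauss_col[x]
    return J


@njit(inline="always")
def _pair_j_axial(sa, sb, x, y, Jtab, ctype, area, sum_x, sum_y, conc_b,
                  gauss_col, beta, mm):
    J = Jtab[ctype[sa], ctype[sb]]
    if sa != 0 and sb != 0:
        vax = x - sum_x[sa] / area[sa]
        vay = y - sum_y[sa] / area[sa]
        vbx = x - sum_x[sb] / area[sb]
        vby = y - sum_y[sb] / area[sb]
        la = math.hypot(vax, vay)
        lb = math.hypot(vbx, vby)
        if la > 0.0 and lb > 0.0:
            J -= 0.5 * beta * (abs(vay) / la) * (abs(vby) / lb)
    return J


@njit(inline="always")
def _pair_j_gradient(sa, sb, x, y, Jtab, ctype, area, sum_x, sum_y, conc_b,
                     gauss_col, beta, mm):
    J = Jtab[ctype[sa], ctype[sb]]
    if sa != 0 and sb != 0:
        bi = conc_b[sa]
        bj = conc_b[sb]
        if not (math.isnan(bi) or math.isnan(bj)):
            J -= mm * (min(1.0 - bi, 1.0 - bj) + min(bi, bj))
    return J


_PAIR_J_FUNCS = {
    MECH_NONE: _pair_j_none,
    MECH_GRADED: _pair_j_graded,
    MECH_AXIAL: _pair_j_axial,
    MECH_GRADIENT: _pair_j_gradient,
}


@njit(inline="always")
def _persistence_term(sig, x, y, area, sum_x, sum_y, tdir_x, tdir_y, mu):
    """mu * cos(zeta): zeta is the angle between the cell's target direction
    and the vector from its centroid to the target site."""
    a = area[sig]
    vx = x - sum_x[sig] / a
    vy = y - sum_y[sig] / a
    norm = math.hypot(vx, vy)
    if norm == 0.0 or math.isnan(tdir_x[sig]):
        return 0.0
    return mu * (tdir_x[sig] * vx + tdir_y[sig] * vy) / norm


@njit(cache=True)
def sample_acceptance(dh, temp, n, rng_state):
    """Apply the kernel's Metropolis acceptance rule ``n`` times to a fixed
    energy change, drawing from the kernel RNG; returns the accept count."""
    accepts = 0
    for _ in range(n):
        if dh <= 0.0:
            accepts += 1
        else:
            u = float(_rng_next(rng_state) >> np.uint64(11)) * _INV_2_53
            if u < math.exp(-dh / temp):
                accepts += 1
    return accepts


def _make_delta_h(pair_j):
    @njit(inline="always")
    def dh_impl(flat, width, idx, x, y, sig_s, Jtab, ctype, area,
                target_area, sum_x, sum_y, conc_b, lam, gauss_col, beta, mm):
        sig_t = flat[idx]
        dh = 0.0
        for k in range(8):
            sig_n = flat[idx + _DY[k] * width + _DX[k]]
            if sig_n == WALL:
                continue
            if sig_n != sig_t:
                dh -= pair_j(sig_t, sig_n, x, y, Jtab, ctype, area, sum_x,
                             sum_y, conc_b, gauss_col, beta, mm)
            if sig_n != sig_s:
                dh += pair_j(sig_s, sig_n, x, y, Jtab, ctype, area, sum_x,
                             sum_y, conc_b, gauss_col, beta, mm)
        # quadratic area penalty, expanded incrementally:
        # (a+1-A)^2 - (a-A)^2 = 2(a-A)+1 ; (a-1-A)^2 - (a-A)^2 = -2(a-A)+1
        if sig_s != 0:
            dh += lam * float(2 * (area[sig_s] - target_area[sig_s]) + 1)
        if sig_t != 0:
            dh += lam * float(-2 * (area[sig_t] - target_area[sig_t]) + 1)
        return dh
    return dh_impl


def _make_delta_h_entry(dh_impl):
    @njit(cache=True)
    def dh_entry(sites, x, y, sig_s, Jtab, ctype, area, target_area,
                 sum_x, sum_y, conc_b, lam, gauss_col, beta, mm):
        width = sites.shape[1]
        flat = sites.ravel()
        return dh_impl(flat, width, y * width + x, x, y, sig_s, Jtab, ctype,
                       area, target_area, sum_x, sum_y, conc_b, lam,
                       gauss_col, beta, mm)
    return dh_entry


def _make_run_mcs(dh_impl):
    @njit(cache=True)
    def run_impl(sites, area, target_area, ctype, conc_b, sum_x, sum_y,
                 tdir_x, tdir_y, anchor_x, anchor_y,
                 Jtab, lam, temp, gauss_col, beta, mm,
                 pers_on, mu, s_interval, bias_retraction,
                 n_mcs, mcs_start, rng_state, counters):
        height, width = sites.shape
        flat = sites.ravel()
        n_sites = height * width
        n_sites_u = np.uint64(n_sites)
        t32 = np.uint64(32)
        seven = np.uint64(7)
        n_slots = area.shape[0]
        nulls = np.int64(0)
        accepts = np.int64(0)
        offs = np.empty(8, dtype=np.int64)
        for k in range(8):
            offs[k] = _DY[k] * width + _DX[k]
        s = rng_state[0]
        for m in range(n_mcs):
            for _ in range(n_sites):
                s ^= s >> np.uint64(12)
                s ^= s << np.uint64(25)
                s ^= s >> np.uint64(27)
                r = s * _XS_MULT
                # index from the high 32 bits (multiply-shift); the low
                # 3 bits pick the neighbour
                idx = np.int64(((r >> t32) * n_sites_u) >> t32)
                sig_t = flat[idx]
                if sig_t == WALL:
                    nulls += 1
                    continue
                k = np.int64(r & seven)
                sig_s = flat[idx + offs[k]]
                if sig_s == sig_t or sig_s == WALL:
                    nulls += 1
                    continue
                y = idx // width
                x = idx - y * width
                dh = dh_impl(flat, width, idx, x, y, sig_s, Jtab, ctype,
                             area, target_area, sum_x, sum_y, conc_b, lam,
                             gauss_col, beta, mm)
                if pers_on:
                    if sig_s != 0:
                        dh -= _persistence_term(sig_s, x, y, area, sum_x,
                                                sum_y, tdir_x, tdir_y, mu)
                    if bias_retraction and sig_t != 0:
                        dh += _persistence_term(sig_t, x, y, area, sum_x,
                                                sum_y, tdir_x, tdir_y, mu)
                if dh <= 0.0:
                    accept = True
                else:
                    s ^= s >> np.uint64(12)
                    s ^= s << np.uint64(25)
                    s ^= s >> np.uint64(27)
                    u = float((s * _XS_MULT) >> np.uint64(11)) * _INV_2_53
                    accept = u < math.exp(-dh / temp)
                if accept:
                    flat[idx] = sig_s
                    if sig_s != 0:
                        area[sig_s] += 1
                        sum_x[sig_s] += x
                        sum_y[sig_s] += y
                    if sig_t != 0:
                        area[sig_t] -= 1
                        sum_x[sig_t] -= x
                        sum_y[sig_t] -= y
                    accepts += 1
            mcs = mcs_start + m + 1
            if pers_on and mcs % s_interval == 0:
                for c in range(1, n_slots):
                    if area[c] > 0 and ctype[c] != 0:
                        cx = sum_x[c] / area[c]
                        cy = sum_y[c] / area[c]
                        dx = cx - anchor_x[c]
                        dy = cy - anchor_y[c]
                        d = math.hypot(dx, dy)
                        if d > 0.0:
                            tdir_x[c] = dx / d
                            tdir_y[c] = dy / d
                        anchor_x[c] = cx
                        anchor_y[c] = cy
        rng_state[0] = s
        counters[0] += np.int64(n_mcs) * np.int64(n_sites)
        counters[1] += nulls
        counters[2] += accepts
        return counters
    return run_impl


_DH_IMPLS = {code: _make_delta_h(fn) for code, fn in _PAIR_J_FUNCS.items()}
_DH_ENTRIES = {code: _make_delta_h_entry(impl)
               for code, impl in _DH_IMPLS.items()}
_RUN_IMPLS = {code: _make_run_mcs(impl) for code, impl in _DH_IMPLS.items()}


def delta_h(sites, x, y, sig_s, Jtab, ctype, area, target_area,
            sum_x, sum_y, conc_b, lam, mech, gauss_col, beta, mm):
    """Exact change in the Hamiltonian caused by copying identity ``sig_s``
    into site (x, y), computed from the 8 contact pairs touching the target
    site plus the two area terms.  Dispatches to the mechanism-specialised
    compiled implementation."""
    return float(_DH_ENTRIES[int(mech)](
        sites, x, y, sig_s, Jtab, ctype, area, target_area,
        sum_x, sum_y, conc_b, lam, gauss_col, beta, mm))


def run_mcs(sites, area, target_area, ctype, conc_b, sum_x, sum_y,
            tdir_x, tdir_y, anchor_x, anchor_y,
            Jtab, lam, temp, mech, gauss_col, beta, mm,
            pers_on, mu, s_interval, bias_retraction,
            n_mcs, mcs_start, rng_state, counters):
    """Advance the state by ``n_mcs`` Monte Carlo steps in place.

    counters: int64[3] accumulating (attempts, null attempts, accepted
    copies).  Target-direction updates run at every global MCS multiple of
    ``s_interval`` while persistence is enabled.
    """
    return _RUN_IMPLS[int(mech)](
        sites, area, target_area, ctype, conc_b, sum_x, sum_y,
        tdir_x, tdir_y, anchor_x, anchor_y,
        Jtab, lam, temp, gauss_col, beta, mm,
        pers_on, mu, s_interval, bias_retraction,
        n_mcs, mcs_start, rng_state, counters)
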