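"""Numba-compiled inner loops for pair-force accumulation.

The kernel is the per-step hot path: for every candidate pair it evaluates
the shifted pair potential's analytic force and scatters equal-and-opposite
force vectors, so Newton's third law holds pair-wise exactly by construction.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# shifted-distance floor, as a fraction of d_eq (see potential.MIN_GAP_FACTOR)
_MIN_GAP_FACTOR = 0.05
# pairs closer than this (um) indicate a blown-up configuration
COINCIDENCE_TOL = 1e-6


@njit(cache=True, fastmath=True)
def accumulate_pair_forces(pos, pi, pj, shift, rep_only,
                           u0, rho, alpha, d_eq, r_cut,
                           forces, fpair):
    """Fill per-particle ``forces`` (n,3) and per-pair ``fpair`` (P,3).

    ``fpair[p]`` is the force exerted on particle ``pi[p]`` by ``pj[p]``.
    Returns the index of the first coincident pair, or -1 if none.
    """
    min_gap = _MIN_GAP_FACTOR * d_eq
    inv_deq2 = 1.0 / (d_eq * d_eq)
    for p in range(pi.shape[0]):
        a = pi[p]
        b = pj[p]
        dx = pos[a, 0] - pos[b, 0]
        dy = pos[a, 1] - pos[b, 1]
        dz = pos[a, 2] - pos[b, 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        if d < COINCIDENCE_TOL:
            return p
        dp = d - shift[p]
        if dp > r_cut:
            fpair[p, 0] = 0.0
            fpair[p, 1] = 0.0
            fpair[p, 2] = 0.0
            continue
        if dp < min_gap:
            dp = min_gap
        e1 = np.exp(rho * (1.0 - dp * dp * inv_deq2))
        pref = 2.0 * rho * dp * inv_deq2 * u0
        if rep_only[p]:
            fmag = 2.0 * pref * e1 * e1
        else:
            fmag = pref * (2.0 * e1 * e1 - alpha * e1)
        s = fmag / d
        fx = s * dx
        fy = s * dy
        fz = s * dz
        fpair[p, 0] = fx
        fpair[p, 1] = fy
        fpair[p, 2] = fz
        forces[a, 0] += fx
        forces[a, 1] += fy
        forces[a, 2] += fz
        forces[b, 0] -= fx
        forces[b, 1] -= fy
        forces[b, 2] -= fz
    return -1


@njit(cache=True, fastmath=True)
def pair_distances(pos, pi, pj, shift, rho, d_eq, r_cut, d_out, dp_out, x_out):
    """Pass 1 of the hot path: per-pair distance, shifted distance and the
    exponent argument rho*(1 - dp^2/d_eq^2).  Beyond-cutoff pairs get a
    dummy exponent of 0 (kept in the normal range: exp underflow is very
    slow) and are masked out in pass 2.  Returns the first coincident pair
    index or -1."""
    min_gap = _MIN_GAP_FACTOR * d_eq
    inv_deq2 = 1.0 / (d_eq * d_eq)
    for p in range(pi.shape[0]):
        a = pi[p]
        b = pj[p]
        dx = pos[a, 0] - pos[b, 0]
        dy = pos[a, 1] - pos[b, 1]
        dz = pos[a, 2] - pos[b, 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        if d < COINCIDENCE_TOL:
            return p
        dp = d - shift[p]
        if dp < min_gap:
            dp = min_gap
        d_out[p] = d
        dp_out[p] = dp
        x_out[p] = rho * (1.0 - dp * dp * inv_deq2) if dp <= r_cut else 0.0
    return -1


@njit(cache=True, fastmath=True)
def scatter_pair_forces(pos, pi, pj, rep_only, d, dp, e1,
                        u0, rho, alpha, d_eq, r_cut, forces):
    """Pass 2: force magnitudes from the precomputed exp values, scattered
    equal-and-opposite onto the per-particle force table."""
    inv_deq2 = 1.0 / (d_eq * d_eq)
    for p in range(pi.shape[0]):
        if dp[p] > r_cut:
            continue
        e = e1[p]
        pref = 2.0 * rho * dp[p] * inv_deq2 * u0
        if rep_only[p]:
            fmag = 2.0 * pref * e * e
        else:
            fmag = pref * (2.0 * e * e - alpha * e)
        a = pi[p]
        b = pj[p]
        s = fmag / d[p]
        dx = s * (pos[a, 0] - pos[b, 0])
        dy = s * (pos[a, 1] - pos[b, 1])
        dz = s * (pos[a, 2] - pos[b, 2])
        forces[a, 0] += dx
        forces[a, 1] += dy
        forces[a, 2] += dz
        forces[b, 0] -= dx
        forces[b, 1] -= dy
        forces[b, 2] -= dz
    return 0


def accumulate_forces_only(pos, pi, pj, shift, rep_only,
                           u0, rho, alpha, d_eq, r_cut, forces):
    """Hot-path force accumulation without per-pair records.

    Two numba passes around a single vectorized ``np.exp`` (numpy's SIMD exp
    is several times faster than a scalar libm exp per pair).  Returns the
    first coincident pair index, or -1.
    """
    n_pairs = pi.shape[0]
    d = np.empty(n_pairs)
    dp = np.empty(n_pairs)
    x = np.empty(n_pairs)
    bad = pair_distances(pos, pi, pj, shift, rho, d_eq, r_cut, d, dp, x)
    if bad >= 0:
        return bad
    e1 = np.exp(x)
    scatter_pair_forces(pos, pi, pj, rep_only, d, dp, e1,
                        u0, rho, alpha, d_eq, r_cut, forces)
    return -1


@njit(cache=True, fastmath=True)
def total_pair_energy(pos, pi, pj, shift, rep_only, u0, rho, alpha, d_eq, r_cut):
    """Total pair potential energy (J) over the candidate pairs."""
    min_gap = _MIN_GAP_FACTOR * d_eq
    inv_deq2 = 1.0 / (d_eq * d_eq)
    e_tot = 0.0
    for p in range(pi.shape[0]):
        a = pi[p]
        b = pj[p]
        dx = pos[a, 0] - pos[b, 0]
        dy = pos[a, 1] - pos[b, 1]
        dz = pos[a, 2] - pos[b, 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        dp = d - shift[p]
        if dp > r_cut:
            continue
        if dp < min_gap:
            dp = min_gap
        e1 = np.exp(rho * (1.0 - dp * dp * inv_deq2))
        if rep_only[p]:
            e_tot += u0 * e1 * e1
        else:
            e_tot += u0 * e1 * e1 - alpha * u0 * e1
    return e_tot
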