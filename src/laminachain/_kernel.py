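"""Numba-compiled Metropolis inner loop.

Only the energy terms touching the moved bead are evaluated per step
(incremental update); agreement with full recomputation through
``energies.total_energy`` is enforced by the test suite to 1e-9 k_BT.

Randomness is supplied by the caller as pre-generated arrays (bead picks,
in-ball displacements, acceptance uniforms) drawn from one numpy Generator
per replicate, so trajectories are fully determined by (seed, params).
"""
from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["local_energy", "run_steps", "pack_params"]


def pack_params(params, tether_bead: int = -1,
                tether_site=None) -> np.ndarray:
    """Flatten ModelParams (+ optional tether) into a float64 vector for
    the jitted kernel."""
    if tether_site is None:
        tether_site = (0.0, 0.0, 0.0)
    return np.array([
        params.bending_k,                     # 0
        params.stretching_k,                  # 1
        params.bond_length,                   # 2  equilibrium bond 2*r_bead
        params.sigma_wca ** 2,                # 3
        params.wca_cutoff ** 2,               # 4
        params.r_nucleus,                     # 5
        params.wall_k,                        # 6
        params.eps_ads,                       # 7
        params.attraction_radius,             # 8
        params.r_bead,                        # 9  sigma of surface potential
        1.0 if params.excluded_volume else 0.0,  # 10
        1.0 if params.wall else 0.0,          # 11
        float(tether_bead),                   # 12 (-1: no tether)
        float(tether_site[0]),                # 13
        float(tether_site[1]),                # 14
        float(tether_site[2]),                # 15
    ])


@njit(cache=True)
def _dist2(ax, ay, az, bx, by, bz):
    dx = ax - bx
    dy = ay - by
    dz = az - bz
    return dx * dx + dy * dy + dz * dz


@njit(cache=True)
def local_energy(coords, b, px, py, pz, p):
    """Energy of all Hamiltonian terms involving bead ``b`` placed at
    (px,py,pz), other beads at ``coords``. Returns +inf for positions the
    adsorbing surface forbids (r >= attraction radius when eps_ads > 0)."""
    n = coords.shape[0]
    bend_k = p[0]
    stretch_k = p[1]
    bond0 = p[2]
    sig2 = p[3]
    cut2 = p[4]
    r_nuc = p[5]
    wall_k = p[6]
    eps_ads = p[7]
    r_att = p[8]
    sig_s = p[9]
    ev_on = p[10] > 0.5
    wall_on = p[11] > 0.5
    tether_b = int(p[12])

    u = 0.0
    # stretching: bonds (b-1,b) and (b,b+1)
    for j in (b - 1, b):
        if 0 <= j < n - 1:
            if j == b:
                d2 = _dist2(px, py, pz, coords[j + 1, 0], coords[j + 1, 1],
                            coords[j + 1, 2])
            else:
                d2 = _dist2(coords[j, 0], coords[j, 1], coords[j, 2],
                            px, py, pz)
            d = np.sqrt(d2)
            u += stretch_k * (d - bond0) * (d - bond0)

    # bending: joints centered at b-1, b, b+1 (those using a bond of b)
    for c in (b - 1, b, b + 1):
        if 1 <= c <= n - 2:
            # beads c-1, c, c+1 with bead b substituted
            if c - 1 == b:
                ax, ay, az = px, py, pz
            else:
                ax, ay, az = coords[c - 1, 0], coords[c - 1, 1], coords[c - 1, 2]
            if c == b:
                mx, my, mz = px, py, pz
            else:
                mx, my, mz = coords[c, 0], coords[c, 1], coords[c, 2]
            if c + 1 == b:
                ex, ey, ez = px, py, pz
            else:
                ex, ey, ez = coords[c + 1, 0], coords[c + 1, 1], coords[c + 1, 2]
            v1x, v1y, v1z = mx - ax, my - ay, mz - az
            v2x, v2y, v2z = ex - mx, ey - my, ez - mz
            n1 = np.sqrt(v1x * v1x + v1y * v1y + v1z * v1z)
            n2 = np.sqrt(v2x * v2x + v2y * v2y + v2z * v2z)
            cos_t = (v1x * v2x + v1y * v2y + v1z * v2z) / (n1 * n2)
            u += bend_k * (1.0 - cos_t)

    # excluded volume: WCA against all nonconsecutive beads
    if ev_on:
        for j in range(n):
            if j < b - 1 or j > b + 1:
                d2 = _dist2(px, py, pz, coords[j, 0], coords[j, 1],
                            coords[j, 2])
                if d2 < cut2:
                    s6 = (sig2 / d2) ** 3
                    u += 4.0 * (s6 * s6 - s6) + 1.0

    r2 = px * px + py * py + pz * pz
    r = np.sqrt(r2)

    # wall restoring spring
    if wall_on and r > r_nuc:
        u += 0.5 * wall_k * (r - r_nuc) * (r - r_nuc)

    # surface attraction (10-4 integrated LJ)
    if eps_ads > 0.0:
        if r >= r_att:
            return np.inf
        xm = sig_s / (r_att - r)
        xp = sig_s / (r_att + r)
        u += (4.0 * eps_ads * np.pi * (r_att / r)
              * ((xm**10 - xp**10) / 5.0 - (xm**4 - xp**4) / 2.0))

    # pinning tether
    if tether_b == b:
        d2 = _dist2(px, py, pz, p[13], p[14], p[15])
        u += stretch_k * d2

    return u


@njit(cache=True)
def run_steps(coords, free_idx, bead_u, disp, acc_u, p,
              sweep_len, capture_b, capture_r2):
    """Run one batch of Metropolis steps in place.

    bead_u:  uniform [0,1) draws selecting the free bead per step
    disp:    (n_steps, 3) displacement vectors, uniform in the move ball
    acc_u:   uniform [0,1) acceptance draws
    sweep_len / capture_b / capture_r2: when capture_b >= 0, check at each
    sweep boundary whether bead capture_b is within sqrt(capture_r2) of
    the tether site (p[13:16]) and return early if so.

    Returns (steps_done, n_accepted, captured).
    """
    n_free = free_idx.shape[0]
    n_steps = bead_u.shape[0]
    n_acc = 0
    for i in range(n_steps):
        b = free_idx[int(bead_u[i] * n_free)]
        ox, oy, oz = coords[b, 0], coords[b, 1], coords[b, 2]
        nx = ox + disp[i, 0]
        ny = oy + disp[i, 1]
        nz = oz + disp[i, 2]
        u_old = local_energy(coords, b, ox, oy, oz, p)
        u_new = local_energy(coords, b, nx, ny, nz, p)
        du = u_new - u_old
        if du <= 0.0 or acc_u[i] < np.exp(-du):
            coords[b, 0] = nx
            coords[b, 1] = ny
            coords[b, 2] = nz
            n_acc += 1
        if capture_b >= 0 and (i + 1) % sweep_len == 0:
            d2 = _dist2(coords[capture_b, 0], coords[capture_b, 1],
                        coords[capture_b, 2], p[13], p[14], p[15])
            if d2 <= capture_r2:
                return i + 1, n_acc, True
    return n_steps, n_acc, False
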