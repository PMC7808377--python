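"""Energy terms of the chain Hamiltonian, in k_BT units.

H = U_bending + U_stretching + U_excluded-volume (WCA, nonconsecutive
pairs) + wall restoring spring (+ surface attraction when eps_ads > 0,
+ an optional harmonic tether used only during the second-anchor pinning
protocol).

These are straightforward, vectorized reference implementations; the
Monte Carlo hot path uses the incremental kernel in ``_kernel`` and is
tested against full recomputation through these functions.
"""
from __future__ import annotations

import numpy as np

from .params import ModelParams
from .state import ChainState

__all__ = [
    "bending_energy",
    "stretching_energy",
    "wca_pair_energy",
    "excluded_volume_energy",
    "wall_restoring_energy",
    "surface_attraction_energy",
    "tether_energy",
    "total_energy",
]


def bending_energy(coords: np.ndarray, params: ModelParams) -> float:
    """Discrete worm-like-chain bending energy.

    U = (L_P / (2·r_bead)) · Σ_joints (1 − cos θ), with θ the angle between
    consecutive bond vectors. Zero for a collinear chain; invariant under
    global rotation and translation.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 3:
        return 0.0
    bonds = np.diff(coords, axis=0)
    norms = np.linalg.norm(bonds, axis=1)
    if np.any(norms == 0.0):
        raise ValueError("degenerate (zero-length) bond: corrupt state")
    cos_t = np.einsum("ij,ij->i", bonds[:-1], bonds[1:]) / (norms[:-1] * norms[1:])
    return float(params.bending_k * np.sum(1.0 - cos_t))


def stretching_energy(coords: np.ndarray, params: ModelParams) -> float:
    """Harmonic bond-stretching energy.

    U = (L_P / r_bead³) · Σ_bonds (|b| − 2·r_bead)²; zero iff every bond
    is at its equilibrium length 2·r_bead.
    """
    coords = np.asarray(coords, dtype=float)
    bonds = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    return float(params.stretching_k * np.sum((bonds - params.bond_length) ** 2))


def wca_pair_energy(dist, params: ModelParams):
    """Weeks–Chandler–Andersen excluded-volume energy of one bead pair.

    4ε[(σ/r)¹² − (σ/r)⁶] + ε for r ≤ 2^(1/6)σ and 0 beyond, with ε = 1 k_BT
    and σ = 2·r_bead/2^(1/6): purely repulsive, continuous at the cutoff.
    Applies to nonconsecutive bead pairs. Accepts scalars or arrays.
    """
    r = np.asarray(dist, dtype=float)
    if np.any(r <= 0.0):
        raise ValueError("pair distance must be positive")
    sr6 = (params.sigma_wca / r) ** 6
    u = np.where(r <= params.wca_cutoff, 4.0 * (sr6**2 - sr6) + 1.0, 0.0)
    return float(u) if u.ndim == 0 else u


def excluded_volume_energy(coords: np.ndarray, params: ModelParams) -> float:
    """Sum of WCA energies over all nonconsecutive bead pairs."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(i + 2, n):
            d = float(np.linalg.norm(coords[i] - coords[j]))
            total += wca_pair_energy(d, params)
    return total


def wall_restoring_energy(coords_i: np.ndarray, params: ModelParams) -> float:
    """Harmonic penalty retaining a bead that escapes the nucleus.

    0 inside (|r| ≤ r_nucleus); (k/2)·(|r| − r_nucleus)² outside, with
    spring stiffness k = k_BT/r_bead² acting on the bead center.
    """
    r = float(np.linalg.norm(np.asarray(coords_i, dtype=float)))
    if r <= params.r_nucleus:
        return 0.0
    return 0.5 * params.wall_k * (r - params.r_nucleus) ** 2


def surface_attraction_energy(radial_dist, params: ModelParams):
    """Sphere-integrated 10–4 Lennard-Jones surface potential.

    Integrating 12–6 Lennard-Jones pair interactions over the spherical
    periphery of radius R = r_nucleus gives, for a bead center at radial
    distance r < R,

        U(r) = 4·ε_ads·π·(R/r)·[ (1/5)((σ/(R−r))¹⁰ − (σ/(R+r))¹⁰)
                                 − (1/2)((σ/(R−r))⁴  − (σ/(R+r))⁴) ]

    with σ = r_bead and the pair well depth ε_ads in k_BT setting the
    overall strength of the surface interaction. The potential diverges as
    r → R (beads cannot cross the periphery), has its single minimum at a
    height ≈ r_bead above the surface — the imposed anchor height — with
    depth ≈ 4π·0.3·ε_ads k_BT, and decays to ~0 in the nucleus interior.
    Accepts scalars or arrays.
    """
    r = np.asarray(radial_dist, dtype=float)
    R = params.attraction_radius
    if np.any(r <= 0.0):
        raise ValueError("radial distance must be positive")
    if np.any(r >= R):
        raise ValueError(
            "bead center at or beyond the attractive surface: corrupt state")
    sig = params.r_bead
    xm = sig / (R - r)
    xp = sig / (R + r)
    u = (4.0 * params.eps_ads * np.pi * (R / r)
         * ((xm**10 - xp**10) / 5.0 - (xm**4 - xp**4) / 2.0))
    return float(u) if u.ndim == 0 else u


def tether_energy(coords_i: np.ndarray, site: np.ndarray,
                  params: ModelParams) -> float:
    """Harmonic tether used while pinning bead N to the second anchor:
    (L_P/r_bead³)·|r − a₂|² (stretching form, zero equilibrium length)."""
    d2 = float(np.sum((np.asarray(coords_i, float) - np.asarray(site, float)) ** 2))
    return params.stretching_k * d2


def total_energy(state: ChainState, params: ModelParams,
                 tether: tuple[int, np.ndarray] | None = None) -> float:
    """Full Hamiltonian of a chain state by term-wise summation.

    The surface term enters only when eps_ads > 0 (a neutral periphery
    exerts no potential beyond the escape-restoring spring). ``tether``
    optionally adds the pinning tether as (bead_index, site).
    """
    coords = state.coords
    u = bending_energy(coords, params) + stretching_energy(coords, params)
    if params.excluded_volume:
        u += excluded_volume_energy(coords, params)
    if params.wall:
        for i in range(state.n_beads):
            u += wall_restoring_energy(coords[i], params)
    if params.eps_ads > 0.0:
        r = np.linalg.norm(coords, axis=1)
        u += float(np.sum(surface_attraction_energy(r, params)))
    if tether is not None:
        b, site = tether
        u += tether_energy(coords[b], site, params)
    return u
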