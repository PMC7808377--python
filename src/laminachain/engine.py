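"""Metropolis kinetic Monte Carlo dynamics of the anchored chain.

One MCStep displaces a uniformly chosen free bead within a ball of radius
R_move = r_bead/5 and accepts with probability min(1, exp(−ΔU/k_BT)); one
MCSweep is n_free such steps (each free bead attempts on average one move
per sweep). A simulation initializes the chain at the anchor height, pins
bead N to the second anchor when present (tether + capture, counted
against the pre-equilibration budget), discards pre-equilibration, then
records one configuration every ``sample_every`` sweeps.
"""
from __future__ import annotations

import math
import time
from dataclasses import dataclass

import numpy as np

from . import _kernel
from .params import ModelParams
from .state import ChainState, height_above_np, initialize_chain

__all__ = [
    "TrajectorySample",
    "ReplicateResult",
    "SimulationResult",
    "propose_move",
    "metropolis_accept",
    "run_sweep",
    "pin_second_anchor",
    "run_simulation",
]

# sweeps per kernel batch during unsampled phases (bounds RNG array memory)
_CHUNK_SWEEPS = 50_000
# sweeps per kernel batch during the pinning phase (capture checked every sweep)
_PIN_CHUNK_SWEEPS = 2_000


@dataclass(frozen=True)
class TrajectorySample:
    """One sampled configuration of one replicate."""

    sweep_index: int
    coords: np.ndarray
    heights: np.ndarray
    replicate_id: int
    seed: int


@dataclass
class ReplicateResult:
    """Samples and run metadata of one independent simulation."""

    replicate_id: int
    seed: int
    samples: list[TrajectorySample]
    acceptance_rate: float
    pinning_sweeps: int
    final_state: ChainState
    wall_time_s: float


@dataclass
class SimulationResult:
    """Replicate results plus the parameter echo."""

    params: ModelParams
    replicates: list[ReplicateResult]

    @property
    def samples_by_replicate(self) -> list[list[TrajectorySample]]:
        return [r.samples for r in self.replicates]


def _ball_draws(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    """n points uniform in the ball of given radius, by rejection from the
    bounding cube (deterministic given the generator state)."""
    out = np.empty((n, 3))
    filled = 0
    while filled < n:
        m = int((n - filled) * 2.1) + 16
        pts = rng.uniform(-1.0, 1.0, size=(m, 3))
        pts = pts[np.einsum("ij,ij->i", pts, pts) <= 1.0]
        take = min(pts.shape[0], n - filled)
        out[filled:filled + take] = pts[:take]
        filled += take
    return out * radius


def propose_move(state: ChainState, bead_index: int,
                 rng: np.random.Generator, params: ModelParams) -> np.ndarray:
    """Candidate position for one free bead: current + u, u uniform in the
    ball of radius R_move."""
    if state.pinned[bead_index]:
        raise ValueError(f"bead {bead_index} is pinned; no moves allowed")
    return state.coords[bead_index] + _ball_draws(rng, 1, params.move_radius)[0]


def metropolis_accept(delta_u: float, rng: np.random.Generator) -> bool:
    """Metropolis rule: accept with probability min(1, exp(−ΔU))."""
    if math.isnan(delta_u):
        raise ValueError("NaN energy difference: corrupt state")
    if delta_u <= 0.0:
        return True
    return rng.random() < math.exp(-delta_u)


def _kernel_batch(state: ChainState, params: ModelParams,
                  rng: np.random.Generator, n_sweeps: int,
                  packed: np.ndarray, free_idx: np.ndarray,
                  capture_b: int = -1, capture_r2: float = 0.0):
    """Draw the random streams for ``n_sweeps`` sweeps and run the jitted
    step loop in place. Returns (sweeps_done, accepted, captured)."""
    n_free = free_idx.shape[0]
    n_steps = n_sweeps * n_free
    bead_u = rng.random(n_steps)
    disp = _ball_draws(rng, n_steps, params.move_radius)
    acc_u = rng.random(n_steps)
    steps_done, n_acc, captured = _kernel.run_steps(
        state.coords, free_idx, bead_u, disp, acc_u, packed,
        n_free, capture_b, capture_r2)
    return steps_done // n_free, n_acc, captured


def run_sweep(state: ChainState, params: ModelParams,
              rng: np.random.Generator) -> ChainState:
    """Perform one MCSweep (n_free Metropolis step attempts) in place and
    return the state."""
    free_idx = state.free_indices()
    packed = _kernel.pack_params(params)
    _kernel_batch(state, params, rng, 1, packed, free_idx)
    return state


def pin_second_anchor(state: ChainState, params: ModelParams,
                      rng: np.random.Generator) -> tuple[ChainState, int]:
    """Drive bead N onto the second anchor site and freeze it there.

    Metropolis dynamics run under the full Hamiltonian plus a harmonic
    tether (L_P/r_bead³)·|r_N − a₂|² between bead N and the anchor site;
    once |r_N − a₂| ≤ R_move (checked each sweep) the bead is set exactly
    onto the site and flagged pinned, and the tether is removed. Returns
    (state, sweeps used). Raises RuntimeError if capture is not achieved
    within the pre-equilibration budget.
    """
    if params.n_anchors != 2:
        raise ValueError("pin_second_anchor requires n_anchors == 2")
    last = state.n_beads - 1
    if state.pinned[last]:
        raise ValueError("bead N is already pinned")
    site = state.anchor_sites[1]
    packed = _kernel.pack_params(params, tether_bead=last, tether_site=site)
    free_idx = state.free_indices()
    budget = params.schedule.pre_equilibration_sweeps
    capture_r2 = params.move_radius**2
    sweeps_used = 0
    captured = (float(np.sum((state.coords[last] - site) ** 2)) <= capture_r2)
    while not captured and sweeps_used < budget:
        chunk = min(_PIN_CHUNK_SWEEPS, budget - sweeps_used)
        done, _, captured = _kernel_batch(
            state, params, rng, chunk, packed, free_idx,
            capture_b=last, capture_r2=capture_r2)
        sweeps_used += done
    if not captured:
        raise RuntimeError(
            f"second-anchor pinning not achieved within "
            f"{budget} pre-equilibration sweeps "
            f"(d_E={params.anchor_separation}, L_P={params.persistence_length}): "
            f"pathological parameter combination")
    state.coords[last] = site.copy()
    state.pinned[last] = True
    return state, sweeps_used


def run_replicate(params: ModelParams, replicate_id: int) -> ReplicateResult:
    """Run one independent simulation (one seed) and collect samples."""
    t0 = time.perf_counter()
    seed = params.replicate_seed(replicate_id)
    rng = np.random.default_rng(seed)
    state = initialize_chain(params)

    pinning_sweeps = 0
    if params.n_anchors == 2:
        state, pinning_sweeps = pin_second_anchor(state, params, rng)

    packed = _kernel.pack_params(params)
    free_idx = state.free_indices()
    sched = params.schedule

    remaining_pre = sched.pre_equilibration_sweeps - pinning_sweeps
    while remaining_pre > 0:
        chunk = min(_CHUNK_SWEEPS, remaining_pre)
        done, _, _ = _kernel_batch(state, params, rng, chunk, packed, free_idx)
        remaining_pre -= done

    samples: list[TrajectorySample] = []
    attempted = 0
    accepted = 0
    n_free = free_idx.shape[0]
    sweep = sched.pre_equilibration_sweeps
    while sweep + sched.sample_every <= sched.total_sweeps:
        done, n_acc, _ = _kernel_batch(state, params, rng, sched.sample_every,
                                       packed, free_idx)
        sweep += done
        attempted += done * n_free
        accepted += n_acc
        state.validate(params)
        samples.append(TrajectorySample(
            sweep_index=sweep,
            coords=state.coords.copy(),
            heights=np.asarray(height_above_np(state.coords, params)),
            replicate_id=replicate_id,
            seed=seed,
        ))
    acc_rate = accepted / attempted if attempted else float("nan")
    return ReplicateResult(
        replicate_id=replicate_id,
        seed=seed,
        samples=samples,
        acceptance_rate=acc_rate,
        pinning_sweeps=pinning_sweeps,
        final_state=state,
        wall_time_s=time.perf_counter() - t0,
    )


def run_simulation(params: ModelParams) -> SimulationResult:
    """Run ``params.n_replicates`` independent replicates (seeds =
    base seed + replicate id) and return their sampled trajectories."""
    replicates = [run_replicate(params, rid)
                  for rid in range(params.n_replicates)]
    return SimulationResult(params=params, replicates=replicates)
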