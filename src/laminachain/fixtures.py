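"""Deterministic synthetic trajectory fixtures with known classifier
ground truth, for tests and documentation examples.

Each fixture builds coordinates whose center-to-NP heights realize a
prescribed adsorption pattern exactly: beads are placed along a
great-circle fan of directions with bead k at radius r_nucleus − h_k.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np

from .engine import SimulationResult, ReplicateResult, TrajectorySample
from .params import ModelParams
from .state import ChainState, anchor_sites
from .trajio import write_trajectory_csv

__all__ = ["FIXTURE_KINDS", "fixture_heights", "generate_fixture"]

FIXTURE_KINDS = ("straight_chain", "two_train_one_loop", "all_adsorbed",
                 "random_heights")


def fixture_heights(kind: str, params: ModelParams,
                    rng: np.random.Generator) -> np.ndarray:
    """Per-bead height vector of one fixture frame."""
    n = params.n_beads
    h = params.h_anchor
    if kind == "straight_chain":
        return np.full(n, h)
    if kind == "all_adsorbed":
        return np.full(n, params.train_threshold - 5.0)
    if kind == "two_train_one_loop":
        # beads 1,2 and N-1,N adsorbed, middle desorbed
        heights = np.full(n, params.train_threshold + 60.0)
        heights[:2] = h
        heights[-2:] = h
        return heights
    if kind == "random_heights":
        return rng.uniform(0.0, 2.5 * params.train_threshold, size=n)
    raise ValueError(f"unknown fixture kind: {kind!r}")


def _coords_for_heights(heights: np.ndarray, params: ModelParams) -> np.ndarray:
    """Place bead k at radius r_nucleus − h_k along direction k of a
    great-circle fan, so heights are realized exactly."""
    n = heights.shape[0]
    phi = 2.0 * np.arcsin(params.r_bead / params.anchor_radius)
    k = np.arange(n)
    dirs = np.column_stack([np.sin(k * phi), np.zeros(n), np.cos(k * phi)])
    return dirs * (params.r_nucleus - heights)[:, None]


def generate_fixture(kind: str, seed: int, out_dir: str | Path,
                     params: ModelParams | None = None,
                     n_frames: int = 4) -> Path:
    """Write a small deterministic trajectory CSV for ``kind`` and return
    its path. ``straight_chain`` is a single zero-bending frame; the other
    kinds emit ``n_frames`` frames (identical except ``random_heights``)."""
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind: {kind!r}")
    params = params or ModelParams(seed=seed, n_replicates=1)
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_frames = 1 if kind == "straight_chain" else n_frames
    samples = []
    for f in range(n_frames):
        heights = fixture_heights(kind, params, rng)
        coords = _coords_for_heights(heights, params)
        samples.append(TrajectorySample(
            sweep_index=(f + 1) * params.schedule.sample_every,
            coords=coords,
            heights=heights,
            replicate_id=0,
            seed=seed,
        ))
    rep = ReplicateResult(replicate_id=0, seed=seed, samples=samples,
                          acceptance_rate=float("nan"), pinning_sweeps=0,
                          final_state=ChainState(
                              samples[-1].coords.copy(),
                              np.zeros(params.n_beads, dtype=bool),
                              anchor_sites(params)),
                          wall_time_s=0.0)
    result = SimulationResult(params=params, replicates=[rep])
    path = out_dir / f"fixture_{kind}.csv"
    write_trajectory_csv(result, path, config_hash=f"fixture-{kind}-{seed}")
    return path
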