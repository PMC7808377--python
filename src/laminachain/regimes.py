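"""Adsorption/desorption regime statistics across samples and replicates.

The regime statistic is F = F_train − F_other (in percent), where F_train
is the frequency of free-bead observations in a train and F_other is the
frequency in the remaining configurations (loop + tail for one anchor,
loop for two anchors). Regimes: adsorption (F > 50), adsorption-desorption
(0 < F ≤ 50), desorption (F ≤ 0). Error bars are s.e.m. over replicate
means (not raw samples), which sidesteps trajectory autocorrelation.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .engine import SimulationResult, TrajectorySample, run_simulation
from .params import ModelParams
from .state import anchor_sites
from .topology import SegmentLabeling, segment_chain

__all__ = [
    "RegimeSummary",
    "BeadTrajectory",
    "f_statistic",
    "classify_regime",
    "distance_profile",
    "bead_trajectory",
    "phase_grid",
    "rigid_rod_reference",
]


@dataclass
class RegimeSummary:
    """F statistic, component frequencies and the regime call."""

    F: float  # percent, in [-100, 100]
    regime: str
    f_train: float
    f_loop: float
    f_tail: float
    n_anchors: int
    per_replicate_F: tuple[float, ...] = ()
    sem: float | None = None
    params: dict | None = None


def classify_regime(F: float) -> str:
    """Threshold rules: adsorption (F > 50), adsorption-desorption
    (0 < F ≤ 50), desorption (F ≤ 0)."""
    if F > 50.0:
        return "adsorption"
    if F > 0.0:
        return "adsorption-desorption"
    return "desorption"


def _free_bead_slice(n_beads: int, n_anchors: int) -> slice:
    return slice(1, n_beads) if n_anchors == 1 else slice(1, n_beads - 1)


def _frequencies(labelings: Sequence[SegmentLabeling],
                 n_anchors: int) -> tuple[float, float, float]:
    """(f_train, f_loop, f_tail) in percent of free-bead observations."""
    counts = {"train": 0, "loop": 0, "tail": 0}
    total = 0
    for lab in labelings:
        if lab.n_anchors != n_anchors:
            raise ValueError("mixed anchor counts in labelings")
        kinds = lab.bead_kinds()[_free_bead_slice(lab.n_beads, n_anchors)]
        for k in counts:
            counts[k] += int(np.sum(kinds == k))
        total += kinds.shape[0]
    if total == 0:
        raise ValueError("no free-bead observations")
    return tuple(100.0 * counts[k] / total for k in ("train", "loop", "tail"))


def f_statistic(labelings: Sequence[SegmentLabeling] | Sequence[Sequence[SegmentLabeling]],
                n_anchors: int) -> RegimeSummary:
    """F = f_train − f_other over free-bead observations, with the regime
    call. Accepts a flat list of labelings (one replicate) or a list of
    per-replicate lists (pooled mean F with s.e.m. over replicates)."""
    if not labelings:
        raise ValueError("f_statistic requires at least one labeling")
    by_replicate: list[Sequence[SegmentLabeling]]
    if isinstance(labelings[0], SegmentLabeling):
        by_replicate = [labelings]  # type: ignore[list-item]
    else:
        by_replicate = list(labelings)  # type: ignore[arg-type]

    per_rep_F = []
    for labs in by_replicate:
        ft, fl, fta = _frequencies(labs, n_anchors)
        other = fl + fta if n_anchors == 1 else fl
        per_rep_F.append(ft - other)
    ft, fl, fta = _frequencies([lab for labs in by_replicate for lab in labs],
                               n_anchors)
    other = fl + fta if n_anchors == 1 else fl
    F = float(np.mean(per_rep_F))
    sem = (float(np.std(per_rep_F, ddof=1) / np.sqrt(len(per_rep_F)))
           if len(per_rep_F) >= 2 else None)
    return RegimeSummary(F=F, regime=classify_regime(F), f_train=ft,
                         f_loop=fl, f_tail=fta, n_anchors=n_anchors,
                         per_replicate_F=tuple(per_rep_F), sem=sem)


def distance_profile(samples_by_replicate: Sequence[Sequence[TrajectorySample]]
                     ) -> pd.DataFrame:
    """Per-bead mean center-to-NP height with s.e.m. over replicates.

    The mean is taken over samples within each replicate first; the
    reported mean and s.e.m. are then across replicate means. With a
    single replicate the s.e.m. column is NaN (unavailable).
    """
    rep_means = []
    for samples in samples_by_replicate:
        if not samples:
            raise ValueError("empty replicate")
        rep_means.append(np.mean([s.heights for s in samples], axis=0))
    rep_means = np.asarray(rep_means)
    mean = rep_means.mean(axis=0)
    if rep_means.shape[0] >= 2:
        sem = rep_means.std(axis=0, ddof=1) / np.sqrt(rep_means.shape[0])
    else:
        sem = np.full(mean.shape, np.nan)
    return pd.DataFrame({
        "bead": np.arange(1, mean.shape[0] + 1),
        "mean_height_nm": mean,
        "sem_nm": sem,
    })


@dataclass
class BeadTrajectory:
    """Height time series of one bead plus its adsorbed dwell fraction."""

    frame: pd.DataFrame  # columns: time_s, height_nm, adsorbed
    dwell_fraction: float


def bead_trajectory(samples: Sequence[TrajectorySample], bead_index: int,
                    params: ModelParams) -> BeadTrajectory:
    """Time series (sweep·dt, height) of one bead (0-based index) and the
    fraction of samples in which it is adsorbed."""
    if not 0 <= bead_index < params.n_beads:
        raise IndexError(f"bead index {bead_index} out of range")
    dt = params.dt_per_sweep
    heights = np.array([s.heights[bead_index] for s in samples])
    sweeps = np.array([s.sweep_index for s in samples])
    adsorbed = heights <= params.train_threshold
    frame = pd.DataFrame({"time_s": sweeps * dt, "height_nm": heights,
                          "adsorbed": adsorbed})
    return BeadTrajectory(frame=frame,
                          dwell_fraction=float(np.mean(adsorbed)))


def summarize_run(result: SimulationResult) -> RegimeSummary:
    """Segment every sample of a simulation and compute its F statistic."""
    params = result.params
    labelings = [[segment_chain(s, params) for s in rep.samples]
                 for rep in result.replicates]
    summary = f_statistic(labelings, params.n_anchors)
    summary.params = params.to_dict()
    return summary


def phase_grid(base_params: ModelParams,
               cells: Iterable[dict]) -> pd.DataFrame:
    """Run one simulation per grid cell and tabulate F and the regime.

    ``cells`` is an iterable of ModelParams field overrides, e.g.
    ``{"n_anchors": 1, "persistence_length": 5, "eps_ads": 0.05}``.
    Columns: n_anchors, L_P, d_E, eps_ads, F_percent, sem, regime.
    """
    rows = []
    for overrides in cells:
        params = base_params.replace(**overrides)
        summary = summarize_run(run_simulation(params))
        rows.append({
            "n_anchors": params.n_anchors,
            "L_P": params.persistence_length,
            "d_E": params.anchor_separation if params.n_anchors == 2 else np.nan,
            "eps_ads": params.eps_ads,
            "F_percent": summary.F,
            "sem": np.nan if summary.sem is None else summary.sem,
            "regime": summary.regime,
        })
    return pd.DataFrame(rows)


def rigid_rod_reference(params: ModelParams, n_draws: int,
                        seed: int | None = None) -> np.ndarray:
    """Per-bead mean heights of a rigid rod hinged at the anchor.

    Monte Carlo reference for the rigid limit L_P ≫ L_C of a one-anchor
    chain at a neutral surface: rod orientations are drawn uniformly over
    the solid angle, orientations placing any bead center below the
    periphery (height < 0, the hard-constraint reading of the wall) are
    rejected, and mean heights are averaged over accepted draws. Bead 1 is
    the hinge at the anchor height exactly.
    """
    if params.n_anchors != 1:
        raise ValueError("rigid rod reference is defined for one anchor")
    if n_draws < 1_000:
        raise ValueError("n_draws must be >= 1000 for a stable estimate")
    rng = np.random.default_rng(seed)
    a1 = anchor_sites(params)[0]
    k = np.arange(params.n_beads)[:, None]  # bead offsets along the rod
    total = np.zeros(params.n_beads)
    accepted = 0
    batch = 8192
    while accepted < n_draws:
        u = rng.normal(size=(batch, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        # positions of all beads for all orientations: (batch, n_beads, 3)
        pos = a1[None, None, :] + params.bond_length * k.T[:, :, None] * u[:, None, :]
        heights = params.r_nucleus - np.linalg.norm(pos, axis=2)
        ok = np.all(heights >= 0.0, axis=1)
        take = min(int(np.sum(ok)), n_draws - accepted)
        total += heights[ok][:take].sum(axis=0)
        accepted += take
    return total / n_draws
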