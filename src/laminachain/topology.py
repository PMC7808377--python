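"""Tail/train/loop segmentation of sampled chain configurations.

A bead is adsorbed when its center lies within ``r_bead + adsorption_zone``
(default 30 nm, inclusive) of the nuclear periphery. Maximal runs of
adsorbed beads are trains (a single adsorbed bead — anchored or not — is a
size-1 train); maximal desorbed runs containing a chain end are tails;
maximal desorbed runs flanked by trains on both sides are loops. Segments
partition the chain, and trains alternate with tails/loops.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import TrajectorySample
from .params import ModelParams

__all__ = ["Segment", "SegmentLabeling", "bead_state", "segment_chain",
           "configuration_census"]

ADSORBED = "adsorbed"
DESORBED = "desorbed"


@dataclass(frozen=True)
class Segment:
    """One maximal segment: kind ∈ {tail, train, loop}, beads
    [start, end] inclusive, 0-based."""

    kind: str
    start: int
    end: int

    @property
    def size(self) -> int:
        return self.end - self.start + 1


@dataclass
class SegmentLabeling:
    """Per-bead adsorption states and the segment partition of one sample."""

    bead_states: np.ndarray  # bool, True = adsorbed
    segments: list[Segment]
    n_anchors: int

    @property
    def n_beads(self) -> int:
        return self.bead_states.shape[0]

    @property
    def counts(self) -> tuple[int, int, int]:
        """(n_tails, n_trains, n_loops)."""
        kinds = [s.kind for s in self.segments]
        return (kinds.count("tail"), kinds.count("train"), kinds.count("loop"))

    def bead_kinds(self) -> np.ndarray:
        """Per-bead segment kind as an array of {'tail','train','loop'}."""
        out = np.empty(self.n_beads, dtype=object)
        for s in self.segments:
            out[s.start:s.end + 1] = s.kind
        return out


def bead_state(height: float, params: ModelParams) -> str:
    """'adsorbed' iff center-to-NP height ≤ r_bead + adsorption_zone
    (threshold inclusive)."""
    return ADSORBED if height <= params.train_threshold else DESORBED


def segment_chain(sample: TrajectorySample | np.ndarray,
                  params: ModelParams) -> SegmentLabeling:
    """Segment one configuration into tails, trains and loops.

    Accepts a TrajectorySample or a bare per-bead height vector. Desorbed
    runs touching a chain end are tails (with the anchored end(s) always
    adsorbed, a one-anchor chain has 0 or 1 tail and a two-anchor chain
    none); interior desorbed runs are loops.
    """
    heights = sample.heights if isinstance(sample, TrajectorySample) else np.asarray(sample, float)
    n = heights.shape[0]
    adsorbed = heights <= params.train_threshold
    segments: list[Segment] = []
    start = 0
    for i in range(1, n + 1):
        if i == n or adsorbed[i] != adsorbed[start]:
            if adsorbed[start]:
                kind = "train"
            elif start == 0 or i == n:
                kind = "tail"
            else:
                kind = "loop"
            segments.append(Segment(kind, start, i - 1))
            start = i
    return SegmentLabeling(bead_states=adsorbed, segments=segments,
                           n_anchors=params.n_anchors)


def configuration_census(labelings: list[SegmentLabeling]) -> dict[str, pd.DataFrame]:
    """Aggregate per-sample labelings into the three census tables.

    Returns a dict with:

    ``configurations`` — joint (n_tails, n_trains, n_loops) histogram as
    percent of structures;
    ``sizes`` — distribution of beads per segment, per kind, as percent of
    segments of that kind;
    ``per_bead`` — percent of samples in which each bead is in a tail,
    train or loop (rows sum to 100; beads numbered from 1).
    """
    if not labelings:
        raise ValueError("configuration_census requires at least one labeling")
    n_beads = labelings[0].n_beads

    config_counter: Counter = Counter()
    size_counter: dict[str, Counter] = {"tail": Counter(), "train": Counter(),
                                        "loop": Counter()}
    per_bead = {k: np.zeros(n_beads) for k in ("tail", "train", "loop")}
    for lab in labelings:
        config_counter[lab.counts] += 1
        for s in lab.segments:
            size_counter[s.kind][s.size] += 1
        kinds = lab.bead_kinds()
        for k in ("tail", "train", "loop"):
            per_bead[k] += kinds == k

    n = len(labelings)
    conf = pd.DataFrame(
        [(t, tr, lo, 100.0 * c / n)
         for (t, tr, lo), c in sorted(config_counter.items())],
        columns=["n_tails", "n_trains", "n_loops", "percent"],
    )
    size_rows = []
    for kind, counter in size_counter.items():
        total = sum(counter.values())
        for size, c in sorted(counter.items()):
            size_rows.append((kind, size, 100.0 * c / total))
    sizes = pd.DataFrame(size_rows, columns=["kind", "n_beads", "percent"])
    pb = pd.DataFrame({
        "bead": np.arange(1, n_beads + 1),
        "tail_percent": 100.0 * per_bead["tail"] / n,
        "train_percent": 100.0 * per_bead["train"] / n,
        "loop_percent": 100.0 * per_bead["loop"] / n,
    })
    return {"configurations": conf, "sizes": sizes, "per_bead": pb}
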