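"""Plain-text serialization: trajectories (CSV/XYZ), census and phase
tables (TSV), and run metadata (JSON).

Coordinates are written in nm with 6 decimal places; heights are derived
quantities included in the CSV for convenience. Every file starts with
comment headers carrying the config hash and seed(s).
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .engine import SimulationResult, TrajectorySample
from .params import ModelParams

__all__ = [
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_xyz",
    "write_metadata",
    "write_census_tables",
    "write_table",
]


def _header_lines(comment: str, meta: dict) -> str:
    pairs = " ".join(f"{k}={v}" for k, v in meta.items())
    return f"# {comment}\n# {pairs}\n"


def write_trajectory_csv(result: SimulationResult, path: str | Path,
                         config_hash: str = "") -> None:
    """One row per (replicate, sweep, bead): coordinates and height."""
    rows = []
    for rep in result.replicates:
        for s in rep.samples:
            for b in range(s.coords.shape[0]):
                rows.append((rep.replicate_id, s.sweep_index, b + 1,
                             s.coords[b, 0], s.coords[b, 1], s.coords[b, 2],
                             s.heights[b]))
    frame = pd.DataFrame(
        rows, columns=["replicate", "sweep", "bead", "x_nm", "y_nm", "z_nm",
                       "height_nm"])
    with open(path, "w") as fh:
        fh.write(_header_lines(
            "laminachain trajectory (nm)",
            {"config": config_hash, "seed": result.params.seed,
             "version": __version__}))
        frame.to_csv(fh, index=False, float_format="%.6f")


def read_trajectory_csv(path: str | Path) -> list[list[TrajectorySample]]:
    """Read a trajectory CSV back into per-replicate sample lists."""
    frame = pd.read_csv(path, comment="#")
    out: list[list[TrajectorySample]] = []
    for rid, rep_frame in frame.groupby("replicate"):
        samples = []
        for sweep, g in rep_frame.groupby("sweep"):
            g = g.sort_values("bead")
            samples.append(TrajectorySample(
                sweep_index=int(sweep),
                coords=g[["x_nm", "y_nm", "z_nm"]].to_numpy(),
                heights=g["height_nm"].to_numpy(),
                replicate_id=int(rid),
                seed=-1,
            ))
        samples.sort(key=lambda s: s.sweep_index)
        out.append(samples)
    return out


def write_xyz(samples: Sequence[TrajectorySample], path: str | Path) -> None:
    """Multi-frame XYZ trajectory; the comment line holds the sweep index."""
    with open(path, "w") as fh:
        for s in samples:
            fh.write(f"{s.coords.shape[0]}\n")
            fh.write(f"sweep={s.sweep_index} replicate={s.replicate_id}\n")
            for b in range(s.coords.shape[0]):
                fh.write(f"C {s.coords[b, 0]:.6f} {s.coords[b, 1]:.6f} "
                         f"{s.coords[b, 2]:.6f}\n")


def write_metadata(result: SimulationResult, path: str | Path,
                   config_hash: str = "") -> None:
    """JSON run metadata: parameter echo, seeds, acceptance rates."""
    meta = {
        "version": __version__,
        "config_hash": config_hash,
        "params": result.params.to_dict(),
        "replicates": [
            {
                "replicate_id": rep.replicate_id,
                "seed": rep.seed,
                "n_samples": len(rep.samples),
                "acceptance_rate": rep.acceptance_rate,
                "pinning_sweeps": rep.pinning_sweeps,
                "wall_time_s": rep.wall_time_s,
            }
            for rep in result.replicates
        ],
    }
    Path(path).write_text(json.dumps(meta, indent=2))


def write_table(frame: pd.DataFrame, path: str | Path, comment: str,
                meta: dict | None = None) -> None:
    """TSV with a commented header (units in column names)."""
    with open(path, "w") as fh:
        fh.write(_header_lines(comment, meta or {}))
        frame.to_csv(fh, sep="\t", index=False, float_format="%.4f")


def write_census_tables(census: dict[str, pd.DataFrame], out_dir: str | Path,
                        meta: dict | None = None) -> dict[str, Path]:
    """Write the three census tables (configurations, sizes, per-bead
    state frequencies) as TSV files in ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    comments = {
        "configurations": "joint (n_tails, n_trains, n_loops) histogram, percent of structures",
        "sizes": "beads per segment, percent of segments of each kind",
        "per_bead": "percent of samples with each bead in tail/train/loop",
    }
    for name, frame in census.items():
        p = out_dir / f"census_{name}.tsv"
        write_table(frame, p, comments[name], meta)
        paths[name] = p
    return paths
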