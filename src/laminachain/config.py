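"""Run configuration: TOML load/save, validation, hashing.

The config file has three optional tables — ``[model]``, ``[schedule]``
and ``[run]`` — whose keys map onto ModelParams / SweepSchedule fields
and the output settings. Omitted keys take the model defaults (paper
geometry, desk-scale sweep schedule); unknown keys are rejected.
"""
from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass
from pathlib import Path
from typing import Any

from .params import ModelParams, SweepSchedule

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]

_MODEL_KEYS = {
    "n_beads", "r_bead", "persistence_length", "r_nucleus", "eps_ads",
    "n_anchors", "anchor_separation", "h_anchor", "adsorption_zone",
    "move_radius", "excluded_volume", "wall",
}
_SCHEDULE_KEYS = {"total_sweeps", "pre_equilibration_sweeps", "sample_every",
                  "diffusion_nm2_per_s"}
_RUN_KEYS = {"n_replicates", "seed", "output_dir", "verbosity"}


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration: model parameters + output settings."""

    params: ModelParams
    output_dir: str | None = None
    verbosity: str = "info"

    def to_dict(self) -> dict[str, Any]:
        d = self.params.to_dict()
        sched = d.pop("schedule")
        return {
            "model": {k: d[k] for k in sorted(_MODEL_KEYS)},
            "schedule": sched,
            "run": {
                "n_replicates": d["n_replicates"],
                "seed": d["seed"],
                "output_dir": self.output_dir,
                "verbosity": self.verbosity,
            },
        }

    @property
    def hash(self) -> str:
        return config_hash(self)


def config_hash(config: RunConfig) -> str:
    """Short stable digest of the full configuration (recorded in every
    output file so results can be traced to their settings)."""
    canon = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _check_keys(section: str, given: dict, allowed: set) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ValueError(
            f"unknown key(s) in [{section}]: {', '.join(sorted(unknown))}")


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a TOML run configuration.

    Raises ValueError with the offending key for malformed or physically
    invalid settings (e.g. anchor_separation beyond the contour length).
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    _check_keys("<root>", raw, {"model", "schedule", "run"})
    model = raw.get("model", {})
    sched = raw.get("schedule", {})
    run = raw.get("run", {})
    _check_keys("model", model, _MODEL_KEYS)
    _check_keys("schedule", sched, _SCHEDULE_KEYS)
    _check_keys("run", run, _RUN_KEYS)
    try:
        schedule = SweepSchedule(**sched)
        params = ModelParams(
            schedule=schedule,
            n_replicates=run.get("n_replicates", 3),
            seed=run.get("seed", 0),
            **model,
        )
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid configuration in {path}: {exc}") from exc
    return RunConfig(params=params,
                     output_dir=run.get("output_dir"),
                     verbosity=run.get("verbosity", "info"))


def _toml_value(v: Any) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    return json.dumps(str(v))


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write the configuration as TOML (round-trips through load_config
    to an identical hash)."""
    d = config.to_dict()
    lines = []
    for section in ("model", "schedule", "run"):
        lines.append(f"[{section}]")
        for k, v in d[section].items():
            if v is None:
                continue
            lines.append(f"{k} = {_toml_value(v)}")
        lines.append("")
    Path(path).write_text("\n".join(lines))
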