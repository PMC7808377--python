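"""Physical and algorithmic parameters of the chromatin-at-the-periphery model.

Units convention: lengths in nm, energies in units of k_BT (k_BT ≡ 1; no
temperature parameter is exposed). The nucleus is a sphere of radius
``r_nucleus`` centered at the origin; "height above NP" of a point is
``r_nucleus − |r|`` (negative outside the nucleus).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

__all__ = ["SweepSchedule", "ModelParams", "PAPER_SCHEDULE", "DESK_SCHEDULE"]


@dataclass(frozen=True)
class SweepSchedule:
    """Monte Carlo sweep budget and sampling cadence.

    One MCSweep is a sequence of MCSteps in which each free bead attempts
    on average one move. Physical time is metadata only: each sweep maps to
    ``dt = dr_max² / D`` seconds, with ``D`` the chromatin diffusion
    constant near the periphery (default 10⁻⁴ µm²/s = 100 nm²/s, so the
    default move radius of 3 nm gives dt = 0.09 s/sweep).
    """

    total_sweeps: int = 10_000_000
    pre_equilibration_sweeps: int = 100_000
    sample_every: int = 1_000
    diffusion_nm2_per_s: float = 100.0

    def __post_init__(self) -> None:
        if self.total_sweeps <= 0:
            raise ValueError("total_sweeps must be positive")
        if not 0 <= self.pre_equilibration_sweeps < self.total_sweeps:
            raise ValueError(
                "pre_equilibration_sweeps must satisfy "
                "0 <= pre_equilibration_sweeps < total_sweeps"
            )
        if self.sample_every < 1:
            raise ValueError("sample_every must be >= 1")
        if self.diffusion_nm2_per_s <= 0:
            raise ValueError("diffusion_nm2_per_s must be positive")

    def dt_per_sweep(self, dr_max_nm: float) -> float:
        """Duration of one sweep in seconds, from dt = dr²/D."""
        return dr_max_nm**2 / self.diffusion_nm2_per_s

    def n_samples(self) -> int:
        """Number of configurations sampled after pre-equilibration."""
        return (self.total_sweeps - self.pre_equilibration_sweeps) // self.sample_every


#: Publication-scale schedule (5×10⁸ sweeps; hours of compute per condition).
PAPER_SCHEDULE = SweepSchedule(total_sweeps=500_000_000,
                               pre_equilibration_sweeps=5_000_000,
                               sample_every=1_000)

#: Desk-scale schedule (default): minutes per condition on one CPU.
DESK_SCHEDULE = SweepSchedule()


@dataclass(frozen=True)
class ModelParams:
    """All physical constants and run settings of the model.

    The chain is ``n_beads`` hard beads of radius ``r_bead`` (defaults 12
    and 15 nm, i.e. a ~50 kb chromatin segment of contour length 330...
    2·r_bead·(n_beads−1) = 360 nm), bending stiffness set by the
    persistence length ``persistence_length`` and anchored to the inner
    surface of the nuclear sphere by one or two anchors at height
    ``h_anchor`` above the periphery. ``eps_ads`` sets the depth scale of
    the adsorbing surface potential (0 = neutral surface).

    ``excluded_volume`` and ``wall`` are validation switches used to turn
    individual Hamiltonian terms off for analytic cross-checks (free-chain
    statistics); production runs keep them True.
    """

    n_beads: int = 12
    r_bead: float = 15.0
    persistence_length: float = 50.0
    r_nucleus: float = 5000.0
    eps_ads: float = 0.0
    n_anchors: int = 1
    anchor_separation: float = 50.0  # d_E, used only when n_anchors == 2
    h_anchor: float | None = None  # defaults to r_bead
    adsorption_zone: float = 15.0
    move_radius: float | None = None  # defaults to r_bead / 5
    schedule: SweepSchedule = field(default_factory=SweepSchedule)
    n_replicates: int = 3
    seed: int = 0
    excluded_volume: bool = True
    wall: bool = True

    def __post_init__(self) -> None:
        if self.n_beads < 2:
            raise ValueError("n_beads must be >= 2")
        if self.r_bead <= 0:
            raise ValueError("r_bead must be positive")
        if self.persistence_length <= 0:
            raise ValueError("persistence_length must be positive")
        if self.eps_ads < 0:
            raise ValueError("eps_ads must be >= 0")
        if self.n_anchors not in (1, 2):
            raise ValueError("n_anchors must be 1 or 2")
        if self.h_anchor is None:
            object.__setattr__(self, "h_anchor", self.r_bead)
        if self.move_radius is None:
            object.__setattr__(self, "move_radius", self.r_bead / 5.0)
        if self.h_anchor <= 0:
            raise ValueError("h_anchor must be positive")
        if self.move_radius <= 0:
            raise ValueError("move_radius must be positive")
        if self.adsorption_zone < 0:
            raise ValueError("adsorption_zone must be >= 0")
        if self.r_nucleus < 10.0 * self.contour_length:
            raise ValueError(
                f"r_nucleus={self.r_nucleus} too small: the model assumes "
                f"r_nucleus >> contour length (require >= 10*L_C = "
                f"{10.0 * self.contour_length})"
            )
        if self.n_anchors == 2 and not 0.0 <= self.anchor_separation <= self.contour_length:
            raise ValueError(
                f"anchor_separation={self.anchor_separation} is unreachable: "
                f"require 0 <= d_E <= contour length L_C = {self.contour_length}"
            )
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    # ---- derived geometric/energetic constants -------------------------

    @property
    def contour_length(self) -> float:
        """Material contour length L_C = 2·r_bead·N nm (default 360).

        This is the center-to-center span of the taut chain,
        2·r_bead·(N−1), plus one bead radius at each end — i.e. N bead
        diameters of chromatin fiber.
        """
        return 2.0 * self.r_bead * self.n_beads

    @property
    def bond_length(self) -> float:
        """Equilibrium bond length 2·r_bead nm."""
        return 2.0 * self.r_bead

    @property
    def sigma_wca(self) -> float:
        """WCA collision diameter σ, from 2·r_bead = 2^(1/6)·σ."""
        return 2.0 * self.r_bead / 2.0 ** (1.0 / 6.0)

    @property
    def wca_cutoff(self) -> float:
        """WCA cutoff 2^(1/6)·σ = 2·r_bead."""
        return 2.0 * self.r_bead

    @property
    def bending_k(self) -> float:
        """Bending prefactor L_P/(2·r_bead), in k_BT per (1−cos θ)."""
        return self.persistence_length / (2.0 * self.r_bead)

    @property
    def stretching_k(self) -> float:
        """Stretching prefactor L_P/r_bead³, in k_BT/nm²."""
        return self.persistence_length / self.r_bead**3

    @property
    def wall_k(self) -> float:
        """Escape-restoring spring stiffness k_BT/r_bead², in k_BT/nm²."""
        return 1.0 / self.r_bead**2

    @property
    def attraction_radius(self) -> float:
        """Radius of the attractive sphere over which the 12-6 pair
        interaction is integrated (the nuclear periphery itself)."""
        return self.r_nucleus

    @property
    def anchor_radius(self) -> float:
        """Radial distance of anchor sites: r_nucleus − h_anchor."""
        return self.r_nucleus - self.h_anchor

    @property
    def train_threshold(self) -> float:
        """Center-to-NP height at/below which a bead counts as adsorbed:
        one bead radius plus the adsorption zone (default 30 nm)."""
        return self.r_bead + self.adsorption_zone

    @property
    def dt_per_sweep(self) -> float:
        """Physical duration of one sweep in seconds (dr²/D)."""
        return self.schedule.dt_per_sweep(self.move_radius)

    def replicate_seed(self, replicate_id: int) -> int:
        """Seed of replicate ``replicate_id`` (base seed + replicate id)."""
        return self.seed + replicate_id

    def replace(self, **kwargs: Any) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        """Flat JSON-serializable echo of all fields (schedule nested)."""
        return {
            "n_beads": self.n_beads,
            "r_bead": self.r_bead,
            "persistence_length": self.persistence_length,
            "r_nucleus": self.r_nucleus,
            "eps_ads": self.eps_ads,
            "n_anchors": self.n_anchors,
            "anchor_separation": self.anchor_separation,
            "h_anchor": self.h_anchor,
            "adsorption_zone": self.adsorption_zone,
            "move_radius": self.move_radius,
            "schedule": {
                "total_sweeps": self.schedule.total_sweeps,
                "pre_equilibration_sweeps": self.schedule.pre_equilibration_sweeps,
                "sample_every": self.schedule.sample_every,
                "diffusion_nm2_per_s": self.schedule.diffusion_nm2_per_s,
            },
            "n_replicates": self.n_replicates,
            "seed": self.seed,
            "excluded_volume": self.excluded_volume,
            "wall": self.wall,
        }

    @staticmethod
    def from_dict(d: dict[str, Any]) -> "ModelParams":
        d = dict(d)
        sched = d.pop("schedule", None)
        if sched is not None:
            d["schedule"] = SweepSchedule(**sched)
        return ModelParams(**d)
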