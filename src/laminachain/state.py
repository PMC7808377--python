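"""Chain state: bead coordinates, anchors, and geometric conventions."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParams

__all__ = ["ChainState", "height_above_np", "anchor_sites", "initialize_chain"]


def height_above_np(coords: np.ndarray, params: ModelParams) -> np.ndarray | float:
    """Distance from point(s) to the nuclear periphery, r_nucleus − |r|.

    Positive inside the nucleus, zero on the periphery, negative outside.
    Accepts a single 3-vector or an (..., 3) array.
    """
    coords = np.asarray(coords, dtype=float)
    r = np.linalg.norm(coords, axis=-1)
    return params.r_nucleus - r


def anchor_sites(params: ModelParams) -> np.ndarray:
    """Fixed anchor positions on the sphere of radius r_nucleus − h_anchor.

    Anchor 1 sits on the +z axis. For two anchors, anchor 2 lies in the
    x–z plane at chord (Euclidean) distance d_E from anchor 1.
    """
    ra = params.anchor_radius
    sites = [np.array([0.0, 0.0, ra])]
    if params.n_anchors == 2:
        alpha = 2.0 * np.arcsin(params.anchor_separation / (2.0 * ra))
        sites.append(np.array([ra * np.sin(alpha), 0.0, ra * np.cos(alpha)]))
    return np.array(sites)


@dataclass
class ChainState:
    """Evolving Monte Carlo state: coordinates + anchor bookkeeping.

    ``coords`` is an (n_beads, 3) array in nm with the nucleus center at
    the origin; ``pinned`` flags beads that coincide exactly with an
    anchor site and never move.
    """

    coords: np.ndarray
    pinned: np.ndarray
    anchor_sites: np.ndarray

    def copy(self) -> "ChainState":
        return ChainState(self.coords.copy(), self.pinned.copy(),
                          self.anchor_sites.copy())

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]

    def free_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.pinned)

    def heights(self, params: ModelParams) -> np.ndarray:
        return height_above_np(self.coords, params)

    def validate(self, params: ModelParams) -> None:
        """Sampling-time sanity checks (raise AssertionError on corruption).

        Excursions beyond the nucleus are energetically penalized rather
        than forbidden, so the radial check allows a 5·r_bead margin.
        """
        if params.wall:
            r = np.linalg.norm(self.coords, axis=1)
            assert np.all(r <= params.r_nucleus + 5.0 * params.r_bead), \
                "bead center far outside the nucleus: corrupt state"
        bonds = np.linalg.norm(np.diff(self.coords, axis=0), axis=1)
        # connectivity band: equilibrium length + 8 thermal standard
        # deviations of the harmonic bond (the bond spring softens as
        # L_P/r_bead^3, so the band must scale with stiffness)
        sigma_bond = np.sqrt(1.0 / (2.0 * params.stretching_k))
        bond_max = max(4.0 * params.r_bead,
                       params.bond_length + 8.0 * sigma_bond)
        assert np.all((bonds > 0.0) & (bonds < bond_max)), \
            "bond length outside the thermal connectivity band: corrupt state"
        pinned_idx = np.flatnonzero(self.pinned)
        for k, i in enumerate(pinned_idx):
            assert np.array_equal(self.coords[i], self.anchor_sites[k]), \
                "pinned bead does not coincide with its anchor site"


def initialize_chain(params: ModelParams) -> ChainState:
    """Straight-chain initialization at constant height h_anchor above NP.

    Bead 1 is placed at (and pinned to) anchor site 1; the remaining beads
    follow a great-circle arc on the sphere of radius r_nucleus − h_anchor
    with consecutive chord separation 2·r_bead, so every bead center starts
    at the anchor height and every bond at its equilibrium length. With two
    anchors the arc heads toward anchor site 2; bead N starts free and is
    pinned later by the tethering protocol.
    """
    if params.n_anchors == 2 and params.anchor_separation > params.contour_length:
        raise ValueError("anchor_separation exceeds the contour length")
    ra = params.anchor_radius
    sites = anchor_sites(params)
    # angular step whose chord on the sphere of radius ra is one bond length
    phi = 2.0 * np.arcsin(params.r_bead / ra)
    k = np.arange(params.n_beads)
    coords = np.column_stack([
        ra * np.sin(k * phi),
        np.zeros(params.n_beads),
        ra * np.cos(k * phi),
    ])
    pinned = np.zeros(params.n_beads, dtype=bool)
    pinned[0] = True
    coords[0] = sites[0]
    return ChainState(coords=coords, pinned=pinned, anchor_sites=sites)
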