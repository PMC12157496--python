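"""Lattice occupancy state and initialization.

Each site of the grid holds at most one agent: a tumor cell, an astrocyte
(anti- or pro-metastatic), or an inert neutral filler agent.  A parallel
float field carries the chemotherapy concentration.  Astrocyte and neutral
positions are fixed for the whole run; only tumor cells appear (division)
and disappear (chemotherapy death).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Optional

import numpy as np

from .config import ConfigurationError, SimulationConfig
from . import layouts


class CellKind(IntEnum):
    """Integer codes of the occupancy grid."""

    EMPTY = 0
    TUMOR = 1
    ASTRO_ANTI = 2
    ASTRO_PRO = 3
    NEUTRAL = 4


@dataclass
class LatticeState:
    """Mutable state of a running simulation.

    ``occupancy`` is an int8 grid of :class:`CellKind` codes; ``drug`` the
    non-negative chemotherapy concentration field on the same grid.
    """

    occupancy: np.ndarray
    drug: np.ndarray
    timestep: int = 0
    treatment_active: bool = False
    treatment_start_step: Optional[int] = None

    def count(self, kind: CellKind) -> int:
        return int(np.count_nonzero(self.occupancy == kind))

    @property
    def tumor_count(self) -> int:
        return self.count(CellKind.TUMOR)

    @property
    def n_anti(self) -> int:
        return self.count(CellKind.ASTRO_ANTI)

    @property
    def n_pro(self) -> int:
        return self.count(CellKind.ASTRO_PRO)

    def copy(self) -> "LatticeState":
        return LatticeState(
            occupancy=self.occupancy.copy(),
            drug=self.drug.copy(),
            timestep=self.timestep,
            treatment_active=self.treatment_active,
            treatment_start_step=self.treatment_start_step,
        )


def initialize(config: SimulationConfig, rng: np.random.Generator | None = None) -> LatticeState:
    """Build the initial lattice for a configuration.

    A single tumor cell sits at the central site; astrocytes are placed by
    the configured layout (all anti-metastatic at t=0) and inert neutral
    agents top the non-tumor compartment up to ``config.non_tumor_total``.
    The drug field starts at zero.  Identical config and seed give an
    identical lattice.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    shape = (config.grid_width, config.grid_height)
    occ = np.full(shape, CellKind.EMPTY, dtype=np.int8)
    center = (config.grid_width // 2, config.grid_height // 2)
    occ[center] = CellKind.TUMOR

    astro_sites = layouts.place_astrocytes(
        config.layout,
        config.astrocyte_count,
        shape,
        rng,
        params=config.layout_params,
        reserved=center,
    )
    if astro_sites.shape[0] != config.astrocyte_count:
        raise ConfigurationError("layout failed to place the requested astrocyte count")
    occ[astro_sites[:, 0], astro_sites[:, 1]] = CellKind.ASTRO_ANTI

    neutral_sites = layouts.fill_neutral(occ, config.neutral_count, rng)
    occ[neutral_sites[:, 0], neutral_sites[:, 1]] = CellKind.NEUTRAL

    drug = np.zeros(shape, dtype=float)
    return LatticeState(occupancy=occ, drug=drug)
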