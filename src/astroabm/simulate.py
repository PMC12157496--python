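"""Per-step scheduler and run orchestration.

One timestep (about 17 h of biological time) applies, in order:

1. the chemotherapy field update, if treatment has been triggered
   (ADI diffusion with the schedule's boundary condition, then decay and
   tumor uptake);
2. one shuffled switching pass over the anti-metastatic astrocytes;
3. one shuffled pass over the tumor cells, each cell first checked for
   chemotherapy death and, if it survives, attempting division.

All randomness comes from a single generator seeded by the configuration,
so identical config and seed reproduce a run bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import chemo, lattice, morphometrics, tumor
from .astrocytes import astrocyte_pass
from .config import SimulationConfig
from .kernel import InfluenceKernel
from .lattice import CellKind, LatticeState

logger = logging.getLogger("astroabm")

__all__ = ["Simulation", "run_simulation", "step"]


@dataclass
class Simulation:
    """A configured run: owns the lattice, the RNG stream and the kernel."""

    config: SimulationConfig
    state: LatticeState = field(init=False)
    rng: np.random.Generator = field(init=False, repr=False)
    kernel: InfluenceKernel = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.rng = np.random.default_rng(self.config.seed)
        ap = self.config.astro_params
        self.kernel = InfluenceKernel(
            steepness=ap.steepness, half_distance=ap.half_distance
        )
        self.state = lattice.initialize(self.config, self.rng)
        self._was_dosing = False

    # ------------------------------------------------------------- stepping
    def step(self) -> LatticeState:
        """Advance one timestep in place and return the state."""
        cfg = self.config
        state = self.state
        occ = state.occupancy

        previously_active = state.treatment_active
        dosing = chemo.update_treatment_state(state, cfg.chemo_params)
        if state.treatment_active and not previously_active:
            logger.info(
                "treatment triggered at step %d (tumor count %d)",
                state.timestep,
                state.tumor_count,
            )
        if dosing != self._was_dosing:
            logger.info(
                "dosing %s at step %d", "on" if dosing else "off", state.timestep
            )
            self._was_dosing = dosing

        death_field: Optional[np.ndarray] = None
        if state.treatment_active:
            cp = cfg.chemo_params
            state.drug = chemo.diffuse(
                state.drug, cp.diffusion, dosing, cp.boundary_conc
            )
            state.drug = chemo.decay_and_uptake(
                state.drug, occ, cp.retention, cp.uptake_fraction
            )
            death_field = chemo.death_probability_field(state.drug, occ, cp)

        if cfg.switching_enabled:
            astrocyte_pass(occ, cfg.astro_params, self.kernel, self.rng)

        self._tumor_pass(death_field)
        state.timestep += 1
        return state

    def _tumor_pass(self, death_field: Optional[np.ndarray]) -> None:
        """Shuffled sequential pass: death check, then division attempt.

        The division-probability field depends only on astrocyte positions
        and states, which are frozen during the pass, so it is evaluated
        once; crowding (empty-neighbor availability) is read from the live
        grid so daughters placed earlier in the pass block later ones.
        """
        occ = self.state.occupancy
        cells = np.argwhere(occ == CellKind.TUMOR)
        if cells.shape[0] == 0:
            return
        order = self.rng.permutation(cells.shape[0])
        cells = cells[order]
        p_div = tumor.division_probability_field(
            occ, self.kernel, self.config.tumor_params
        )
        for x, y in cells:
            site = (int(x), int(y))
            if death_field is not None:
                if self.rng.random() < death_field[site]:
                    occ[site] = CellKind.EMPTY
                    continue
            tumor.division_attempt(site, occ, p_div[site], self.rng)

    # ------------------------------------------------------------------ run
    def run(self, record_initial: bool = True) -> pd.DataFrame:
        """Run ``n_steps`` steps, recording morphology metrics each step."""
        rows = []
        if record_initial:
            rows.append(self._metrics_row())
        for _ in range(self.config.n_steps):
            self.step()
            rows.append(self._metrics_row())
            logger.debug(
                "step %d: %d tumor cells", self.state.timestep, rows[-1]["tumor_count"]
            )
        return pd.DataFrame(rows)

    def _metrics_row(self) -> dict:
        state = self.state
        m = morphometrics.compute_metrics(state.occupancy, state.timestep)
        dosing = False
        if state.treatment_active and self.config.chemo_params is not None:
            dosing = chemo.is_dosing(
                state.timestep - state.treatment_start_step, self.config.chemo_params
            )
        return {
            "step": state.timestep,
            "tumor_count": m.tumor_count,
            "n_anti": state.n_anti,
            "n_pro": state.n_pro,
            "fractal_dimension": m.fractal_dimension,
            "lacunarity": m.lacunarity,
            "eccentricity": m.eccentricity,
            "mean_drug": float(state.drug.mean()),
            "treatment_on": dosing,
        }


def step(state: LatticeState, config: SimulationConfig,
         rng: np.random.Generator | None = None) -> LatticeState:
    """Functional single-step interface around :class:`Simulation`.

    Builds the kernel on the fly; ``rng`` defaults to a generator seeded by
    the configuration.  For long runs prefer the class, which keeps one
    stream across steps.
    """
    sim = Simulation.__new__(Simulation)
    sim.config = config
    sim.rng = rng if rng is not None else np.random.default_rng(config.seed)
    ap = config.astro_params
    sim.kernel = InfluenceKernel(steepness=ap.steepness, half_distance=ap.half_distance)
    sim.state = state
    sim._was_dosing = False
    return sim.step()


def run_simulation(config: SimulationConfig) -> tuple[LatticeState, pd.DataFrame]:
    """Run a full simulation; returns the final state and per-step metrics."""
    sim = Simulation(config)
    metrics = sim.run()
    return sim.state, metrics
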