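"""Simulation configuration.

All tunable model parameters live here, grouped the way the model uses them:
astrocyte switching (:class:`AstrocyteParams`), tumor division
(:class:`TumorParams`), chemotherapy (:class:`ChemoParams`) and the run-level
settings (:class:`SimulationConfig`).  Configurations round-trip through flat
dictionaries and JSON/YAML files so that every run can be replayed from its
manifest.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

#: Discrete levels explored for the switching-curve steepness.
SWITCH_SENSITIVITY_LEVELS = (8, 16, 32)
#: Discrete levels explored for the division-curve steepness.
DIVISION_SENSITIVITY_LEVELS = (4, 8, 16)

LAYOUT_KINDS = ("uniform", "random", "clustered", "radial", "inverse_radial", "gradient")


class ConfigurationError(ValueError):
    """Raised when a configuration violates a model invariant."""


def _check_unit(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ConfigurationError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass
class AstrocyteParams:
    """Parameters of the tumor -> astrocyte influence and phenotype switch.

    Attributes
    ----------
    effect_per_tumor_cell : float
        kappa, the influence magnitude a single tumor cell exerts on a
        nearby astrocyte, in [0, 1].
    switch_sensitivity : int
        S_A, steepness of the sigmoidal switching curve; one of {8, 16, 32}.
    conversion_threshold : float
        theta, the normalized influence at which the switch probability
        is 50%, in [0, 1].
    steepness : float
        S, steepness of the distance-decay sigmoid (fixed at 3 in the
        baseline model).
    half_distance : float
        d, the lattice distance at which per-cell influence halves
        (fixed at 1.5).
    """

    effect_per_tumor_cell: float = 0.8
    switch_sensitivity: int = 16
    conversion_threshold: float = 0.2
    steepness: float = 3.0
    half_distance: float = 1.5

    def __post_init__(self) -> None:
        _check_unit("effect_per_tumor_cell", self.effect_per_tumor_cell)
        _check_unit("conversion_threshold", self.conversion_threshold)
        if int(self.switch_sensitivity) not in SWITCH_SENSITIVITY_LEVELS:
            raise ConfigurationError(
                f"switch_sensitivity must be one of {SWITCH_SENSITIVITY_LEVELS}"
            )
        self.switch_sensitivity = int(self.switch_sensitivity)
        if self.steepness <= 0 or self.half_distance <= 0:
            raise ConfigurationError("steepness and half_distance must be positive")


@dataclass
class TumorParams:
    """Parameters of the astrocyte -> tumor division modulation.

    ``effect_anti_met`` (alpha) scales the suppressive influence of
    anti-metastatic astrocytes, ``effect_pro_met`` (beta) the promoting
    influence of reprogrammed (pro-metastatic) astrocytes; both use the same
    distance-decay kernel as the astrocyte switch.  ``division_sensitivity``
    (S_T) is the steepness of the division-probability sigmoid; at zero net
    influence the division probability is exactly 0.5 per step.
    """

    effect_anti_met: float = 0.5
    effect_pro_met: float = 0.9
    division_sensitivity: int = 8
    steepness: float = 3.0
    half_distance: float = 1.5

    def __post_init__(self) -> None:
        _check_unit("effect_anti_met", self.effect_anti_met)
        _check_unit("effect_pro_met", self.effect_pro_met)
        if int(self.division_sensitivity) not in DIVISION_SENSITIVITY_LEVELS:
            raise ConfigurationError(
                f"division_sensitivity must be one of {DIVISION_SENSITIVITY_LEVELS}"
            )
        self.division_sensitivity = int(self.division_sensitivity)
        if self.steepness <= 0 or self.half_distance <= 0:
            raise ConfigurationError("steepness and half_distance must be positive")


@dataclass
class ChemoParams:
    """Chemotherapy field and schedule parameters.

    The drug diffuses from the grid boundary (Dirichlet C = ``boundary_conc``
    while dosing, zero-flux otherwise), is retained by the factor
    ``retention`` per step, and is taken up by tumor cells.  Per-cell kill
    probability is a sigmoid of the gap-junction-modulated effective
    concentration.  Numeric defaults are documented stand-ins chosen for
    qualitative realism at the default grid scale; see docs/methods.md.
    """

    diffusion: float = 100.0          # lattice^2 per step
    retention: float = 0.98           # lambda, per-step retention multiplier
    boundary_conc: float = 1.0        # Cb during dosing
    uptake_fraction: float = 0.02     # fraction absorbed per tumor cell per step
    gap_junction_factor: float = 0.5  # Gf in [0, 1]
    kill_steepness: float = 10.0      # k
    kill_half_conc: float = 0.5       # T, concentration of 50% kill
    start_threshold: int = 3000       # tumor count triggering therapy
    steps_on: int = 14                # dosing steps per cycle
    steps_off: int = 7                # rest steps per cycle

    def __post_init__(self) -> None:
        for name in ("retention", "uptake_fraction", "gap_junction_factor"):
            _check_unit(name, getattr(self, name))
        for name in ("diffusion", "boundary_conc", "kill_steepness", "kill_half_conc"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.start_threshold < 1 or self.steps_on < 1 or self.steps_off < 0:
            raise ConfigurationError("invalid treatment schedule")

    @property
    def cycle_length(self) -> int:
        return self.steps_on + self.steps_off


@dataclass
class LayoutParams:
    """Free parameters of the clustered / radial / gradient layouts."""

    n_clusters: int = 25
    cluster_spread: float = 8.0
    gradient_axis: str = "x"

    def __post_init__(self) -> None:
        if self.n_clusters < 1 or self.cluster_spread <= 0:
            raise ConfigurationError("invalid clustered-layout parameters")
        if self.gradient_axis not in ("x", "y"):
            raise ConfigurationError("gradient_axis must be 'x' or 'y'")


@dataclass
class SimulationConfig:
    """Full configuration of one simulation run.

    The non-tumor compartment (astrocytes + inert neutral agents) is held at
    ``non_tumor_total`` sites regardless of astrocyte density, so density
    comparisons are not confounded by crowding.  ``non_tumor_total`` defaults
    to half the lattice (45,000 on the default 300 x 300 grid).
    """

    grid_width: int = 300
    grid_height: int = 300
    n_steps: int = 150
    astrocyte_density: float = 0.3
    non_tumor_total: Optional[int] = None
    layout: str = "random"
    switching_enabled: bool = True
    seed: int = 0
    astro_params: AstrocyteParams = field(default_factory=AstrocyteParams)
    tumor_params: TumorParams = field(default_factory=TumorParams)
    chemo_params: Optional[ChemoParams] = None
    layout_params: LayoutParams = field(default_factory=LayoutParams)

    def __post_init__(self) -> None:
        if self.grid_width < 9 or self.grid_height < 9:
            raise ConfigurationError("grid must be at least 9x9")
        if self.n_steps < 1:
            raise ConfigurationError("n_steps must be >= 1")
        if not 0.0 <= self.astrocyte_density <= 0.5:
            raise ConfigurationError("astrocyte_density must lie in [0, 0.5]")
        if self.layout not in LAYOUT_KINDS:
            raise ConfigurationError(f"layout must be one of {LAYOUT_KINDS}")
        if self.non_tumor_total is None:
            self.non_tumor_total = self.n_sites // 2
        if self.astrocyte_count > self.non_tumor_total:
            raise ConfigurationError(
                "astrocyte_density * grid sites exceeds non_tumor_total"
            )
        if self.non_tumor_total > self.n_sites - 1:
            raise ConfigurationError("non_tumor_total leaves no room for the tumor")

    @property
    def n_sites(self) -> int:
        return self.grid_width * self.grid_height

    @property
    def astrocyte_count(self) -> int:
        return int(round(self.astrocyte_density * self.n_sites))

    @property
    def neutral_count(self) -> int:
        return self.non_tumor_total - self.astrocyte_count

    # ---------------------------------------------------------------- i/o
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.chemo_params is None:
            d["chemo_params"] = None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if d.get("astro_params") is not None and not isinstance(
            d["astro_params"], AstrocyteParams
        ):
            d["astro_params"] = AstrocyteParams(**d["astro_params"])
        if d.get("tumor_params") is not None and not isinstance(
            d["tumor_params"], TumorParams
        ):
            d["tumor_params"] = TumorParams(**d["tumor_params"])
        if d.get("chemo_params") is not None and not isinstance(
            d["chemo_params"], ChemoParams
        ):
            d["chemo_params"] = ChemoParams(**d["chemo_params"])
        if d.get("layout_params") is not None and not isinstance(
            d["layout_params"], LayoutParams
        ):
            d["layout_params"] = LayoutParams(**d["layout_params"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(d, indent=2))
        else:
            path.write_text(yaml.safe_dump(d, sort_keys=False))
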