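"""Astrocyte reprogramming: influence accumulation and the anti->pro switch.

Each anti-metastatic astrocyte integrates the distance-weighted influence of
every tumor cell in its 7x7 neighborhood, normalizes by the theoretical
maximum (all 48 sites tumor-occupied), and switches irreversibly to the
pro-metastatic phenotype with a sigmoidal probability of that normalized
influence.  Pro-metastatic astrocytes never revert; astrocytes never move.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .config import AstrocyteParams
from .kernel import InfluenceKernel, influence_weight  # noqa: F401  (re-export)
from .lattice import CellKind

__all__ = [
    "influence_weight",
    "cumulative_influence",
    "cumulative_influence_field",
    "normalize_influence",
    "switch_probability",
    "astrocyte_pass",
]

_NORMALIZATION_TOL = 1e-9


def cumulative_influence(
    site: tuple[int, int],
    occupancy: np.ndarray,
    kernel: InfluenceKernel,
    kappa: float,
) -> float:
    """Raw cumulative tumor influence on the astrocyte at ``site``.

    Sums ``kappa * w(d_i)`` over tumor cells in the edge-truncated 7x7
    neighborhood; zero when no tumor cell is nearby.
    """
    x, y = site
    total = 0.0
    for (ox, oy), w in zip(kernel.offsets, kernel.weights):
        nx, ny = x + ox, y + oy
        if 0 <= nx < occupancy.shape[0] and 0 <= ny < occupancy.shape[1]:
            if occupancy[nx, ny] == CellKind.TUMOR:
                total += kappa * w
    return total


def cumulative_influence_field(
    occupancy: np.ndarray, kernel: InfluenceKernel, kappa: float
) -> np.ndarray:
    """Raw tumor influence at every site, via 2-D convolution.

    Off-grid neighbors contribute zero (edge truncation), matching the
    per-site accumulation exactly.
    """
    tumor = (occupancy == CellKind.TUMOR).astype(float)
    return kappa * ndimage.convolve(tumor, kernel.grid, mode="constant", cval=0.0)


def normalize_influence(raw: float, kernel: InfluenceKernel, kappa: float) -> float:
    """Normalize raw influence by the theoretical maximum ``kappa * I_max``.

    Raises if ``raw`` exceeds the maximum beyond numerical tolerance; clamps
    tiny overshoot so the result is always in [0, 1].  Zero magnitude maps
    to zero influence.
    """
    if raw < 0:
        raise ValueError("raw influence must be non-negative")
    if kappa == 0.0:
        return 0.0
    maximum = kappa * kernel.i_max
    if raw > maximum * (1.0 + _NORMALIZATION_TOL) + _NORMALIZATION_TOL:
        raise ValueError(
            f"raw influence {raw} exceeds theoretical maximum {maximum}"
        )
    return min(raw / maximum, 1.0)


def switch_probability(
    i_norm: float | np.ndarray, sensitivity: float, threshold: float
) -> float | np.ndarray:
    """Per-step anti->pro switch probability at normalized influence.

    ``1 / (1 + exp(-S_A * (I_norm - theta)))``: exactly 0.5 when the
    normalized influence equals the conversion threshold, for any steepness.
    """
    i_norm = np.asarray(i_norm, dtype=float)
    out = 1.0 / (1.0 + np.exp(-sensitivity * (i_norm - threshold)))
    return float(out) if out.ndim == 0 else out


def astrocyte_pass(
    occupancy: np.ndarray,
    params: AstrocyteParams,
    kernel: InfluenceKernel,
    rng: np.random.Generator,
) -> int:
    """One switching pass over all anti-metastatic astrocytes.

    Every anti-astrocyte, visited once in a freshly shuffled order, draws a
    uniform variate and switches iff the draw falls below its switch
    probability.  Switches within a pass do not feed back on each other
    (only tumor cells contribute influence), so the shuffled sequential
    scheme and this vectorized evaluation are exactly equivalent.

    Mutates ``occupancy`` in place; returns the number of switches.
    """
    anti = np.argwhere(occupancy == CellKind.ASTRO_ANTI)
    if anti.shape[0] == 0:
        return 0
    order = rng.permutation(anti.shape[0])
    anti = anti[order]
    raw = cumulative_influence_field(occupancy, kernel, params.effect_per_tumor_cell)
    maximum = params.effect_per_tumor_cell * kernel.i_max
    if maximum > 0:
        i_norm = np.clip(raw[anti[:, 0], anti[:, 1]] / maximum, 0.0, 1.0)
    else:
        i_norm = np.zeros(anti.shape[0])
    p = switch_probability(
        i_norm, params.switch_sensitivity, params.conversion_threshold
    )
    draws = rng.random(anti.shape[0])
    switched = draws < p
    occupancy[anti[switched, 0], anti[switched, 1]] = CellKind.ASTRO_PRO
    return int(switched.sum())
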