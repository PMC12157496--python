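"""Tumor division: astrocyte-modulated probability and the division attempt.

Anti-metastatic astrocytes contribute negative (suppressive) influence and
pro-metastatic astrocytes positive (promoting) influence, both through the
same sigmoidal distance kernel over the 7x7 neighborhood.  The signed sum is
normalized to [-1, 1] and mapped through a sigmoid so that the per-step
division probability is exactly 0.5 in the absence of astrocyte influence.
A dividing cell places its daughter on a uniformly chosen empty site of its
3x3 Moore neighborhood; with no empty neighbor the division silently fails.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .config import TumorParams
from .kernel import InfluenceKernel
from .lattice import CellKind

__all__ = [
    "tumor_influence",
    "tumor_influence_field",
    "normalize_tumor_influence",
    "division_probability",
    "division_probability_field",
    "division_attempt",
]

#: Moore-neighborhood displacement vectors (3x3 minus center).
MOORE_OFFSETS = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)], dtype=int
)


def tumor_influence(
    site: tuple[int, int],
    occupancy: np.ndarray,
    kernel: InfluenceKernel,
    alpha: float,
    beta: float,
) -> float:
    """Signed raw astrocyte influence on the tumor cell at ``site``."""
    x, y = site
    total = 0.0
    for (ox, oy), w in zip(kernel.offsets, kernel.weights):
        nx, ny = x + ox, y + oy
        if 0 <= nx < occupancy.shape[0] and 0 <= ny < occupancy.shape[1]:
            code = occupancy[nx, ny]
            if code == CellKind.ASTRO_ANTI:
                total -= alpha * w
            elif code == CellKind.ASTRO_PRO:
                total += beta * w
    return total


def tumor_influence_field(
    occupancy: np.ndarray, kernel: InfluenceKernel, alpha: float, beta: float
) -> np.ndarray:
    """Signed raw influence at every site via two convolutions."""
    anti = (occupancy == CellKind.ASTRO_ANTI).astype(float)
    pro = (occupancy == CellKind.ASTRO_PRO).astype(float)
    field = np.zeros(occupancy.shape, dtype=float)
    if alpha > 0:
        field -= alpha * ndimage.convolve(anti, kernel.grid, mode="constant", cval=0.0)
    if beta > 0:
        field += beta * ndimage.convolve(pro, kernel.grid, mode="constant", cval=0.0)
    return field


def normalize_tumor_influence(
    raw: float | np.ndarray, kernel: InfluenceKernel, alpha: float, beta: float
) -> float | np.ndarray:
    """Normalize signed influence to [-1, 1].

    The normalizer is the largest achievable single-sign magnitude,
    ``max(alpha, beta) * I_max``.  When both magnitudes are zero no
    astrocyte can exert influence and the normalized value is 0 by contract.
    """
    scale = max(alpha, beta)
    if scale == 0.0:
        return np.zeros_like(np.asarray(raw, dtype=float)) if np.ndim(raw) else 0.0
    out = np.clip(np.asarray(raw, dtype=float) / (scale * kernel.i_max), -1.0, 1.0)
    return float(out) if out.ndim == 0 else out


def division_probability(
    i_norm: float | np.ndarray, sensitivity: float
) -> float | np.ndarray:
    """Per-step division probability ``1 / (1 + exp(-S_T * I_norm))``.

    Equals 0.5 at zero influence for any sensitivity, preserving the
    baseline doubling behavior in astrocyte-free tissue.
    """
    i_norm = np.asarray(i_norm, dtype=float)
    out = 1.0 / (1.0 + np.exp(-sensitivity * i_norm))
    return float(out) if out.ndim == 0 else out


def division_probability_field(
    occupancy: np.ndarray, kernel: InfluenceKernel, params: TumorParams
) -> np.ndarray:
    """Division probability at every site for the current astrocyte field.

    Valid for the whole tumor pass of one step: astrocyte states are frozen
    while tumor cells update, so one evaluation serves all cells.
    """
    raw = tumor_influence_field(
        occupancy, kernel, params.effect_anti_met, params.effect_pro_met
    )
    i_norm = normalize_tumor_influence(
        raw, kernel, params.effect_anti_met, params.effect_pro_met
    )
    return division_probability(i_norm, params.division_sensitivity)


def empty_moore_neighbors(
    occupancy: np.ndarray, site: tuple[int, int]
) -> list[tuple[int, int]]:
    """Empty sites of the 3x3 Moore neighborhood (edge-truncated)."""
    x, y = site
    w, h = occupancy.shape
    out = []
    for ox, oy in MOORE_OFFSETS:
        nx, ny = x + ox, y + oy
        if 0 <= nx < w and 0 <= ny < h and occupancy[nx, ny] == CellKind.EMPTY:
            out.append((nx, ny))
    return out


def division_attempt(
    site: tuple[int, int],
    occupancy: np.ndarray,
    p_div: float,
    rng: np.random.Generator,
) -> tuple[int, int] | None:
    """Attempt one division; returns the daughter site or ``None``.

    A uniform draw below ``p_div`` triggers division; the daughter occupies
    a uniformly chosen empty Moore neighbor.  With no empty neighbor the
    attempt is a silent no-op (the draw is still consumed, keeping the RNG
    stream independent of crowding).
    """
    if rng.random() >= p_div:
        return None
    free = empty_moore_neighbors(occupancy, site)
    if not free:
        return None
    daughter = free[int(rng.integers(len(free)))]
    occupancy[daughter] = CellKind.TUMOR
    return daughter
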