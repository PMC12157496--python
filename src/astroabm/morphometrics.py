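"""Spatial morphometrics of the simulated tumor.

Three summary statistics characterize tumor shape at each timestep:

* **fractal dimension** — box-counting slope of the tumor front, measuring
  boundary complexity (1 for a smooth line, 2 for a filled region);
* **lacunarity** — variance-to-squared-mean ratio of front-cell counts in
  non-overlapping windows, measuring spatial gappiness;
* **eccentricity** — ``1 - lambda2/lambda1`` of the bulk-tumor coordinate
  covariance eigenvalues (0 = round, 1 = collinear).

The tumor front is the set of tumor cells with at least one EMPTY site in
their 3x3 Moore neighborhood; fractal dimension and lacunarity are computed
on the front, eccentricity on the whole tumor mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .lattice import CellKind

__all__ = [
    "MorphologyMetrics",
    "tumor_front",
    "box_counts",
    "fractal_dimension",
    "lacunarity",
    "lacunarity_per_scale",
    "eccentricity",
    "eccentricity_from_coords",
    "residualize",
    "compute_metrics",
    "default_scales",
]

_MOORE_KERNEL = np.ones((3, 3), dtype=float)


@dataclass
class MorphologyMetrics:
    """Per-timestep tumor morphology summary."""

    step: int
    tumor_count: int
    fractal_dimension: float  # NaN when undefined (tiny/empty mask)
    lacunarity: float
    eccentricity: float


def tumor_front(occupancy: np.ndarray) -> np.ndarray:
    """Boolean mask of tumor cells adjacent to >= 1 EMPTY Moore neighbor.

    Off-grid sites are not empty (edge truncation), and tumor cells fully
    enclosed by agents of any kind are interior, not front.
    """
    tumor = occupancy == CellKind.TUMOR
    empty = (occupancy == CellKind.EMPTY).astype(float)
    empty_neighbors = ndimage.convolve(empty, _MOORE_KERNEL, mode="constant", cval=0.0)
    # the center term never contributes for tumor cells (site is occupied)
    return tumor & (empty_neighbors > 0.5)


def _crop_to_bbox(mask: np.ndarray) -> np.ndarray:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return mask[rows[0]: rows[-1] + 1, cols[0]: cols[-1] + 1]


def default_scales(side: int, minimum: int = 2) -> list[int]:
    """Powers of two from ``minimum`` up to half the bounding-box side."""
    scales = []
    s = minimum
    while s <= max(side // 2, minimum):
        if s <= side:
            scales.append(s)
        s *= 2
    return scales


def box_counts(mask: np.ndarray, sizes: Sequence[int]) -> np.ndarray:
    """Occupied-box counts N(eps) over non-overlapping grids.

    Boxes are anchored at the mask's bounding-box origin; partial boxes at
    the far edges count if they contain any occupied site.
    """
    mask = _crop_to_bbox(np.asarray(mask, dtype=bool))
    counts = []
    for eps in sizes:
        nx = -(-mask.shape[0] // eps)
        ny = -(-mask.shape[1] // eps)
        padded = np.zeros((nx * eps, ny * eps), dtype=bool)
        padded[: mask.shape[0], : mask.shape[1]] = mask
        blocks = padded.reshape(nx, eps, ny, eps).any(axis=(1, 3))
        counts.append(int(blocks.sum()))
    return np.asarray(counts)


def fractal_dimension(
    mask: np.ndarray, sizes: Optional[Sequence[int]] = None
) -> float:
    """Box-counting fractal dimension of a binary mask.

    The slope of ``log N(eps)`` against ``log eps`` is estimated by least
    squares; the dimension is its negative.  Returns NaN for an empty mask
    or when fewer than 3 scales fit the bounding box (undefined metric,
    reported as missing rather than zero).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return float("nan")
    cropped = _crop_to_bbox(mask)
    if sizes is None:
        sizes = default_scales(max(cropped.shape))
    sizes = [s for s in sizes if s >= 1]
    if len(sizes) < 3:
        return float("nan")
    counts = box_counts(cropped, sizes)
    slope = np.polyfit(np.log(np.asarray(sizes, float)), np.log(counts), 1)[0]
    return float(-slope)


def lacunarity_per_scale(
    mask: np.ndarray, sizes: Optional[Sequence[int]] = None
) -> dict[int, float]:
    """Lacunarity ``sigma^2 / mu^2`` of window masses, per window size.

    The region analyzed is the mask exactly as passed (callers wanting
    position independence crop to the bounding box first); it is partitioned
    into non-overlapping ``eps x eps`` windows, partial edge windows
    included, and the occupied-site count per window forms the mass
    distribution.  A fully occupied region has zero variance and hence zero
    lacunarity under this definition.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return {}
    if sizes is None:
        sizes = default_scales(max(mask.shape))
    out: dict[int, float] = {}
    for eps in sizes:
        if eps < 1 or eps > max(mask.shape):
            continue
        nx = -(-mask.shape[0] // eps)
        ny = -(-mask.shape[1] // eps)
        padded = np.zeros((nx * eps, ny * eps), dtype=float)
        padded[: mask.shape[0], : mask.shape[1]] = mask
        masses = padded.reshape(nx, eps, ny, eps).sum(axis=(1, 3)).ravel()
        mu = masses.mean()
        if mu == 0:
            continue
        out[int(eps)] = float(masses.var() / mu**2)
    return out


def lacunarity(mask: np.ndarray, sizes: Optional[Sequence[int]] = None) -> float:
    """Mean of the per-scale lacunarity over the configured window sizes.

    NaN for an all-zero mask (undefined, reported missing).
    """
    per_scale = lacunarity_per_scale(mask, sizes)
    if not per_scale:
        return float("nan")
    return float(np.mean(list(per_scale.values())))


def eccentricity_from_coords(coords: np.ndarray) -> float:
    """Eccentricity ``1 - lambda2/lambda1`` of a coordinate cloud.

    Uses the population (1/N) covariance; the eigenvalue ratio is
    normalization-invariant.  Degenerate clouds (a single point, or all
    points coincident) return 0 by contract.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 2:
        return 0.0
    cov = np.cov(coords.T, bias=True)
    eig = np.sort(np.linalg.eigvalsh(cov))
    lam2, lam1 = float(eig[0]), float(eig[1])
    if lam1 <= 0:
        return 0.0
    return 1.0 - max(lam2, 0.0) / lam1


def eccentricity(tumor_mask: np.ndarray) -> float:
    """Eccentricity of the full (bulk) tumor mask."""
    coords = np.argwhere(np.asarray(tumor_mask, dtype=bool))
    return eccentricity_from_coords(coords)


def residualize(metric: np.ndarray, tumor_count: np.ndarray) -> np.ndarray:
    """Residualize a metric on tumor count, per time step across replicates.

    ``metric`` and ``tumor_count`` are (n_replicates, n_steps) arrays; for
    each step an ordinary least-squares fit of metric on count is removed.
    Requires >= 3 replicates.
    """
    metric = np.asarray(metric, dtype=float)
    count = np.asarray(tumor_count, dtype=float)
    if metric.shape != count.shape:
        raise ValueError("metric and tumor_count must have matching shapes")
    if metric.shape[0] < 3:
        raise ValueError("residualization requires at least 3 replicates")
    out = np.empty_like(metric)
    for j in range(metric.shape[1]):
        x, y = count[:, j], metric[:, j]
        if np.ptp(x) == 0:
            out[:, j] = y - y.mean()
            continue
        coef = np.polyfit(x, y, 1)
        out[:, j] = y - np.polyval(coef, x)
    return out


def compute_metrics(occupancy: np.ndarray, step: int = 0) -> MorphologyMetrics:
    """All three morphology statistics for one occupancy grid.

    Fractal dimension and lacunarity use the bounding-box-cropped tumor
    front (position-independent); eccentricity uses the bulk tumor mask.
    """
    tumor_mask = occupancy == CellKind.TUMOR
    n = int(tumor_mask.sum())
    front = tumor_front(occupancy)
    if front.any():
        front_cropped = _crop_to_bbox(front)
        df = fractal_dimension(front_cropped)
        lac = lacunarity(front_cropped)
    else:
        df, lac = float("nan"), float("nan")
    ecc = eccentricity(tumor_mask) if n else float("nan")
    return MorphologyMetrics(
        step=step,
        tumor_count=n,
        fractal_dimension=df,
        lacunarity=lac,
        eccentricity=ecc,
    )
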