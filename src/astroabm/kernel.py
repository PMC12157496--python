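"""Distance-decayed influence kernel over the 7x7 neighborhood.

Both the astrocyte switch and the tumor division modulation weigh every agent
in a 7x7 square neighborhood (a 3-cell radius, 48 non-center sites) by a
sigmoidal function of its Euclidean lattice distance::

    w(d) = 1 / (1 + exp(S * (d - d_half)))

with steepness ``S = 3`` and half-maximal distance ``d_half = 1.5`` in the
baseline model, so a neighbor 1.5 sites away contributes exactly half of the
per-agent magnitude.  The kernel is precomputed once; per-agent magnitudes
(kappa, alpha, beta) multiply the weights at accumulation time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Neighborhood radius in lattice sites (7x7 square = radius 3).
NEIGHBORHOOD_RADIUS = 3


def influence_weight(
    distance: float | np.ndarray,
    magnitude: float = 1.0,
    steepness: float = 3.0,
    half_distance: float = 1.5,
) -> float | np.ndarray:
    """Sigmoidal distance decay of per-agent influence.

    Returns ``magnitude / (1 + exp(steepness * (distance - half_distance)))``;
    strictly positive and strictly decreasing in ``distance``, equal to
    ``magnitude / 2`` at the half-maximal distance.
    """
    distance = np.asarray(distance, dtype=float)
    out = magnitude / (1.0 + np.exp(steepness * (distance - half_distance)))
    return float(out) if out.ndim == 0 else out


@dataclass
class InfluenceKernel:
    """Precomputed weights of the 7x7 influence neighborhood.

    Attributes
    ----------
    offsets : (48, 2) int array
        Non-center displacement vectors of the neighborhood.
    weights : (48,) float array
        Unit-magnitude sigmoidal decay per offset.
    i_max : float
        Sum of all weights — the theoretical maximum cumulative influence
        for a per-agent magnitude of 1 (about 7.23 for S=3, d_half=1.5).
    grid : (7, 7) float array
        The same weights arranged for 2-D convolution, zero at the center.
    """

    steepness: float = 3.0
    half_distance: float = 1.5
    radius: int = NEIGHBORHOOD_RADIUS
    offsets: np.ndarray = field(init=False, repr=False)
    weights: np.ndarray = field(init=False, repr=False)
    grid: np.ndarray = field(init=False, repr=False)
    i_max: float = field(init=False)

    def __post_init__(self) -> None:
        r = self.radius
        dx, dy = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1), indexing="ij")
        center = (dx == 0) & (dy == 0)
        dist = np.hypot(dx, dy)
        grid = influence_weight(dist, 1.0, self.steepness, self.half_distance)
        grid = np.where(center, 0.0, grid)
        self.grid = grid
        self.offsets = np.stack([dx[~center], dy[~center]], axis=1)
        self.weights = grid[~center]
        self.i_max = float(self.weights.sum())

    def weight_at(self, offset: tuple[int, int]) -> float:
        """Weight of a single displacement vector (0 at the center)."""
        r = self.radius
        ox, oy = offset
        if abs(ox) > r or abs(oy) > r:
            return 0.0
        return float(self.grid[ox + r, oy + r])
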