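"""Initial astrocyte placement patterns and neutral-agent filling.

Six spatial layouts are supported, spanning biologically motivated
arrangements (random parenchyma, inverse-radial peritumoral enrichment,
gray/white-matter gradient) and theoretical controls (uniform lattice,
clustered aggregates, radial core enrichment).  Every layout places the
exact requested astrocyte count, never on the reserved central tumor site;
the remaining non-tumor compartment is topped up with inert neutral agents
so that total occupancy is identical across densities and layouts.
"""

from __future__ import annotations

import math

import numpy as np

from .config import ConfigurationError, LayoutParams

_EPS = 0.01  # floor weight so every free site stays reachable


def _site_grid(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    x, y = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    return x, y


def _weighted_sample_without_replacement(
    weights: np.ndarray, count: int, rng: np.random.Generator
) -> np.ndarray:
    """Efraimidis–Spirakis reservoir keys: top-`count` of u**(1/w)."""
    u = rng.random(weights.shape[0])
    keys = np.where(weights > 0, u ** (1.0 / np.maximum(weights, 1e-12)), -1.0)
    idx = np.argpartition(keys, -count)[-count:]
    return idx


def place_astrocytes(
    kind: str,
    count: int,
    shape: tuple[int, int],
    rng: np.random.Generator,
    params: LayoutParams | None = None,
    reserved: tuple[int, int] | None = None,
) -> np.ndarray:
    """Return ``count`` distinct lattice sites for astrocytes.

    Parameters
    ----------
    kind : one of uniform, random, clustered, radial, inverse_radial, gradient
    count : number of astrocytes to place
    shape : (width, height) of the lattice
    rng : seeded generator (layouts are deterministic given the rng state)
    params : clustered/gradient free parameters
    reserved : site that must stay free (the initial tumor cell)
    """
    if params is None:
        params = LayoutParams()
    w, h = shape
    n_sites = w * h
    if count < 0 or count > n_sites - 1:
        raise ConfigurationError(f"cannot place {count} astrocytes on {w}x{h} grid")
    if count == 0:
        return np.empty((0, 2), dtype=int)

    reserved_flat = -1
    if reserved is not None:
        reserved_flat = reserved[0] * h + reserved[1]

    if kind == "uniform":
        flat = _uniform_sites(count, shape, rng, reserved_flat)
    elif kind == "random":
        flat = _weighted_sites(np.ones(n_sites), count, rng, reserved_flat)
    elif kind == "clustered":
        flat = _clustered_sites(count, shape, rng, params, reserved_flat)
    elif kind in ("radial", "inverse_radial"):
        x, y = _site_grid(shape)
        cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
        r = np.hypot(x - cx, y - cy)
        r_norm = (r / r.max()).ravel()
        weights = (1.0 - r_norm if kind == "radial" else r_norm) + _EPS
        flat = _weighted_sites(weights, count, rng, reserved_flat)
    elif kind == "gradient":
        x, y = _site_grid(shape)
        coord = x if params.gradient_axis == "x" else y
        extent = max(coord.max(), 1)
        weights = (coord / extent).ravel() + _EPS
        flat = _weighted_sites(weights, count, rng, reserved_flat)
    else:
        raise ConfigurationError(f"unknown layout kind {kind!r}")

    sites = np.column_stack(np.unravel_index(flat, shape))
    return sites


def _weighted_sites(
    weights: np.ndarray, count: int, rng: np.random.Generator, reserved_flat: int
) -> np.ndarray:
    weights = weights.astype(float).copy()
    if reserved_flat >= 0:
        weights[reserved_flat] = 0.0
    if np.count_nonzero(weights) < count:
        raise ConfigurationError("not enough admissible sites for layout")
    return _weighted_sample_without_replacement(weights, count, rng)


def _uniform_sites(
    count: int, shape: tuple[int, int], rng: np.random.Generator, reserved_flat: int
) -> np.ndarray:
    """Evenly spaced lattice, trimmed or topped up to the exact count."""
    w, h = shape
    spacing = math.sqrt(w * h / count)
    xs = np.round((np.arange(math.ceil(w / spacing)) + 0.5) * spacing - 0.5).astype(int)
    ys = np.round((np.arange(math.ceil(h / spacing)) + 0.5) * spacing - 0.5).astype(int)
    xs = np.unique(np.clip(xs, 0, w - 1))
    ys = np.unique(np.clip(ys, 0, h - 1))
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    flat = np.unique(gx.ravel() * h + gy.ravel())
    flat = flat[flat != reserved_flat]
    if flat.size > count:
        # trim with an even stride to preserve regular spacing
        keep = np.round(np.linspace(0, flat.size - 1, count)).astype(int)
        flat = flat[keep]
    elif flat.size < count:
        free = np.ones(w * h, dtype=bool)
        free[flat] = False
        if reserved_flat >= 0:
            free[reserved_flat] = False
        candidates = np.flatnonzero(free)
        extra = rng.choice(candidates, size=count - flat.size, replace=False)
        flat = np.concatenate([flat, extra])
    return flat


def _clustered_sites(
    count: int,
    shape: tuple[int, int],
    rng: np.random.Generator,
    params: LayoutParams,
    reserved_flat: int,
) -> np.ndarray:
    """Gaussian aggregates around uniformly placed cluster seeds."""
    w, h = shape
    seeds = np.column_stack(
        [rng.integers(0, w, params.n_clusters), rng.integers(0, h, params.n_clusters)]
    )
    taken: set[int] = set()
    if reserved_flat >= 0:
        taken.add(reserved_flat)
    out: list[int] = []
    max_draws = 200 * count
    draws = 0
    while len(out) < count and draws < max_draws:
        n = count - len(out)
        which = rng.integers(0, params.n_clusters, n)
        pos = seeds[which] + rng.normal(0.0, params.cluster_spread, (n, 2))
        pos = np.round(pos).astype(int)
        draws += n
        ok = (pos[:, 0] >= 0) & (pos[:, 0] < w) & (pos[:, 1] >= 0) & (pos[:, 1] < h)
        for fx in pos[ok, 0] * h + pos[ok, 1]:
            fi = int(fx)
            if fi not in taken:
                taken.add(fi)
                out.append(fi)
                if len(out) == count:
                    break
    if len(out) < count:
        # top-up from remaining free sites so the exact count is honored
        free = np.ones(w * h, dtype=bool)
        free[list(taken)] = False
        candidates = np.flatnonzero(free)
        if candidates.size < count - len(out):
            raise ConfigurationError("clustered layout cannot place requested count")
        extra = rng.choice(candidates, size=count - len(out), replace=False)
        out.extend(int(e) for e in extra)
    return np.asarray(out, dtype=int)


def fill_neutral(
    occupancy: np.ndarray, neutral_count: int, rng: np.random.Generator
) -> np.ndarray:
    """Choose sites for the inert neutral filler agents.

    Neutral agents occupy uniformly random free sites; they do not interact
    with tumor cells, never switch state, and are unaffected by drug — they
    exist only to hold total non-tumor occupancy constant across densities.
    """
    free = np.flatnonzero(occupancy.ravel() == 0)
    if neutral_count > free.size:
        raise ConfigurationError("not enough free sites for neutral agents")
    if neutral_count == 0:
        return np.empty((0, 2), dtype=int)
    chosen = rng.choice(free, size=neutral_count, replace=False)
    return np.column_stack(np.unravel_index(chosen, occupancy.shape))
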