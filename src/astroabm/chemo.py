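"""Chemotherapy: drug field dynamics, chemoprotection, kill curve, schedule.

The drug concentration obeys a reaction–diffusion equation: diffusion is
advanced with a Peaceman–Rachford alternating-direction-implicit (ADI) step;
decay and tumor uptake follow the discrete update ``C <- C * lambda`` with a
further fractional loss on tumor-occupied sites.  During dosing the grid
boundary is clamped at the infusion concentration (Dirichlet); between doses
the boundary is zero-flux (Neumann) and outflowed drug never re-enters.

Gap-junction chemoprotection reduces the concentration a tumor cell senses
by a factor ``1 - Gf * Npro/8`` where ``Npro`` counts pro-metastatic
astrocytes among its 8 Moore neighbors; the per-step kill probability is a
sigmoid of this effective concentration.  Astrocytes and neutral agents are
never affected by drug.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.linalg import solve_banded

from .config import ChemoParams
from .lattice import CellKind, LatticeState

__all__ = [
    "diffuse",
    "decay_and_uptake",
    "pro_moore_counts",
    "effective_concentration",
    "death_probability",
    "is_dosing",
    "update_treatment_state",
    "death_probability_field",
]

_MOORE_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=float)


def _banded(diag: np.ndarray, off: float, n: int) -> np.ndarray:
    ab = np.zeros((3, n))
    ab[0, 1:] = off
    ab[1, :] = diag
    ab[2, :-1] = off
    return ab


def _implicit_solve(rhs: np.ndarray, r: float, neumann: bool) -> np.ndarray:
    """Solve (I - r*delta) x = rhs along axis 0, batched over axis 1.

    The Neumann operator uses a copied ghost cell (first-order zero-flux),
    which makes the discrete Laplacian exactly conservative: column sums of
    delta vanish, so total mass is preserved to solver precision.
    """
    n = rhs.shape[0]
    diag = np.full(n, 1.0 + 2.0 * r)
    if neumann:
        diag[0] = diag[-1] = 1.0 + r
    ab = _banded(diag, -r, n)
    return solve_banded((1, 1), ab, rhs, overwrite_ab=True)


def _explicit_delta(c: np.ndarray, axis: int, neumann: bool, cb: float) -> np.ndarray:
    """Second difference along ``axis`` with the configured boundary."""
    c = np.moveaxis(c, axis, 0)
    if neumann:
        top = np.concatenate([c[:1], c[:-1]], axis=0)
        bot = np.concatenate([c[1:], c[-1:]], axis=0)
    else:
        pad = np.full_like(c[:1], cb)
        top = np.concatenate([pad, c[:-1]], axis=0)
        bot = np.concatenate([c[1:], pad], axis=0)
    return np.moveaxis(top + bot - 2.0 * c, 0, axis)


def diffuse(
    field: np.ndarray,
    diffusion: float,
    dosing: bool,
    boundary_conc: float = 0.0,
    dt: float = 1.0,
) -> np.ndarray:
    """One ADI (Peaceman–Rachford) diffusion step.

    While dosing, the boundary ring is held at ``boundary_conc`` (Dirichlet
    drug influx); otherwise zero-flux boundaries apply and mass is conserved
    exactly.  Returns a new non-negative field.
    """
    if not np.all(np.isfinite(field)):
        raise FloatingPointError("non-finite drug concentration")
    c = field.astype(float, copy=True)
    neumann = not dosing
    cb = boundary_conc
    if dosing:
        c[0, :] = c[-1, :] = cb
        c[:, 0] = c[:, -1] = cb
    r = 0.5 * diffusion * dt  # half-step diffusion number (dx = 1)

    if neumann:
        # x-implicit, y-explicit
        rhs = c + r * _explicit_delta(c, axis=1, neumann=True, cb=cb)
        c = _implicit_solve(rhs, r, neumann=True)
        # y-implicit, x-explicit
        rhs = c + r * _explicit_delta(c, axis=0, neumann=True, cb=cb)
        c = _implicit_solve(rhs.T, r, neumann=True).T
    else:
        interior = c[1:-1, 1:-1]
        # x-implicit half step on the interior, Dirichlet ring fixed at cb
        rhs = interior + r * _explicit_delta(c, axis=1, neumann=False, cb=cb)[1:-1, 1:-1]
        rhs[0, :] += r * cb
        rhs[-1, :] += r * cb
        interior = _implicit_solve(rhs, r, neumann=False)
        c[1:-1, 1:-1] = interior
        # y-implicit half step
        rhs = interior + r * _explicit_delta(c, axis=0, neumann=False, cb=cb)[1:-1, 1:-1]
        rhs[:, 0] += r * cb
        rhs[:, -1] += r * cb
        interior = _implicit_solve(rhs.T, r, neumann=False).T
        c[1:-1, 1:-1] = interior
        c[0, :] = c[-1, :] = cb
        c[:, 0] = c[:, -1] = cb
    return np.maximum(c, 0.0)


def decay_and_uptake(
    field: np.ndarray,
    occupancy: np.ndarray,
    retention: float,
    uptake_fraction: float,
) -> np.ndarray:
    """Per-step decay then tumor uptake: ``C <- C*lambda``, minus the
    fraction absorbed on tumor-occupied sites (applied to the post-decay
    value).  Result clamped non-negative."""
    c = field * retention
    tumor = occupancy == CellKind.TUMOR
    c[tumor] *= 1.0 - uptake_fraction
    return np.maximum(c, 0.0)


def pro_moore_counts(occupancy: np.ndarray) -> np.ndarray:
    """Count of pro-metastatic astrocytes among the 8 Moore neighbors."""
    pro = (occupancy == CellKind.ASTRO_PRO).astype(float)
    return ndimage.convolve(pro, _MOORE_KERNEL, mode="constant", cval=0.0)


def effective_concentration(
    concentration: float | np.ndarray,
    n_pro: float | np.ndarray,
    gap_junction_factor: float,
) -> float | np.ndarray:
    """Gap-junction-modulated concentration ``C * (1 - Gf * Npro/8)``.

    With all 8 Moore neighbors pro-metastatic and ``Gf = 1`` the blockade is
    complete and the cell senses no drug at all.
    """
    out = np.asarray(concentration, dtype=float) * (
        1.0 - gap_junction_factor * np.asarray(n_pro, dtype=float) / 8.0
    )
    return float(out) if out.ndim == 0 else out


def death_probability(
    c_eff: float | np.ndarray, steepness: float, half_conc: float
) -> float | np.ndarray:
    """Per-step kill probability ``1 / (1 + exp(-k * (C_eff - T)))``."""
    c_eff = np.asarray(c_eff, dtype=float)
    out = 1.0 / (1.0 + np.exp(-steepness * (c_eff - half_conc)))
    return float(out) if out.ndim == 0 else out


def death_probability_field(
    drug: np.ndarray, occupancy: np.ndarray, params: ChemoParams
) -> np.ndarray:
    """Kill probability at every site for the current drug/occupancy."""
    c_eff = effective_concentration(
        drug, pro_moore_counts(occupancy), params.gap_junction_factor
    )
    return death_probability(c_eff, params.kill_steepness, params.kill_half_conc)


def is_dosing(steps_since_start: int, params: ChemoParams) -> bool:
    """Dosing flag within the repeating on/off cycle (14 on / 7 off)."""
    return steps_since_start % params.cycle_length < params.steps_on


def update_treatment_state(state: LatticeState, params: ChemoParams | None) -> bool:
    """Activate treatment when the tumor first reaches the threshold.

    Returns the dosing flag for the current step; always ``False`` for
    untreated runs (``params`` absent).  Once active, treatment cycles
    forever; astrocytes and neutral agents are never affected.
    """
    if params is None:
        return False
    if not state.treatment_active and state.tumor_count >= params.start_threshold:
        state.treatment_active = True
        state.treatment_start_step = state.timestep
    if not state.treatment_active:
        return False
    return is_dosing(state.timestep - state.treatment_start_step, params)
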