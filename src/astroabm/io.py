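"""Run artifacts: grid exports, metric tables, manifests, renders."""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .lattice import CellKind, LatticeState


def save_grid(occupancy: np.ndarray, path: str | Path) -> None:
    """Write the integer-coded occupancy grid as plain text."""
    np.savetxt(path, occupancy.astype(int), fmt="%d")


def load_grid(path: str | Path) -> np.ndarray:
    """Read an integer-coded occupancy grid written by :func:`save_grid`."""
    grid = np.loadtxt(path, dtype=int)
    if grid.ndim == 1:
        grid = grid[None, :]
    if not np.isin(grid, [int(k) for k in CellKind]).all():
        raise ValueError("grid contains codes outside the agent alphabet")
    return grid.astype(np.int8)


def save_drug_field(drug: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, drug, fmt="%.6g")


def save_metrics(metrics: pd.DataFrame, path: str | Path) -> None:
    metrics.to_csv(path, index=False)


def write_manifest(
    config: SimulationConfig, state: LatticeState, path: str | Path
) -> None:
    """Record config, seed and environment versions for exact replay."""
    import astroabm

    manifest = {
        "config": config.to_dict(),
        "final_timestep": state.timestep,
        "final_tumor_count": state.tumor_count,
        "treatment_start_step": state.treatment_start_step,
        "versions": {
            "astroabm": astroabm.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2))


def render_grid(occupancy: np.ndarray, path: str | Path) -> None:
    """Optional PNG render of the occupancy grid (diagnostic only)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    cmap = ListedColormap(["white", "cyan", "indigo", "gold", "lightgray"])
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(occupancy.T, cmap=cmap, vmin=0, vmax=4, origin="lower")
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
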