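"""Sensitivity harness and the five in-silico experiments.

Parameter sets are drawn from a Sobol low-discrepancy sequence over the six
interaction parameters (four continuous on [0, 1], two discrete
sensitivities), each run for several stochastic replicates; parameter
influence on the outputs (final tumor count and the three morphology
metrics) is summarized with partial rank correlation coefficients (PRCC),
and parameter sets are stratified into Inhibitory / Neutral / Promoting
regimes by tertiles of mean final tumor count.

At full scale the designs match the study conditions (n=1000 samples x 10
replicates on the 300x300 grid); the default "ci" scale is a faithful
scaled-down version (n=64 x 3 on 100x100) suitable for a workstation.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from .config import (
    DIVISION_SENSITIVITY_LEVELS,
    SWITCH_SENSITIVITY_LEVELS,
    AstrocyteParams,
    ChemoParams,
    SimulationConfig,
    TumorParams,
)
from .simulate import run_simulation

__all__ = [
    "PARAMETER_COLUMNS",
    "sobol_sample",
    "prcc",
    "stratify_regimes",
    "replicate_seed",
    "run_parameter_set",
    "run_experiment",
    "scaled_chemo_params",
    "EXPERIMENT_NAMES",
]

#: Sweep dimensions, in sample-matrix column order.
PARAMETER_COLUMNS = [
    "effect_anti_met",        # alpha, continuous [0, 1]
    "effect_pro_met",         # beta, continuous [0, 1]
    "conversion_threshold",   # theta, continuous [0, 1]
    "effect_per_tumor_cell",  # kappa, continuous [0, 1]
    "switch_sensitivity",     # S_A, discrete {8, 16, 32}
    "division_sensitivity",   # S_T, discrete {4, 8, 16}
]

EXPERIMENT_NAMES = (
    "switching_comparison",
    "global_sensitivity",
    "density_sweep",
    "layout_sweep",
    "chemo_comparison",
)

DENSITY_SWEEP_LEVELS = (0.0, 0.125, 0.25, 0.375, 0.5)
LAYOUT_SWEEP_KINDS = (
    "uniform", "random", "clustered", "radial", "inverse_radial", "gradient",
)
LAYOUT_SWEEP_DENSITY = 0.3
OUTPUT_COLUMNS = ["tumor_count", "fractal_dimension", "lacunarity", "eccentricity"]


def _map_discrete(u: np.ndarray, levels: Sequence[int]) -> np.ndarray:
    """Equal-probability binning of a unit coordinate onto discrete levels."""
    idx = np.minimum((u * len(levels)).astype(int), len(levels) - 1)
    return np.asarray(levels)[idx]


def sobol_sample(n: int, seed: int = 0) -> pd.DataFrame:
    """Draw ``n`` parameter sets from a scrambled Sobol sequence.

    Continuous dimensions span [0, 1] (the plausible-range bounds of the
    interaction magnitudes and threshold); the two sensitivities are mapped
    by equal-probability binning onto their discrete levels.  Identical
    seed gives an identical sample.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    sampler = qmc.Sobol(d=6, scramble=True, rng=np.random.default_rng(seed))
    with warnings.catch_warnings():
        # non-power-of-two n trades Sobol balance for design flexibility
        warnings.simplefilter("ignore", UserWarning)
        u = sampler.random(n)
    df = pd.DataFrame(
        {
            "effect_anti_met": u[:, 0],
            "effect_pro_met": u[:, 1],
            "conversion_threshold": u[:, 2],
            "effect_per_tumor_cell": u[:, 3],
            "switch_sensitivity": _map_discrete(u[:, 4], SWITCH_SENSITIVITY_LEVELS),
            "division_sensitivity": _map_discrete(u[:, 5], DIVISION_SENSITIVITY_LEVELS),
        }
    )
    df.index.name = "sample"
    return df


def prcc(samples: pd.DataFrame | np.ndarray, output: np.ndarray) -> pd.Series:
    """Partial rank correlation coefficient of each parameter with an output.

    All columns are rank-transformed; for each parameter the residuals of
    its ranks regressed on the other parameters' ranks are correlated with
    the residuals of the output ranks regressed on the same covariates.
    A constant column yields NaN (undefined).
    """
    if isinstance(samples, pd.DataFrame):
        names = list(samples.columns)
        x = samples.to_numpy(dtype=float)
    else:
        x = np.asarray(samples, dtype=float)
        names = [f"x{i}" for i in range(x.shape[1])]
    y = np.asarray(output, dtype=float)
    n, p = x.shape
    if n < p + 2:
        raise ValueError("need at least p+2 samples for PRCC")
    rx = np.column_stack([stats.rankdata(x[:, j]) for j in range(p)])
    ry = stats.rankdata(y)
    out = {}
    for j in range(p):
        if np.ptp(rx[:, j]) == 0:
            out[names[j]] = float("nan")
            continue
        others = np.column_stack(
            [np.ones(n), np.delete(rx, j, axis=1)]
        )
        bx, *_ = np.linalg.lstsq(others, rx[:, j], rcond=None)
        by, *_ = np.linalg.lstsq(others, ry, rcond=None)
        res_x = rx[:, j] - others @ bx
        res_y = ry - others @ by
        denom = np.sqrt((res_x**2).sum() * (res_y**2).sum())
        out[names[j]] = float((res_x * res_y).sum() / denom) if denom > 0 else float("nan")
    return pd.Series(out, name="prcc")


def stratify_regimes(mean_tumor_counts: np.ndarray) -> np.ndarray:
    """Tertile regime labels by mean final tumor count.

    The lower, middle and upper tertiles (sizes equal to within one) are
    labeled Inhibitory, Neutral and Promoting; ties break by stable sample
    index order.  Labels computed under one condition are meant to be
    reused unchanged when the same parameter sets are re-run under other
    densities or layouts.
    """
    counts = np.asarray(mean_tumor_counts, dtype=float)
    if counts.size < 3:
        raise ValueError("need at least 3 samples to stratify")
    order = np.argsort(counts, kind="stable")
    labels = np.empty(counts.size, dtype=object)
    thirds = np.array_split(order, 3)
    for name, idx in zip(("Inhibitory", "Neutral", "Promoting"), thirds):
        labels[idx] = name
    return labels


def replicate_seed(master_seed: int, sample_index: int, replicate_index: int) -> int:
    """Independent, replayable seed for one (sample, replicate) cell."""
    ss = np.random.SeedSequence(
        entropy=master_seed, spawn_key=(sample_index, replicate_index)
    )
    return int(ss.generate_state(1)[0] % (2**31))


def _config_for_sample(
    row: dict, base: SimulationConfig, seed: int
) -> SimulationConfig:
    astro = AstrocyteParams(
        effect_per_tumor_cell=float(row["effect_per_tumor_cell"]),
        switch_sensitivity=int(row["switch_sensitivity"]),
        conversion_threshold=float(row["conversion_threshold"]),
    )
    tum = TumorParams(
        effect_anti_met=float(row["effect_anti_met"]),
        effect_pro_met=float(row["effect_pro_met"]),
        division_sensitivity=int(row["division_sensitivity"]),
    )
    return dataclasses.replace(base, astro_params=astro, tumor_params=tum, seed=seed)


def run_parameter_set(
    row: dict,
    base: SimulationConfig,
    n_replicates: int,
    master_seed: int,
    sample_index: int = 0,
) -> pd.DataFrame:
    """Run one parameter set for several replicates; final-step outputs."""
    recs = []
    for rep in range(n_replicates):
        seed = replicate_seed(master_seed, sample_index, rep)
        cfg = _config_for_sample(row, base, seed)
        _, metrics = run_simulation(cfg)
        final = metrics.iloc[-1]
        recs.append(
            {
                "sample": sample_index,
                "replicate": rep,
                "seed": seed,
                **{k: final[k] for k in OUTPUT_COLUMNS},
            }
        )
    return pd.DataFrame(recs)


def _scale_base(scale: str, seed: int) -> tuple[SimulationConfig, int, int]:
    """Base config, sample count and replicate count for a named scale."""
    if scale == "full":
        base = SimulationConfig(seed=seed)
        return base, 1000, 10
    if scale == "ci":
        base = SimulationConfig(
            grid_width=100, grid_height=100, n_steps=60, seed=seed
        )
        return base, 64, 3
    raise ValueError("scale must be 'ci' or 'full'")


def run_experiment(
    name: str,
    *,
    scale: str = "ci",
    seed: int = 0,
    base_config: Optional[SimulationConfig] = None,
    n_samples: Optional[int] = None,
    n_replicates: Optional[int] = None,
    densities: Optional[Iterable[float]] = None,
    layouts: Optional[Iterable[str]] = None,
    gf_levels: Iterable[float] = (0.0, 0.5, 1.0),
) -> dict[str, pd.DataFrame]:
    """Run one of the five named experiments and return its result tables.

    Every experiment returns a dict with a ``replicates`` table (one row
    per run, final-step outputs) and experiment-specific tables:
    ``summary`` group statistics and, for the sensitivity design,
    ``samples``, ``prcc`` and ``regimes``.
    """
    if name not in EXPERIMENT_NAMES:
        raise ValueError(f"unknown experiment {name!r}; choose from {EXPERIMENT_NAMES}")
    default_base, ns, nr = _scale_base(scale, seed)
    base = base_config if base_config is not None else default_base
    n_samples = ns if n_samples is None else n_samples
    n_replicates = nr if n_replicates is None else n_replicates

    if name == "switching_comparison":
        return _switching_comparison(base, n_replicates, seed)
    if name == "global_sensitivity":
        return _global_sensitivity(base, n_samples, n_replicates, seed)
    if name == "density_sweep":
        dens = tuple(densities) if densities is not None else DENSITY_SWEEP_LEVELS
        return _group_sweep(base, n_replicates, seed, "astrocyte_density", dens)
    if name == "layout_sweep":
        lays = tuple(layouts) if layouts is not None else LAYOUT_SWEEP_KINDS
        base = dataclasses.replace(base, astrocyte_density=LAYOUT_SWEEP_DENSITY)
        return _group_sweep(base, n_replicates, seed, "layout", lays)
    return _chemo_comparison(base, n_replicates, seed, tuple(gf_levels))


def _final_rows(
    base: SimulationConfig, n_replicates: int, seed: int, group_key: str, group_val
) -> list[dict]:
    rows = []
    for rep in range(n_replicates):
        rep_seed = replicate_seed(seed, hash(str(group_val)) % 10_000, rep)
        cfg = dataclasses.replace(base, seed=rep_seed)
        _, metrics = run_simulation(cfg)
        final = metrics.iloc[-1]
        rows.append(
            {
                group_key: group_val,
                "replicate": rep,
                "seed": rep_seed,
                **{k: final[k] for k in OUTPUT_COLUMNS},
            }
        )
    return rows


def _switching_comparison(
    base: SimulationConfig, n_replicates: int, seed: int
) -> dict[str, pd.DataFrame]:
    """With vs without astrocyte reprogramming, fixed parameters."""
    rows = []
    for flag in (True, False):
        cfg = dataclasses.replace(base, switching_enabled=flag)
        rows.extend(_final_rows(cfg, n_replicates, seed, "switching", flag))
    reps = pd.DataFrame(rows)
    on = reps.loc[reps["switching"], "tumor_count"]
    off = reps.loc[~reps["switching"], "tumor_count"]
    u, p = stats.mannwhitneyu(on, off, alternative="two-sided")
    summary = reps.groupby("switching")[OUTPUT_COLUMNS].agg(["mean", "std"])
    tests = pd.DataFrame(
        [{"output": "tumor_count", "test": "mannwhitneyu", "statistic": u, "p_value": p}]
    )
    return {"replicates": reps, "summary": summary, "tests": tests}


def _global_sensitivity(
    base: SimulationConfig, n_samples: int, n_replicates: int, seed: int
) -> dict[str, pd.DataFrame]:
    samples = sobol_sample(n_samples, seed)
    reps = pd.concat(
        [
            run_parameter_set(row._asdict() if hasattr(row, "_asdict") else dict(row), base,
                              n_replicates, seed, i)
            for i, (_, row) in enumerate(samples.iterrows())
        ],
        ignore_index=True,
    )
    per_sample = reps.groupby("sample")[OUTPUT_COLUMNS].mean()
    prcc_table = pd.DataFrame(
        {out: prcc(samples, per_sample[out].to_numpy()) for out in OUTPUT_COLUMNS}
    )
    regimes = pd.DataFrame(
        {
            "sample": per_sample.index,
            "mean_tumor_count": per_sample["tumor_count"].to_numpy(),
            "regime": stratify_regimes(per_sample["tumor_count"].to_numpy()),
        }
    )
    return {
        "samples": samples.reset_index(),
        "replicates": reps,
        "per_sample": per_sample.reset_index(),
        "prcc": prcc_table,
        "regimes": regimes,
    }


def _group_sweep(
    base: SimulationConfig,
    n_replicates: int,
    seed: int,
    field_name: str,
    values: Sequence,
) -> dict[str, pd.DataFrame]:
    rows = []
    for val in values:
        cfg = dataclasses.replace(base, **{field_name: val})
        rows.extend(_final_rows(cfg, n_replicates, seed, field_name, val))
    reps = pd.DataFrame(rows)
    summary = reps.groupby(field_name)[OUTPUT_COLUMNS].agg(["mean", "std"])
    groups = [g["tumor_count"].to_numpy() for _, g in reps.groupby(field_name)]
    tests = []
    if len(groups) >= 2 and all(len(g) >= 2 for g in groups):
        h, p = stats.kruskal(*groups)
        tests.append(
            {"output": "tumor_count", "test": "kruskal", "statistic": h, "p_value": p}
        )
    return {"replicates": reps, "summary": summary, "tests": pd.DataFrame(tests)}


def scaled_chemo_params(config: SimulationConfig) -> ChemoParams:
    """Chemotherapy defaults rescaled to the configured grid.

    The stand-in constants are stated for the default 300x300 grid; on a
    smaller lattice the treatment threshold scales with grid area (it marks
    the same fractional tumor burden) and the diffusion coefficient with
    the squared linear size (the same boundary-to-center transit time in
    steps).  Kill curve, retention and schedule are scale-free.
    """
    ref = ChemoParams()
    area_ratio = config.n_sites / (300 * 300)
    lin_ratio = min(config.grid_width, config.grid_height) / 300.0
    return dataclasses.replace(
        ref,
        start_threshold=max(25, int(round(ref.start_threshold * area_ratio))),
        diffusion=max(1.0, ref.diffusion * lin_ratio**2),
    )


def _chemo_comparison(
    base: SimulationConfig, n_replicates: int, seed: int, gf_levels: Sequence[float]
) -> dict[str, pd.DataFrame]:
    """Chemotherapy on, switching on/off, across gap-junction factors."""
    chemo = (
        base.chemo_params
        if base.chemo_params is not None
        else scaled_chemo_params(base)
    )
    rows = []
    for gf in gf_levels:
        cp = dataclasses.replace(chemo, gap_junction_factor=gf)
        for flag in (True, False):
            cfg = dataclasses.replace(
                base, chemo_params=cp, switching_enabled=flag
            )
            for r in _final_rows(cfg, n_replicates, seed, "switching", flag):
                rows.append({"gap_junction_factor": gf, **r})
    reps = pd.DataFrame(rows)
    summary = reps.groupby(["gap_junction_factor", "switching"])[OUTPUT_COLUMNS].agg(
        ["mean", "std"]
    )
    return {"replicates": reps, "summary": summary}
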