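"""Parameter sweeps over (g_r, g_e, n, alpha) with replicate management,
summary statistics and result serialization.

A sweep runs ``replicates`` independent populations for every cell of a
parameter grid and aggregates, per cell, the mean and standard deviation of
the final mean gene value across *surviving* replicates together with the
survival proportion — the quantities plotted in coarse-versus-fine-grain
endpoint figures (point = mean, error bar = SD, point size = survival).
Endpoint gene statistics deliberately exclude extinct replicates; survival
is reported as its own column.

Replicate random streams derive from (master_seed, cell key, replicate
index), where the cell key hashes the cell's own parameter values, so a
sweep is deterministic under a master seed and adding cells to a grid
never changes the results of existing cells.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    GrainParams,
    ParameterError,
    PayoffParams,
    SimConfig,
    cell_key,
    replicate_rng,
)
from .engine import run_replicate

__all__ = ["ExperimentResult", "run_cell", "run_sweep", "summarize", "read_result"]

logger = logging.getLogger(__name__)

#: documented column order of the long-format result table
RESULT_COLUMNS = [
    "model",
    "g_r",
    "g_e",
    "n",
    "alpha",
    "a",
    "b",
    "mu",
    "mean_final_gene",
    "sd_final_gene",
    "survival_proportion",
    "replicates_run",
]

#: grid axes a sweep may vary; anything else is fixed by the base config
SWEEP_AXES = ("g_r", "g_e", "n", "alpha")


@dataclass
class ExperimentResult:
    """Long-format summary table, one row per parameter-grid cell."""

    table: pd.DataFrame

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExperimentResult):
            return NotImplemented
        return self.table.equals(other.table)


def run_cell(
    config: SimConfig,
    grain: GrainParams,
    params: PayoffParams,
) -> dict:
    """Run all replicates of a single parameter combination and summarize.

    Gene statistics are over surviving replicates; a cell with no
    survivors reports NaN gene statistics and survival 0.
    """
    key = cell_key(
        model=config.model, g_r=grain.g_r, g_e=grain.g_e, n=config.n,
        alpha=config.alpha, a=params.a, b=params.b, mu=params.mu,
    )
    finals = []
    survived = 0
    for rep in range(config.replicates):
        rng = replicate_rng(config.master_seed, rep, cell=key)
        summary = run_replicate(config, grain, params, rng=rng, replicate_id=rep)
        if summary.survived:
            survived += 1
            finals.append(summary.final_mean_gene)
    finals_arr = np.asarray(finals)
    return {
        "model": config.model,
        "g_r": grain.g_r,
        "g_e": grain.g_e,
        "n": config.n,
        "alpha": config.alpha,
        "a": params.a,
        "b": params.b,
        "mu": params.mu,
        "mean_final_gene": float(finals_arr.mean()) if survived else float("nan"),
        "sd_final_gene": (
            float(finals_arr.std(ddof=1)) if survived > 1 else float("nan")
        ),
        "survival_proportion": survived / config.replicates,
        "replicates_run": config.replicates,
    }


def run_sweep(
    base_config: SimConfig,
    grid: Mapping[str, Sequence[float]],
    params: PayoffParams,
    base_grain: Optional[GrainParams] = None,
) -> ExperimentResult:
    """Run every cell of a parameter grid.

    ``grid`` maps a subset of ``("g_r", "g_e", "n", "alpha")`` to value
    lists; the cross product defines the cells, and axes not in the grid
    are held at the base config/grain values.
    """
    if not grid:
        raise ParameterError("parameter grid must be non-empty")
    unknown = set(grid) - set(SWEEP_AXES)
    if unknown:
        raise ParameterError(f"unknown sweep axes: {sorted(unknown)}")
    base_grain = base_grain or GrainParams()
    axes = [ax for ax in SWEEP_AXES if ax in grid]
    rows = []
    cells = list(itertools.product(*(grid[ax] for ax in axes)))
    for i, values in enumerate(cells):
        cell = dict(zip(axes, values))
        grain = GrainParams(
            g_r=cell.get("g_r", base_grain.g_r),
            g_e=cell.get("g_e", base_grain.g_e),
        )
        config = SimConfig(
            **{
                **base_config.__dict__,
                "n": int(cell.get("n", base_config.n)),
                "alpha": float(cell.get("alpha", base_config.alpha)),
            }
        )
        logger.info("cell %d/%d: %s", i + 1, len(cells), cell)
        rows.append(run_cell(config, grain, params))
    return ExperimentResult(table=pd.DataFrame(rows, columns=RESULT_COLUMNS))


def summarize(
    result: ExperimentResult,
    csv_path: str | Path,
    metadata: Optional[Mapping] = None,
    plot_path: Optional[str | Path] = None,
) -> Path:
    """Write the result table as CSV with a JSON metadata sidecar.

    Optionally renders an endpoint figure (mean gene ± SD against grain,
    one series per n, point area scaled by survival proportion).
    """
    csv_path = Path(csv_path)
    try:
        result.table.to_csv(csv_path, index=False)
    except OSError as exc:
        raise OSError(f"could not write result CSV to {csv_path}: {exc}") from exc
    try:
        pkg_version = version("bethedge")
    except PackageNotFoundError:
        pkg_version = "unknown"
    sidecar = {"package_version": pkg_version, **(dict(metadata) if metadata else {})}
    csv_path.with_suffix(".meta.json").write_text(json.dumps(sidecar, indent=2))
    if plot_path is not None:
        _plot_endpoints(result.table, Path(plot_path))
    return csv_path


_FLOAT_COLUMNS = [
    "g_r", "g_e", "alpha", "a", "b", "mu",
    "mean_final_gene", "sd_final_gene", "survival_proportion",
]


def read_result(csv_path: str | Path) -> ExperimentResult:
    """Round-trip inverse of :func:`summarize` for the CSV table."""
    table = pd.read_csv(csv_path, float_precision="round_trip")
    table[_FLOAT_COLUMNS] = table[_FLOAT_COLUMNS].astype(float)
    return ExperimentResult(table=table[RESULT_COLUMNS])


def _plot_endpoints(table: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x_axis = "g_e" if table["g_e"].nunique() > 1 else "g_r"
    fig, ax = plt.subplots(figsize=(5, 4))
    for n_val, sub in table.groupby("n"):
        sub = sub.sort_values(x_axis)
        ax.errorbar(
            sub[x_axis], sub["mean_final_gene"], yerr=sub["sd_final_gene"],
            marker="o", capsize=3, label=f"n = {n_val}",
        )
        ax.scatter(
            sub[x_axis], sub["mean_final_gene"],
            s=80 * sub["survival_proportion"], zorder=3,
        )
    ax.set_xlabel(x_axis)
    ax.set_ylabel("mean evolved gene value")
    ax.set_ylim(-0.05, 1.05)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
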