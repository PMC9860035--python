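"""Parameter sweeps over monitoring and punishment efficiencies.

For each (m, p) cell of a grid the sweep computes the analytic degree
constraints, decides feasibility, samples socially optimal networks under
those constraints, scores every sample on the Krackhardt dimensions, and
records the spread of hierarchy scores. Where a cell is infeasible, universal
free-riding is the socially optimal equilibrium and no networks exist.

Graph efficiency E is constant across samples within a cell (it depends only
on N and the minimum in-degree), so the structural story of a sweep is: E
rises as punishment efficiency lowers the required in-degree, and H spreads
across the sampled topologies; the representative network per cell is the
median-H sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import krackhardt
from .equilibrium import degree_constraints
from .netgen import OptimalNetworkSpec, SamplingError, sample_optimal
from .network import InstitutionalNetwork
from .params import GameParams

__all__ = ["SweepCell", "run_sweep", "summarize", "plot_composite_heatmap"]

logger = logging.getLogger(__name__)

_CSV_COLUMNS = [
    "m", "p", "min_in", "max_out", "feasible", "status", "n_samples",
    "H_min", "H_median", "H_max", "E", "composite_median", "representative",
]


@dataclass
class SweepCell:
    """One (m, p) grid cell: constraints, feasibility, and score summaries."""

    m: float
    p: float
    min_in: int
    max_out: int
    feasible: bool
    status: str = "ok"  # "ok" | "infeasible" | "degenerate"
    n_samples: int = 0
    H_min: float | None = None
    H_median: float | None = None
    H_max: float | None = None
    E: float | None = None
    composite_median: float | None = None
    representative: InstitutionalNetwork | None = field(default=None, repr=False)
    representative_path: str | None = None


def _cell_seed(seed: int, index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(seed), int(index)])


def run_sweep(
    params_base: GameParams,
    m_grid: Sequence[float],
    p_grid: Sequence[float],
    n_samples: int = 10_000,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> list[SweepCell]:
    """Evaluate every (m, p) cell; deterministic given ``seed``.

    When ``out_dir`` is given, each feasible cell's median-H representative
    network is written to ``out_dir/cells/m<m>_p<p>.graphml``.
    """
    if not m_grid or not p_grid:
        raise ValueError("m_grid and p_grid must be non-empty")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    cells_dir: Path | None = None
    if out_dir is not None:
        cells_dir = Path(out_dir) / "cells"
        cells_dir.mkdir(parents=True, exist_ok=True)

    cells: list[SweepCell] = []
    for index, (m, p) in enumerate((m, p) for m in m_grid for p in p_grid):
        params = params_base.replace(m=float(m), p=float(p))
        dc = degree_constraints(params)
        cell = SweepCell(
            m=float(m), p=float(p), min_in=dc.min_in, max_out=dc.max_out,
            feasible=dc.feasible,
        )
        if not dc.feasible:
            cell.status = "infeasible"
            logger.info("cell m=%g p=%g: infeasible (min_in=%d, max_out=%d)",
                        m, p, dc.min_in, dc.max_out)
            cells.append(cell)
            continue

        spec = OptimalNetworkSpec(
            N=params.N, d_in=dc.min_in, d_out_cap=min(dc.max_out, params.N - 1)
        )
        try:
            nets = sample_optimal(spec, n_samples, seed=_cell_seed(seed, index))
        except SamplingError:
            cell.status = "degenerate"
            logger.warning("cell m=%g p=%g: sampler retry cap exhausted", m, p)
            cells.append(cell)
            continue

        h_scores = np.array([krackhardt.graph_hierarchy(net) for net in nets])
        e_score = krackhardt.graph_efficiency(nets[0])
        order = np.argsort(h_scores, kind="stable")
        median_idx = int(order[len(order) // 2])

        cell.n_samples = len(nets)
        cell.H_min = float(h_scores.min())
        cell.H_median = float(np.median(h_scores))
        cell.H_max = float(h_scores.max())
        cell.E = float(e_score)
        cell.composite_median = float(np.median(e_score * h_scores))
        cell.representative = nets[median_idx]
        logger.info(
            "cell m=%g p=%g: min_in=%d max_out=%d E=%.4f H_median=%.4f (%d samples)",
            m, p, dc.min_in, dc.max_out, cell.E, cell.H_median, cell.n_samples,
        )
        if cells_dir is not None:
            path = cells_dir / f"m{m:g}_p{p:g}.graphml"
            cell.representative.write_graphml(path)
            cell.representative_path = str(path)
        cells.append(cell)
    return cells


def summarize(cells: Sequence[SweepCell], csv_path: str | Path | None = None) -> pd.DataFrame:
    """Tidy one-row-per-cell table; optionally written as CSV."""
    rows = []
    for c in cells:
        rows.append({
            "m": c.m, "p": c.p, "min_in": c.min_in, "max_out": c.max_out,
            "feasible": c.feasible, "status": c.status, "n_samples": c.n_samples,
            "H_min": c.H_min, "H_median": c.H_median, "H_max": c.H_max,
            "E": c.E, "composite_median": c.composite_median,
            "representative": c.representative_path,
        })
    df = pd.DataFrame(rows, columns=_CSV_COLUMNS)
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    return df


def plot_composite_heatmap(df: pd.DataFrame, path: str | Path) -> None:
    """Heat map of the median composite hierarchy score over the (m, p) grid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = df.pivot(index="m", columns="p", values="composite_median")
    fig, ax = plt.subplots(figsize=(6, 4.5))
    im = ax.imshow(
        pivot.values, origin="lower", aspect="auto", vmin=0, vmax=1, cmap="viridis"
    )
    ax.set_xticks(range(len(pivot.columns)), [f"{v:g}" for v in pivot.columns])
    ax.set_yticks(range(len(pivot.index)), [f"{v:g}" for v in pivot.index])
    ax.set_xlabel("punishment efficiency p")
    ax.set_ylabel("monitoring efficiency m")
    ax.set_title("median composite hierarchy score (E x H)")
    fig.colorbar(im, ax=ax, label="E x H")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
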