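"""Parameter-sensitivity sweeps for run detection.

The sweep varies one detection parameter at a time around a base scenario
and monitors, per grid point: the number of runs detected, the average
number of runs per animal (all panel animals, including those with none),
the average run size, and -- for ROH sweeps -- the average FROH.  The
monitored axes match the knobs whose influence is debated across studies:
required SNP density, and the heterozygous / missing (or, for
heterozygosity-rich regions, homozygous / missing) calls allowed inside a
run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, MarkerMap
from .runs_detection import (
    ConsecutiveParams,
    RohParams,
    RunSet,
    detect_roh_sliding,
    detect_runs_consecutive,
)
from .runs_summary import froh

__all__ = ["SweepGrid", "sweep", "plot_sweep"]


@dataclass
class SweepGrid:
    """One swept axis with its values and the base parameter set."""

    axis: str
    values: Sequence
    base: RohParams | ConsecutiveParams

    def __post_init__(self) -> None:
        if not dataclasses.is_dataclass(self.base):
            raise TypeError("base must be RohParams or ConsecutiveParams")
        names = {f.name for f in dataclasses.fields(self.base)}
        if self.axis not in names:
            raise ValueError(
                f"axis {self.axis!r} is not a parameter of "
                f"{type(self.base).__name__}")
        if len(self.values) == 0:
            raise ValueError("empty value grid")

    def points(self) -> list[RohParams | ConsecutiveParams]:
        """Parameter sets for every grid value (validates values upfront,
        before any detection runs)."""
        return [dataclasses.replace(self.base, **{self.axis: v})
                for v in self.values]


def sweep(genotypes: GenotypeMatrix, marker_map: MarkerMap, grid: SweepGrid,
          l_auto_mb: float | None = None) -> pd.DataFrame:
    """Run the detector at every grid point and tabulate the monitored
    variables.  Each row is exactly what a direct detector + summary call
    at that parameter point produces (no state is shared between points).

    Columns: axis, value, n_runs, avg_n, avg_size_kb and, for ROH sweeps
    (``RohParams`` base, or consecutive with target 'hom'), avg_froh --
    which requires ``l_auto_mb``.
    """
    points = grid.points()
    is_roh = isinstance(grid.base, RohParams) or (
        isinstance(grid.base, ConsecutiveParams) and grid.base.target == "hom")
    if is_roh and l_auto_mb is None:
        l_auto_mb = marker_map.covered_length_mb()
    rows = []
    for value, params in zip(grid.values, points):
        runset = _detect(genotypes, marker_map, params)
        rows.append(_summarise(runset, grid.axis, value,
                               l_auto_mb if is_roh else None))
    return pd.DataFrame(rows)


def _detect(genotypes, marker_map, params) -> RunSet:
    if isinstance(params, RohParams):
        return detect_roh_sliding(genotypes, marker_map, params)
    return detect_runs_consecutive(genotypes, marker_map, params)


def _summarise(runset: RunSet, axis: str, value, l_auto_mb: float | None
               ) -> dict:
    n_runs = len(runset)
    n_animals = max(len(runset.samples), 1)
    row = {
        "axis": axis,
        "value": value,
        "n_runs": n_runs,
        "avg_n": n_runs / n_animals,
        "avg_size_kb": float(runset.df["length_bp"].mean() / 1000.0)
        if n_runs else 0.0,
    }
    if l_auto_mb is not None:
        row["avg_froh"] = float(froh(runset, l_auto_mb)["froh_total"].mean())
    return row


def plot_sweep(result: pd.DataFrame, path: str | Path,
               base_value=None) -> None:
    """One panel per monitored variable against the swept axis; the base
    scenario value, if given, is shaded."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    monitored = [c for c in ("n_runs", "avg_n", "avg_size_kb", "avg_froh")
                 if c in result.columns]
    fig, axes = plt.subplots(1, len(monitored),
                             figsize=(3.2 * len(monitored), 3.0))
    axes = np.atleast_1d(axes)
    x = result["value"].to_numpy()
    for ax, col in zip(axes, monitored):
        ax.plot(x, result[col].to_numpy(), marker="o", ms=3)
        ax.set_xlabel(str(result["axis"].iloc[0]))
        ax.set_title(col, fontsize=9)
        if base_value is not None:
            ax.axvspan(base_value - 0.25, base_value + 0.25,
                       color="pink", alpha=0.4)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
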