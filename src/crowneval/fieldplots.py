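"""Fixed-area regeneration plot summaries and density expansion.

Field crews tally every regenerating stem taller than 0.3 m inside
fixed-area circular plots; the block-level stem density comes from the
mean plot tally times the plot expansion factor (plots-to-acre: 500 for
the high-density block, 200 for the medium- and low-density blocks),
converted to per-hectare with the 2.471 acre/ha factor. The 0.3 m tally
filter is applied at ingestion, matching the field protocol; summaries
use sample statistics (sd with the n-1 denominator).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ACRES_PER_HECTARE",
    "MIN_TALLY_HEIGHT_M",
    "StemTally",
    "PlotSample",
    "expand_density",
    "read_tallies",
    "summarize_plots",
]

ACRES_PER_HECTARE = 2.471
MIN_TALLY_HEIGHT_M = 0.3


@dataclass(frozen=True)
class StemTally:
    species: str
    rcd_mm: float  # root-collar diameter
    height_m: float
    crown_width_m: float


@dataclass
class PlotSample:
    plot_id: str
    center: tuple[float, float]
    expansion_factor: float  # plots per acre
    block: str = ""
    tallies: list[StemTally] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.expansion_factor <= 0:
            raise ValueError("expansion_factor must be positive")

    @property
    def count(self) -> int:
        return len(self.tallies)


def expand_density(
    mean_plot_count: float,
    expansion_factor: float,
    acre_to_ha: float = ACRES_PER_HECTARE,
) -> float:
    """Stems/ha from a mean plot tally: count x expansion x acre-to-ha."""
    if expansion_factor <= 0:
        raise ValueError("expansion_factor must be positive")
    if mean_plot_count < 0 or acre_to_ha <= 0:
        raise ValueError("inputs must be non-negative (factors positive)")
    return mean_plot_count * expansion_factor * acre_to_ha


def read_tallies(path: str | Path) -> list[PlotSample]:
    """Load plot tallies from CSV.

    Columns: plot_id, block, x, y, expansion_factor, species, rcd_mm,
    height_m, crown_width_m — one row per tallied stem; rows below the
    0.3 m height rule are dropped here (ingestion-time filter). A plot
    with zero qualifying stems still appears (empty tallies) provided it
    has at least one row (possibly with blank species fields).
    """
    df = pd.read_csv(path)
    plots: dict[str, PlotSample] = {}
    for _, row in df.iterrows():
        pid = str(row["plot_id"])
        if pid not in plots:
            plots[pid] = PlotSample(
                plot_id=pid,
                center=(float(row["x"]), float(row["y"])),
                expansion_factor=float(row["expansion_factor"]),
                block=str(row.get("block", "")),
            )
        if pd.isna(row.get("species")) or str(row["species"]) == "":
            continue
        height = float(row["height_m"])
        if height < MIN_TALLY_HEIGHT_M:
            continue
        plots[pid].tallies.append(
            StemTally(
                species=str(row["species"]),
                rcd_mm=float(row["rcd_mm"]),
                height_m=height,
                crown_width_m=float(row["crown_width_m"]),
            )
        )
    return list(plots.values())


def _stats(values: np.ndarray) -> dict[str, float]:
    if len(values) == 0:
        return {k: float("nan") for k in ("mean", "median", "sd", "min", "max")}
    return {
        "mean": float(np.mean(values)),
        "median": float(np.median(values)),
        "sd": float(np.std(values, ddof=1)) if len(values) > 1 else float("nan"),
        "min": float(np.min(values)),
        "max": float(np.max(values)),
    }


def summarize_plots(samples: Sequence[PlotSample]) -> pd.DataFrame:
    """Per-variable summary statistics across plots.

    Rows: count_per_plot (stems/plot), density_stems_ha (plot counts
    expanded to stems/ha before summarizing — both units labeled
    explicitly), crown_width_m, height_m. Columns: mean, median, sd, min,
    max. Stem-level variables pool all tallied stems.
    """
    if not samples:
        raise ValueError("no plots to summarize")
    counts = np.array([p.count for p in samples], dtype=float)
    densities = np.array(
        [expand_density(p.count, p.expansion_factor) for p in samples]
    )
    widths = np.array([t.crown_width_m for p in samples for t in p.tallies])
    heights = np.array([t.height_m for p in samples for t in p.tallies])
    rows = {
        "count_per_plot": _stats(counts),
        "density_stems_ha": _stats(densities),
        "crown_width_m": _stats(widths),
        "height_m": _stats(heights),
    }
    return pd.DataFrame(rows).T[["mean", "median", "sd", "min", "max"]]
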