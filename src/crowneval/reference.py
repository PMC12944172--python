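"""Construction of the "Other" (true-negative candidate) reference layer.

The procedure mirrors the map-based assessment design: overlay a 1 m x 1 m
grid on the test block, buffer each cell center by the site-specific
average crown width (0.5 m for the medium-density block, 1 m for the
high-density block), discard every buffer that intersects a delineated
crown polygon, and retain a fixed number of the survivors (500 MD, 400 HD)
by seeded uniform subsampling.

The 0.5 m / 1 m values are interpreted as buffer *radii*; the study
phrasing ("buffered based on ... average crown width values") leaves
radius-vs-diameter ambiguous, and plot-level mean crown widths are near
1 m, so the radius reading is adopted and exposed as explicit
configuration. Buffers are not required to be mutually disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from shapely import STRtree
from shapely.geometry import Polygon

from .geometry import BBox, GridSpec, buffer_point, grid_centers

__all__ = ["TnConfig", "generate_other_polygons"]


@dataclass(frozen=True)
class TnConfig:
    cell_size_m: float = 1.0
    buffer_radius_m: float = 0.5
    n_target: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_size_m <= 0 or self.buffer_radius_m <= 0:
            raise ValueError("cell size and buffer radius must be positive")
        if self.n_target < 1:
            raise ValueError("n_target must be >= 1")


def generate_other_polygons(
    extent: BBox,
    crowns: Sequence[Polygon],
    cfg: TnConfig,
    rng: Optional[np.random.Generator] = None,
) -> list[Polygon]:
    """Grid -> center buffers -> drop crown-intersecting -> subsample.

    Every returned polygon has zero interior overlap with every crown.
    Raises if fewer than ``cfg.n_target`` buffers survive the filter,
    naming the shortfall.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    centers = grid_centers(GridSpec(extent=extent, cell_size=cfg.cell_size_m))
    buffers = [buffer_point(c, cfg.buffer_radius_m) for c in centers]

    if crowns:
        tree = STRtree(list(crowns))
        survivors = []
        for b in buffers:
            idx = tree.query(b, predicate="intersects")
            # interior overlap only: boundary contact does not disqualify
            if all(b.intersection(crowns[i]).area <= 0.0 for i in idx):
                survivors.append(b)
    else:
        survivors = buffers

    if len(survivors) < cfg.n_target:
        raise ValueError(
            f"only {len(survivors)} candidate 'Other' polygons survive the crown "
            f"filter; {cfg.n_target} requested (short by {cfg.n_target - len(survivors)})"
        )
    if len(survivors) == cfg.n_target:
        return survivors
    keep = rng.choice(len(survivors), size=cfg.n_target, replace=False)
    keep.sort()
    return [survivors[i] for i in keep]
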