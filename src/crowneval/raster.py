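"""Georeferenced rasters: an in-memory container, TIFF I/O, and scene
rendering.

Rasters are stored as plain TIFF via :mod:`tifffile` with an ESRI world
file (``.tfw``) carrying the affine geotransform and a small JSON sidecar
carrying the CRS tag and band count — all plain text next to the image, so
any GIS can open the pair. North-up rasters only: row 0 is the top
(maximum y) of the extent, square pixels at the ground sampling distance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Optional

import numpy as np
import tifffile

from .geometry import BBox

if TYPE_CHECKING:  # pragma: no cover
    from .synth import Scene

__all__ = ["GeoRaster", "rasterize_scene", "write_geotiff", "read_geotiff"]

#: refuse to allocate rasters beyond this many pixels per band
DEFAULT_PIXEL_BUDGET = 200_000_000


@dataclass
class GeoRaster:
    """(bands, rows, cols) array + north-up geotransform in map meters."""

    data: np.ndarray  # shape (bands, rows, cols)
    origin: tuple[float, float]  # map coords of the OUTER top-left corner
    gsd: float  # meters per pixel, square pixels
    crs: str = "local-meters"

    def __post_init__(self) -> None:
        if self.data.ndim == 2:
            self.data = self.data[np.newaxis, ...]
        if self.data.ndim != 3:
            raise ValueError("raster data must be (bands, rows, cols)")
        if self.gsd <= 0:
            raise ValueError("gsd must be positive")

    @property
    def bands(self) -> int:
        return self.data.shape[0]

    @property
    def shape_px(self) -> tuple[int, int]:
        """(width, height) in pixels."""
        return (self.data.shape[2], self.data.shape[1])

    @property
    def extent(self) -> BBox:
        w, h = self.shape_px
        x0, y0 = self.origin
        return BBox(x0, y0 - h * self.gsd, x0 + w * self.gsd, y0)

    def map_to_pixel(self, x: float, y: float) -> tuple[float, float]:
        """Map coords -> fractional (col, row); (0, 0) is the top-left corner."""
        return ((x - self.origin[0]) / self.gsd, (self.origin[1] - y) / self.gsd)

    def pixel_to_map(self, col: float, row: float) -> tuple[float, float]:
        return (self.origin[0] + col * self.gsd, self.origin[1] - row * self.gsd)


def rasterize_scene(
    scene: "Scene",
    bands: int = 1,
    rng: Optional[np.random.Generator] = None,
    pixel_budget: int = DEFAULT_PIXEL_BUDGET,
) -> GeoRaster:
    """Render a scene to imagery: bright crown discs over noisy background.

    Pixel grid covers the extent by ceiling division of extent/gsd. Crowns
    render at a distinct high intensity, 'Other' vegetation at an
    intermediate one; per-band intensity offsets give multiband outputs
    non-identical channels. Not photorealistic — just enough contrast for
    chip export and geometric round-trip checks.
    """
    cfg = scene.config
    w_m, h_m = cfg.extent_m
    gsd = cfg.gsd_m
    w_px = math.ceil(w_m / gsd - 1e-9)
    h_px = math.ceil(h_m / gsd - 1e-9)
    if w_px * h_px > pixel_budget:
        raise ValueError(
            f"raster would be {w_px} x {h_px} px, exceeding the pixel budget "
            f"of {pixel_budget}"
        )
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)

    base = rng.normal(60.0, 5.0, size=(h_px, w_px))

    def paint(polys, level: float) -> None:
        for p in polys:
            xmin, ymin, xmax, ymax = p.bounds
            c0 = max(0, int((xmin - 0) / gsd))
            c1 = min(w_px, int(math.ceil(xmax / gsd)))
            r0 = max(0, int((h_m - ymax) / gsd))
            r1 = min(h_px, int(math.ceil((h_m - ymin) / gsd)))
            if c1 <= c0 or r1 <= r0:
                continue
            cols = (np.arange(c0, c1) + 0.5) * gsd
            rows = h_m - (np.arange(r0, r1) + 0.5) * gsd
            cx, cy = p.centroid.x, p.centroid.y
            rad2 = p.area / math.pi
            dx2 = (cols - cx) ** 2
            dy2 = (rows - cy) ** 2
            mask = dy2[:, None] + dx2[None, :] <= rad2
            block = base[r0:r1, c0:c1]
            block[mask] = level + rng.normal(0.0, 3.0, size=int(mask.sum()))

    paint(scene.others, 100.0)
    paint(scene.crowns, 170.0)

    offsets = np.linspace(0.0, 10.0 * (bands - 1), bands)
    data = np.clip(base[np.newaxis, :, :] + offsets[:, None, None], 0, 255).astype(
        np.uint8
    )
    return GeoRaster(data=data, origin=(0.0, h_m), gsd=gsd, crs=scene.crs)


def write_geotiff(raster: GeoRaster, path: str | Path) -> None:
    """TIFF + .tfw world file + .json CRS sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.moveaxis(raster.data, 0, -1).squeeze())
    gsd = raster.gsd
    # world file: pixel size, rotations, center of the top-left pixel
    cx = raster.origin[0] + gsd / 2.0
    cy = raster.origin[1] - gsd / 2.0
    lines = [f"{gsd:.10f}", "0.0", "0.0", f"{-gsd:.10f}", f"{cx:.10f}", f"{cy:.10f}"]
    path.with_suffix(".tfw").write_text("\n".join(lines) + "\n")
    path.with_suffix(".json").write_text(
        json.dumps({"crs": raster.crs, "bands": raster.bands}) + "\n"
    )


def read_geotiff(path: str | Path) -> GeoRaster:
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim == 3:
        arr = np.moveaxis(arr, -1, 0)
    vals = [float(v) for v in path.with_suffix(".tfw").read_text().split()]
    gsd = vals[0]
    origin = (vals[4] - gsd / 2.0, vals[5] + gsd / 2.0)
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return GeoRaster(data=arr, origin=origin, gsd=gsd, crs=meta.get("crs", "unknown"))
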