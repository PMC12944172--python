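"""Training-chip export: sliding-window tiling, rotation, PASCAL VOC XML.

Reproduces the "export training data" stage of the workflow: a
georeferenced raster is tiled with a 256 px window moving at a 128 px
stride (both configurable), labeled crown polygons are clipped to each
window, and each emitted chip gets a PASCAL VOC annotation file with the
axis-aligned pixel-space envelope of every clipped polygon.

Rotation: with ``rotation_deg = 45`` chips are generated at every multiple
of 45 degrees (0, 45, ..., 315) about the raster center. For each
orientation the raster footprint is tiled in the rotated frame and windows
falling partly outside the footprint are dropped, so rotation multiplies
the chip count by roughly the number of orientations minus boundary
losses. Exact counts are data-dependent; only the direction (rotation
produces strictly more chips) is guaranteed.

VOC dialect: pixel coordinates are written 1-based inclusive (the classic
convention). Chips with zero objects are skipped by default; pass
``keep_empty=True`` to emit background-only chips. Objects clipped at tile
edges are kept whenever the residual overlap area is positive; a
minimum-overlap-fraction option tightens this.
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from scipy import ndimage
from shapely.geometry import Polygon, box as shapely_box

from .raster import GeoRaster

__all__ = [
    "ChipSpec",
    "VocObject",
    "VocAnnotation",
    "ChipSet",
    "plan_tiles",
    "export_chips",
    "write_voc",
    "read_voc",
]


@dataclass(frozen=True)
class ChipSpec:
    tile_x: int = 256
    tile_y: int = 256
    stride_x: int = 128
    stride_y: int = 128
    rotation_deg: int = 0  # 0 or 45
    image_format: str = "TIFF"
    metadata_format: str = "PASCAL VOC"
    min_overlap_frac: float = 0.0
    keep_empty: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.stride_x <= self.tile_x and 0 < self.stride_y <= self.tile_y):
            raise ValueError("stride must satisfy 0 < stride <= tile")
        if self.rotation_deg not in (0, 45):
            raise ValueError("rotation_deg must be 0 or 45")
        if not 0.0 <= self.min_overlap_frac <= 1.0:
            raise ValueError("min_overlap_frac must be in [0, 1]")

    @property
    def orientations(self) -> tuple[int, ...]:
        if self.rotation_deg == 0:
            return (0,)
        return tuple(range(0, 360, self.rotation_deg))


@dataclass(frozen=True)
class VocObject:
    name: str
    xmin: int
    ymin: int
    xmax: int
    ymax: int  # 1-based inclusive pixel coords


@dataclass
class VocAnnotation:
    filename: str
    width: int
    height: int
    depth: int
    objects: list[VocObject] = field(default_factory=list)


@dataclass
class ChipSet:
    out_dir: Path
    annotations: list[VocAnnotation]
    n_orientations: int

    @property
    def n_chips(self) -> int:
        return len(self.annotations)

    @property
    def n_objects(self) -> int:
        return sum(len(a.objects) for a in self.annotations)


def _axis_positions(dim: int, tile: int, stride: int) -> tuple[list[int], bool]:
    """Window offsets along one axis; second value flags a padded window.

    Offsets step by ``stride`` while a full tile fits; a trailing window
    flush with the far edge is added when the last step falls short. A
    raster smaller than the tile yields a single zero-padded window.
    """
    if dim <= 0:
        raise ValueError(f"nonpositive raster dimension {dim}")
    if dim < tile:
        return [0], True
    pos = list(range(0, dim - tile + 1, stride))
    if pos[-1] + tile < dim:
        pos.append(dim - tile)
    return pos, False


def plan_tiles(width_px: int, height_px: int, spec: ChipSpec) -> list[tuple[int, int]]:
    """(col_off, row_off) for every window over an unrotated raster."""
    cols, _ = _axis_positions(width_px, spec.tile_x, spec.stride_x)
    rows, _ = _axis_positions(height_px, spec.tile_y, spec.stride_y)
    return [(c, r) for r in rows for c in cols]


def _rot(theta_deg: float) -> np.ndarray:
    t = math.radians(theta_deg)
    return np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])


def export_chips(
    raster: GeoRaster,
    polygons: Sequence[tuple[str, Polygon]],
    spec: ChipSpec,
    out_dir: str | Path,
) -> ChipSet:
    """Tile ``raster``, clip ``polygons`` (label, geometry) to each window,
    and write TIFF chips under ``images/`` with VOC XML under ``labels/``.
    """
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    lbl_dir = out_dir / "labels"
    img_dir.mkdir(parents=True, exist_ok=True)
    lbl_dir.mkdir(parents=True, exist_ok=True)

    w_px, h_px = raster.shape_px
    gsd = raster.gsd
    ext = raster.extent
    cx, cy = ext.center
    footprint = ext.to_shapely()

    annotations: list[VocAnnotation] = []
    for theta in spec.orientations:
        R = _rot(theta)
        Rinv = R.T
        # raster footprint in the rotated frame
        corners = np.array(
            [
                [ext.xmin, ext.ymin],
                [ext.xmax, ext.ymin],
                [ext.xmax, ext.ymax],
                [ext.xmin, ext.ymax],
            ]
        )
        q = (corners - [cx, cy]) @ Rinv.T
        umin, vmin = q.min(axis=0)
        umax, vmax = q.max(axis=0)
        dim_u = max(1, math.ceil((umax - umin) / gsd - 1e-9))
        dim_v = max(1, math.ceil((vmax - vmin) / gsd - 1e-9))

        u_pos, pad_u = _axis_positions(dim_u, spec.tile_x, spec.stride_x)
        v_pos, pad_v = _axis_positions(dim_v, spec.tile_y, spec.stride_y)
        padded = pad_u or pad_v

        for row_off in v_pos:
            for col_off in u_pos:
                # window corners in map coords
                wu0 = umin + col_off * gsd
                wv1 = vmax - row_off * gsd
                wu1 = wu0 + spec.tile_x * gsd
                wv0 = wv1 - spec.tile_y * gsd
                win_q = np.array([[wu0, wv0], [wu1, wv0], [wu1, wv1], [wu0, wv1]])
                win_map = win_q @ R.T + [cx, cy]
                win_poly = Polygon(win_map)
                if not padded and not footprint.covers(
                    win_poly.buffer(-1e-9 * spec.tile_x * gsd)
                ):
                    continue

                objects = _window_objects(
                    polygons, theta, (cx, cy), (wu0, wv1), gsd, spec
                )
                if not objects and not spec.keep_empty:
                    continue

                chip = _sample_chip(raster, theta, (cx, cy), (wu0, wv1), spec)
                stem = f"chip_r{theta:03d}_{col_off:06d}_{row_off:06d}"
                fname = stem + ".tif"
                tifffile.imwrite(img_dir / fname, np.moveaxis(chip, 0, -1).squeeze())
                ann = VocAnnotation(
                    filename=fname,
                    width=spec.tile_x,
                    height=spec.tile_y,
                    depth=raster.bands,
                    objects=objects,
                )
                write_voc(ann, lbl_dir / (stem + ".xml"))
                annotations.append(ann)

    return ChipSet(out_dir=out_dir, annotations=annotations, n_orientations=len(spec.orientations))


def _window_objects(
    polygons: Sequence[tuple[str, Polygon]],
    theta: float,
    center: tuple[float, float],
    win_origin_uv: tuple[float, float],
    gsd: float,
    spec: ChipSpec,
) -> list[VocObject]:
    """Clip polygons to one rotated window; boxes in chip pixel coords."""
    wu0, wv1 = win_origin_uv
    win_box = shapely_box(0, 0, spec.tile_x, spec.tile_y)
    out: list[VocObject] = []
    for label, poly in polygons:
        # map -> rotated frame -> chip pixel coords (row axis down)
        px = _poly_to_chip(poly, theta, center, wu0, wv1, gsd)
        clipped = px.intersection(win_box)
        if clipped.is_empty or clipped.area <= 0.0:
            continue
        if px.area > 0 and clipped.area / px.area < spec.min_overlap_frac:
            continue
        bxmin, bymin, bxmax, bymax = clipped.bounds
        out.append(
            VocObject(
                name=label,
                xmin=max(1, int(math.floor(bxmin)) + 1),
                ymin=max(1, int(math.floor(bymin)) + 1),
                xmax=min(spec.tile_x, int(math.ceil(bxmax))),
                ymax=min(spec.tile_y, int(math.ceil(bymax))),
            )
        )
    return out


def _poly_to_chip(
    poly: Polygon,
    theta: float,
    center: tuple[float, float],
    wu0: float,
    wv1: float,
    gsd: float,
) -> Polygon:
    Rinv = _rot(theta).T
    coords = np.asarray(poly.exterior.coords)
    q = (coords - center) @ Rinv.T
    cols = (q[:, 0] - wu0) / gsd
    rows = (wv1 - q[:, 1]) / gsd
    return Polygon(np.column_stack([cols, rows]))


def _sample_chip(
    raster: GeoRaster,
    theta: float,
    center: tuple[float, float],
    win_origin_uv: tuple[float, float],
    spec: ChipSpec,
) -> np.ndarray:
    """Bilinear resample of the source raster over one rotated window."""
    wu0, wv1 = win_origin_uv
    gsd = raster.gsd
    jj, ii = np.meshgrid(np.arange(spec.tile_x), np.arange(spec.tile_y))
    u = wu0 + (jj + 0.5) * gsd
    v = wv1 - (ii + 0.5) * gsd
    R = _rot(theta)
    x = center[0] + R[0, 0] * u + R[0, 1] * v
    y = center[1] + R[1, 0] * u + R[1, 1] * v
    col = (x - raster.origin[0]) / gsd - 0.5
    row = (raster.origin[1] - y) / gsd - 0.5
    out = np.empty((raster.bands, spec.tile_y, spec.tile_x), dtype=raster.data.dtype)
    for b in range(raster.bands):
        out[b] = ndimage.map_coordinates(
            raster.data[b], [row, col], order=1, mode="constant", cval=0
        )
    return out


# ---------------------------------------------------------------------------
# PASCAL VOC XML


def write_voc(ann: VocAnnotation, path: str | Path) -> None:
    """Serialize deterministically (byte-stable across round-trips)."""
    lines = [
        "<annotation>",
        f"  <filename>{ann.filename}</filename>",
        "  <size>",
        f"    <width>{ann.width}</width>",
        f"    <height>{ann.height}</height>",
        f"    <depth>{ann.depth}</depth>",
        "  </size>",
    ]
    for o in ann.objects:
        lines += [
            "  <object>",
            f"    <name>{o.name}</name>",
            "    <bndbox>",
            f"      <xmin>{o.xmin}</xmin>",
            f"      <ymin>{o.ymin}</ymin>",
            f"      <xmax>{o.xmax}</xmax>",
            f"      <ymax>{o.ymax}</ymax>",
            "    </bndbox>",
            "  </object>",
        ]
    lines.append("</annotation>")
    Path(path).write_text("\n".join(lines) + "\n")


def read_voc(path: str | Path) -> VocAnnotation:
    """Parse a PASCAL VOC annotation file (inverse of :func:`write_voc`)."""
    root = ET.parse(str(path)).getroot()
    size = root.find("size")
    objects = []
    for obj in root.findall("object"):
        bb = obj.find("bndbox")
        objects.append(
            VocObject(
                name=obj.findtext("name", ""),
                xmin=int(float(bb.findtext("xmin"))),
                ymin=int(float(bb.findtext("ymin"))),
                xmax=int(float(bb.findtext("xmax"))),
                ymax=int(float(bb.findtext("ymax"))),
            )
        )
    return VocAnnotation(
        filename=root.findtext("filename", ""),
        width=int(size.findtext("width")),
        height=int(size.findtext("height")),
        depth=int(size.findtext("depth", "1")),
        objects=objects,
    )
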