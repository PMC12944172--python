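"""GeoJSON I/O for reference polygons and detections.

Plain FeatureCollections written with the standard library JSON encoder
and shapely's geometry mapping; a foreign ``crs`` member carries the
projected-CRS tag (all coordinates are meters in one local projected
frame — nothing is ever reprojected). Detections carry a ``confidence``
property; reference polygons a ``class`` property ("White Pine"/"Other").
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

from shapely.geometry import mapping, shape
from shapely.geometry import Polygon

from .geometry import BBox
from .postprocess import Detection

__all__ = [
    "write_polygons",
    "read_polygons",
    "write_detections",
    "read_detections",
    "CrsMismatchError",
]


class CrsMismatchError(ValueError):
    """Raised when layers carry different CRS tags (no silent reprojection)."""


def _fc(features: list[dict], crs: str) -> dict:
    return {"type": "FeatureCollection", "crs": crs, "features": features}


def write_polygons(
    polys: Sequence[Polygon], path: str | Path, label: str, crs: str = "local-meters"
) -> None:
    feats = [
        {"type": "Feature", "properties": {"class": label}, "geometry": mapping(p)}
        for p in polys
    ]
    Path(path).write_text(json.dumps(_fc(feats, crs)) + "\n")


def read_polygons(
    path: str | Path, expect_crs: Optional[str] = None
) -> tuple[list[tuple[str, Polygon]], str]:
    """Returns ([(class label, polygon), ...], crs tag)."""
    data = json.loads(Path(path).read_text())
    crs = data.get("crs", "unknown")
    if expect_crs is not None and crs != expect_crs:
        raise CrsMismatchError(f"layer CRS {crs!r} != expected {expect_crs!r}")
    out = []
    for f in data["features"]:
        geom = shape(f["geometry"])
        out.append((f.get("properties", {}).get("class", ""), geom))
    return out, crs


def write_detections(
    dets: Sequence[Detection], path: str | Path, crs: str = "local-meters"
) -> None:
    feats = []
    for d in dets:
        feats.append(
            {
                "type": "Feature",
                "properties": {"confidence": d.confidence, "class": d.label},
                "geometry": mapping(d.box.to_shapely()),
            }
        )
    Path(path).write_text(json.dumps(_fc(feats, crs)) + "\n")


def read_detections(
    path: str | Path, expect_crs: Optional[str] = None
) -> tuple[list[Detection], str]:
    data = json.loads(Path(path).read_text())
    crs = data.get("crs", "unknown")
    if expect_crs is not None and crs != expect_crs:
        raise CrsMismatchError(f"layer CRS {crs!r} != expected {expect_crs!r}")
    dets = []
    for f in data["features"]:
        geom = shape(f["geometry"])
        props = f.get("properties", {})
        dets.append(
            Detection(
                box=BBox.from_shapely(geom),
                confidence=float(props.get("confidence", 1.0)),
                label=props.get("class"),
            )
        )
    return dets, crs
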