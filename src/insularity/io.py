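"""GeoJSON / CSV input-output for archipelagos and result tables.

GeoJSON carries no CRS by convention; the projected CRS of the coordinates
is declared in a top-level ``"crs_name"`` member on write and may be
supplied on read.  Coordinates must be metres — lon/lat input is rejected
by :class:`~insularity.geometry.Archipelago`.
"""

from __future__ import annotations

import json
from pathlib import Path

from shapely.geometry import mapping, shape

from .geometry import Archipelago, IslandPolygon

__all__ = ["read_archipelago", "write_archipelago"]


def read_archipelago(path: str | Path, crs: str | None = None) -> Archipelago:
    """Read island polygons from a GeoJSON FeatureCollection.

    Each feature needs properties ``id`` (string) and ``sampled`` (0/1 or
    bool).  ``crs`` overrides any ``crs_name`` stored in the file.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    islands = []
    for k, feat in enumerate(doc.get("features", [])):
        props = feat.get("properties") or {}
        if "id" not in props:
            raise ValueError(f"{path}: feature {k} is missing the 'id' property")
        geom = shape(feat["geometry"])
        islands.append(
            IslandPolygon(
                id=str(props["id"]),
                geometry=geom,
                sampled=bool(int(props.get("sampled", 1))),
            )
        )
    file_crs = crs or doc.get("crs_name") or "local-metric"
    return Archipelago(islands, crs=file_crs)


def write_archipelago(arch: Archipelago, path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"id": isl.id, "sampled": int(isl.sampled)},
            "geometry": mapping(isl.geometry),
        }
        for isl in arch
    ]
    doc = {"type": "FeatureCollection", "crs_name": arch.crs, "features": features}
    with open(path, "w") as fh:
        json.dump(doc, fh)
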