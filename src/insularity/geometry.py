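"""Island shape and isolation predictors from polygon geometry.

All distances are planar Euclidean in a projected, metre-unit CRS.  The
module computes, per sampled island, the predictors used by habitat-island
biogeography: area (m²), perimeter (m), edge-to-edge distance to the nearest
neighbouring island, edge-to-edge distance to the archipelago's largest
island (the "mainland equivalent", DMI), and the area-scaled isolation
index known as the target effect,

    target_effect = log10(DMI / sqrt(A)),

which is high for small islands far from the species pool.  An optional
proximity index (sum of neighbour area over squared edge distance within a
search radius) is provided as an explicitly reconstructed landscape-ecology
measure and is not part of the default predictor set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon
from shapely.geometry.base import BaseGeometry

__all__ = [
    "IslandPolygon",
    "Archipelago",
    "GeometryError",
    "compute_area_perimeter",
    "nearest_neighbour_distance",
    "distance_to_main_island",
    "target_effect",
    "proximity_index",
    "predictor_geometry_table",
    "DEFAULT_EPSILON",
]

#: substitute edge distance for touching / coincident cases (one image cell)
DEFAULT_EPSILON = 2.0


class GeometryError(ValueError):
    """Invalid or degenerate geometry, or an ill-posed geometric query."""


@dataclass(frozen=True)
class IslandPolygon:
    """One habitat island: an id, a simple polygon (holes allowed), and a
    flag marking whether its flora was sampled."""

    id: str
    geometry: Polygon
    sampled: bool = True

    def __post_init__(self) -> None:
        geom = self.geometry
        if not isinstance(geom, Polygon):
            raise GeometryError(f"island {self.id!r}: geometry must be a Polygon")
        if geom.is_empty or not geom.is_valid:
            raise GeometryError(f"island {self.id!r}: invalid or empty polygon")
        if geom.area <= 0:
            raise GeometryError(f"island {self.id!r}: non-positive area")
        coords = shapely.get_coordinates(geom)
        if not np.all(np.isfinite(coords)):
            raise GeometryError(f"island {self.id!r}: non-finite coordinates")


class Archipelago:
    """The full set of island polygons (sampled and unsampled) in one
    projected metric CRS.

    Predictors for sampled islands consider *all* islands, so unsampled
    islands must be present.  Geographic (lon/lat) coordinates are rejected:
    all distance math here is planar and in metres.
    """

    def __init__(self, islands: list[IslandPolygon], crs: str = "local-metric"):
        if len(islands) < 2:
            raise GeometryError("an archipelago needs at least 2 islands")
        ids = [isl.id for isl in islands]
        if len(set(ids)) != len(ids):
            raise GeometryError("island ids are not unique")
        self._check_projected(islands, crs)
        self._check_disjoint(islands)
        self.islands = list(islands)
        self.crs = crs
        self._by_id = {isl.id: isl for isl in islands}

    @staticmethod
    def _check_projected(islands: list[IslandPolygon], crs: str) -> None:
        coords = np.concatenate([shapely.get_coordinates(i.geometry) for i in islands])
        lonlatish = np.all(np.abs(coords[:, 0]) <= 180) and np.all(np.abs(coords[:, 1]) <= 90)
        declared_geographic = any(tag in crs.lower() for tag in ("4326", "wgs84", "longlat", "lonlat"))
        undeclared = crs in ("", "unknown", None)
        if declared_geographic or (undeclared and lonlatish):
            raise GeometryError(
                "coordinates look geographic (lon/lat); reproject to a metric CRS first"
            )

    @staticmethod
    def _check_disjoint(islands: list[IslandPolygon]) -> None:
        tree = shapely.STRtree([i.geometry for i in islands])
        pairs = tree.query([i.geometry for i in islands], predicate="intersects")
        for a, b in pairs.T:
            if a < b:
                inter = islands[a].geometry.intersection(islands[b].geometry)
                if inter.area > 0:
                    raise GeometryError(
                        f"islands {islands[a].id!r} and {islands[b].id!r} have overlapping interiors"
                    )

    def __len__(self) -> int:
        return len(self.islands)

    def __iter__(self):
        return iter(self.islands)

    def __getitem__(self, island_id: str) -> IslandPolygon:
        return self._by_id[island_id]

    def sampled(self) -> list[IslandPolygon]:
        return [i for i in self.islands if i.sampled]

    def main_island(self) -> IslandPolygon:
        """The biggest island in the archipelago; area ties broken by
        lexicographically smallest id (deterministic pipelines need it)."""
        return min(self.islands, key=lambda i: (-i.geometry.area, i.id))


def compute_area_perimeter(island: IslandPolygon) -> tuple[float, float]:
    """Area (m²) and perimeter (m) of an island polygon.

    Holes subtract from the area and their ring length adds to the
    perimeter (shapely's ``.length`` already sums all rings).
    """
    geom = island.geometry
    return float(geom.area), float(geom.length)


def _others(focal: IslandPolygon, arch: Archipelago) -> list[IslandPolygon]:
    others = [i for i in arch if i.id != focal.id]
    if not others:
        raise GeometryError("isolation is undefined for a singleton archipelago")
    return others


def nearest_neighbour_distance(focal: IslandPolygon, arch: Archipelago) -> float:
    """Minimum edge-to-edge distance (m) from the focal island's boundary
    to the coast of any other island, sampled or not.  0 iff they touch."""
    others = _others(focal, arch)
    return float(min(focal.geometry.distance(o.geometry) for o in others))


def distance_to_main_island(focal: IslandPolygon, arch: Archipelago) -> float:
    """Edge-to-edge distance (m) to the archipelago's largest island; 0 for
    the main island itself."""
    main = arch.main_island()
    if main.id == focal.id:
        return 0.0
    return float(focal.geometry.distance(main.geometry))


def target_effect(area: float, dmi: float, epsilon: float = DEFAULT_EPSILON, base: float = 10.0) -> float:
    """Area-scaled isolation from the mainland equivalent:
    ``log(max(dmi, epsilon) / sqrt(area))``.

    ``epsilon`` (default one image cell, 2 m) only matters when ``dmi == 0``
    — i.e. for the main island itself — and keeps it in the models instead
    of dropping it.  High values mean a small island far from the pool.
    """
    if area <= 0:
        raise GeometryError("target effect needs a positive area")
    if dmi < 0:
        raise GeometryError("dmi must be non-negative")
    if epsilon <= 0:
        raise GeometryError("epsilon must be positive")
    d = max(dmi, epsilon)
    return float(math.log(d / math.sqrt(area)) / math.log(base))


def proximity_index(
    focal: IslandPolygon,
    arch: Archipelago,
    radius: float,
    epsilon: float = DEFAULT_EPSILON,
) -> float:
    """Reconstructed proximity index: Σ area_j / d_j² over islands j whose
    edge-to-edge distance d_j to the focal island is ≤ ``radius``.

    Touching neighbours (d_j = 0) use ``epsilon`` to stay finite.  This is a
    reconstruction of the standard fragmentation-analysis index and is
    excluded from the default predictor table.
    """
    if radius <= 0:
        raise GeometryError("proximity radius must be positive")
    total = 0.0
    for other in _others(focal, arch):
        d = focal.geometry.distance(other.geometry)
        if d <= radius:
            total += other.geometry.area / max(d, epsilon) ** 2
    return float(total)


def predictor_geometry_table(arch: Archipelago, epsilon: float = DEFAULT_EPSILON) -> pd.DataFrame:
    """Geometry-derived predictors for every *sampled* island.

    Columns: island_id, area_m2, perimeter_m, nn_dist_m, dmi_m,
    target_effect.  Distances consider all islands, sampled or not.
    """
    rows = []
    for isl in arch.sampled():
        area, perim = compute_area_perimeter(isl)
        nn = nearest_neighbour_distance(isl, arch)
        dmi = distance_to_main_island(isl, arch)
        rows.append(
            {
                "island_id": isl.id,
                "area_m2": area,
                "perimeter_m": perim,
                "nn_dist_m": nn,
                "dmi_m": dmi,
                "target_effect": target_effect(area, dmi, epsilon=epsilon),
            }
        )
    return pd.DataFrame(rows)
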