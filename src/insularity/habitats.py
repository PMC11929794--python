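"""Topographic habitat mapping and the habitat diversity index (HDI).

Each island is partitioned into five main habitat types — ridge, slope,
plain, valley, drainage — by ordered per-cell rules on terrain layers,
with slope cells further split into aspect-quadrant sub-habitats.  The
habitat diversity index is

    HDI = TP / (2 * sqrt(pi * A)),

where TP (total perimeter) is the island's exterior perimeter plus the
length of all internal habitat boundaries (each shared boundary counted
once) and A the island area.  A homogeneous circular island scores exactly
1; internal boundaries and shape complexity push HDI up, so the index
captures edge effects at the island–matrix interface and inside the island
alike.

The exact rule thresholds behind the original habitat maps are not fixed
by theory, so the classifier is fully configurable; the defaults produce
all five classes on realistic synthetic terrain.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import Polygon

from .geometry import IslandPolygon
from .raster import RasterGrid
from .terrain import FLAT_ASPECT, TerrainStack

__all__ = [
    "HabitatRules",
    "HabitatMap",
    "classify_habitats",
    "total_perimeter",
    "habitat_diversity_index",
    "heterogeneity_table",
    "MAIN_CLASSES",
]

MAIN_CLASSES = ("ridge", "slope", "plain", "valley", "drainage")
_ASPECT_QUADRANTS = ("N", "E", "S", "W")


@dataclass(frozen=True)
class HabitatRules:
    """Ordered per-cell classification rules.

    A cell is drainage if its flow accumulation reaches
    ``drainage_threshold`` cells; else valley / ridge by TPI against
    ``±tpi_threshold`` (m); else slope if steeper than ``slope_threshold``
    (degrees); else plain.  Patches smaller than ``min_patch_cells`` are
    merged into their largest 4-neighbouring patch to suppress single-cell
    raster artefacts (set to 1 to disable).
    """

    tpi_threshold: float = 0.5
    slope_threshold: float = 5.0
    drainage_threshold: float = 50.0
    min_patch_cells: int = 4
    split_slope_by_aspect: bool = True


def rule_labels(
    slope: np.ndarray, aspect: np.ndarray, tpi: np.ndarray, flowacc: np.ndarray,
    rules: HabitatRules,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the ordered rules cell-wise.

    Returns (main, sub): main is an index into :data:`MAIN_CLASSES`,
    sub a small integer distinguishing sub-habitats (aspect quadrants of
    slope cells; identical to a class offset elsewhere).
    """
    main = np.full(slope.shape, MAIN_CLASSES.index("plain"), dtype=np.int16)
    main[slope >= rules.slope_threshold] = MAIN_CLASSES.index("slope")
    main[tpi >= rules.tpi_threshold] = MAIN_CLASSES.index("ridge")
    main[tpi <= -rules.tpi_threshold] = MAIN_CLASSES.index("valley")
    main[flowacc >= rules.drainage_threshold] = MAIN_CLASSES.index("drainage")

    sub = main.astype(np.int16) * 10
    if rules.split_slope_by_aspect:
        is_slope = main == MAIN_CLASSES.index("slope")
        quad = (((aspect + 45.0) % 360.0) // 90.0).astype(np.int16)
        quad[aspect == FLAT_ASPECT] = 0
        sub[is_slope] += quad[is_slope]
    return main, sub


@dataclass
class HabitatMap:
    """Per-cell habitat labels for one island, on the island's raster
    window.  ``main``/``sub`` are label arrays; cells outside the island
    carry -1.  Vector patches are derived on demand."""

    island_id: str
    grid: RasterGrid            # georeference carrier (window of the scene)
    main: np.ndarray            # int16, -1 outside island
    sub: np.ndarray             # int16, -1 outside island
    island: IslandPolygon

    @property
    def inside(self) -> np.ndarray:
        return self.main >= 0

    def n_habitats(self) -> int:
        """Number of distinct sub-habitats present on the island."""
        return int(len(np.unique(self.sub[self.inside])))

    def n_main_classes(self) -> int:
        return int(len(np.unique(self.main[self.inside])))

    def class_name(self, main_code: int) -> str:
        return MAIN_CLASSES[main_code]

    def sub_name(self, sub_code: int) -> str:
        cls = MAIN_CLASSES[sub_code // 10]
        if cls == "slope":
            return f"slope-{_ASPECT_QUADRANTS[sub_code % 10]}"
        return cls

    def patches(self) -> list[tuple[str, str, Polygon]]:
        """Vector patches: one (class, sub_habitat, polygon) per connected
        component of the sub-habitat labelling, clipped to the island.

        Patch interiors are pairwise disjoint and union to the island
        polygon (up to floating-point slivers)."""
        out: list[tuple[str, str, Polygon]] = []
        xs, ys = self.grid.cell_centers()
        half = self.grid.cell / 2.0
        for code in np.unique(self.sub[self.inside]):
            comp, n = ndimage.label(self.sub == code, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
            for ci in range(1, n + 1):
                rows, cols = np.nonzero(comp == ci)
                boxes = shapely.box(xs[cols] - half, ys[rows] - half, xs[cols] + half, ys[rows] + half)
                poly = shapely.union_all(boxes).intersection(self.island.geometry)
                if poly.is_empty:
                    continue
                geoms = getattr(poly, "geoms", [poly])
                for g in geoms:
                    if g.area > 0:
                        out.append((self.class_name(code // 10), self.sub_name(code), g))
        return out

    def coverage_error(self) -> float:
        """Relative area mismatch between the patch union and the island."""
        union = shapely.union_all([p for _, _, p in self.patches()])
        a = self.island.geometry.area
        return abs(union.area - a) / a


def _island_mask(grid: RasterGrid, island: IslandPolygon) -> np.ndarray:
    """Cells whose square intersects the island polygon."""
    xs, ys = grid.cell_centers()
    X, Y = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(island.geometry, X.ravel(), Y.ravel()).reshape(X.shape)
    # cells whose centre is near the boundary may still intersect the island
    pts = shapely.points(X.ravel(), Y.ravel())
    near = shapely.distance(pts, island.geometry.boundary).reshape(X.shape) <= grid.cell * 0.7072
    cand = near & ~inside
    if np.any(cand):
        rows, cols = np.nonzero(cand)
        half = grid.cell / 2.0
        boxes = shapely.box(xs[cols] - half, ys[rows] - half, xs[cols] + half, ys[rows] + half)
        hit = shapely.intersects(boxes, island.geometry)
        # a box sharing only a boundary point contributes no area
        touch = shapely.touches(boxes[hit], island.geometry)
        inside[rows[hit][~touch], cols[hit][~touch]] = True
    return inside


def _merge_small_patches(sub: np.ndarray, inside: np.ndarray, min_cells: int) -> np.ndarray:
    """Merge connected sub-habitat patches below ``min_cells`` into their
    largest 4-neighbouring patch (repeated, smallest patch first, until
    every patch reaches the minimum or has no neighbour)."""
    if min_cells <= 1:
        return sub
    four = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    comp = np.zeros_like(sub, dtype=np.int32)
    next_id = 1
    code_of: dict[int, int] = {}
    for code in np.unique(sub[inside]):
        lab, n = ndimage.label((sub == code) & inside, structure=four)
        comp[lab > 0] = lab[lab > 0] + next_id - 1
        for i in range(next_id, next_id + n):
            code_of[i] = int(code)
        next_id += n

    sizes = np.bincount(comp.ravel(), minlength=next_id).astype(np.int64)
    # component adjacency graph from 4-neighbour cell pairs
    neigh: dict[int, set[int]] = {i: set() for i in range(1, next_id)}
    for a, b in ((comp[:-1, :], comp[1:, :]), (comp[:, :-1], comp[:, 1:])):
        m = (a > 0) & (b > 0) & (a != b)
        for u, v in zip(a[m].ravel(), b[m].ravel()):
            neigh[int(u)].add(int(v))
            neigh[int(v)].add(int(u))

    # union-find over components; merging happens on the graph only
    parent = list(range(next_id))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    heap = [(int(sizes[i]), i) for i in range(1, next_id) if sizes[i] < min_cells]
    heapq.heapify(heap)
    while heap:
        size, i = heapq.heappop(heap)
        ri = find(i)
        if ri != i or sizes[ri] != size or sizes[ri] >= min_cells:
            continue  # stale entry
        nb = {find(j) for j in neigh[ri]} - {ri}
        if not nb:
            continue  # patch fills the whole island window
        target = max(nb, key=lambda j: (sizes[j], -j))
        parent[ri] = target
        sizes[target] += sizes[ri]
        neigh[target] |= neigh[ri]
        if sizes[target] < min_cells:
            heapq.heappush(heap, (int(sizes[target]), target))

    root_code = np.array([code_of.get(find(i), 0) for i in range(next_id)], dtype=sub.dtype)
    out = sub.copy()
    out[inside] = root_code[comp[inside]]
    return out


def classify_habitats(
    island: IslandPolygon,
    terrain: TerrainStack,
    rules: HabitatRules = HabitatRules(),
) -> HabitatMap:
    """Label every raster cell of the island with its habitat class.

    The terrain stack must cover the island's extent; otherwise a
    ValueError names the island.
    """
    b = island.geometry.bounds
    gx0, gy0, gx1, gy1 = terrain.elevation.bounds
    if b[0] < gx0 or b[1] < gy0 or b[2] > gx1 or b[3] > gy1:
        raise ValueError(f"island {island.id!r} extends outside the terrain raster")
    pad = terrain.elevation.cell
    win = (b[0] - pad, b[1] - pad, b[2] + pad, b[3] + pad)
    grids = {
        name: getattr(terrain, name).window(*win)
        for name in ("slope", "aspect", "tpi", "flowacc")
    }
    ref = grids["slope"]
    inside = _island_mask(ref, island)
    if not np.any(inside):
        raise ValueError(f"island {island.id!r} covers no raster cells")
    main, sub = rule_labels(
        grids["slope"].values, grids["aspect"].values,
        grids["tpi"].values, grids["flowacc"].values, rules,
    )
    sub = _merge_small_patches(sub, inside, rules.min_patch_cells)
    main = (sub // 10).astype(np.int16)
    main[~inside] = -1
    sub = sub.copy()
    sub[~inside] = -1
    return HabitatMap(island_id=island.id, grid=ref, main=main, sub=sub, island=island)


def total_perimeter(hmap: HabitatMap, island: IslandPolygon | None = None) -> float:
    """Total perimeter TP (m): island exterior perimeter + internal habitat
    boundary length, each shared boundary counted once.

    Internal boundaries are the shared edges between 4-adjacent cells with
    different sub-habitat labels, clipped to the island polygon (raster
    staircase, no smoothing)."""
    island = island or hmap.island
    if island.id != hmap.island_id:
        raise ValueError("habitat map does not belong to this island")
    tp = float(island.geometry.length)
    tp += _internal_boundary_length(hmap, island)
    return tp


def _internal_boundary_length(hmap: HabitatMap, island: IslandPolygon) -> float:
    sub, inside = hmap.sub, hmap.inside
    cell = hmap.grid.cell
    xs, ys = hmap.grid.cell_centers()
    half = cell / 2.0
    total = 0.0
    boundary = island.geometry.boundary
    # distance of centres to the coast, to spot edges needing exact clipping
    X, Y = np.meshgrid(xs, ys)
    interior_ok = shapely.contains_xy(island.geometry, X.ravel(), Y.ravel()).reshape(X.shape)
    pts = shapely.points(X.ravel(), Y.ravel())
    deep = (shapely.distance(pts, boundary).reshape(X.shape) > cell * 1.5) & interior_ok

    for axis in (0, 1):  # vertical neighbours (rows) and horizontal (cols)
        if axis == 0:
            a, b = sub[:-1, :], sub[1:, :]
            ina, inb = inside[:-1, :], inside[1:, :]
            deep_pair = deep[:-1, :] & deep[1:, :]
        else:
            a, b = sub[:, :-1], sub[:, 1:]
            ina, inb = inside[:, :-1], inside[:, 1:]
            deep_pair = deep[:, :-1] & deep[:, 1:]
        diff = ina & inb & (a != b)
        if not np.any(diff):
            continue
        total += float(np.count_nonzero(diff & deep_pair)) * cell
        rows, cols = np.nonzero(diff & ~deep_pair)
        if rows.size:
            if axis == 0:
                # shared edge between cell (r, c) and (r+1, c): horizontal
                x0 = xs[cols] - half; x1 = xs[cols] + half
                y0 = y1 = ys[rows] - half
            else:
                x0 = x1 = xs[cols] + half
                y0 = ys[rows] - half; y1 = ys[rows] + half
            segs = shapely.linestrings(
                np.stack([np.stack([x0, y0], axis=1), np.stack([x1, y1], axis=1)], axis=1)
            )
            clipped = shapely.intersection(segs, island.geometry)
            total += float(np.sum(shapely.length(clipped)))
    return total


def habitat_diversity_index(tp: float, area: float) -> float:
    """HDI = TP / (2*sqrt(pi*A)); 1.0 for a homogeneous circular island."""
    if tp <= 0 or area <= 0:
        raise ValueError("total perimeter and area must be positive")
    return float(tp / (2.0 * math.sqrt(math.pi * area)))


def heterogeneity_table(
    islands: list[IslandPolygon],
    terrain: TerrainStack,
    rules: HabitatRules = HabitatRules(),
) -> pd.DataFrame:
    """Per-island TP, HDI and habitat counts (columns island_id, tp_m, hdi,
    n_habitats)."""
    rows = []
    for isl in islands:
        hmap = classify_habitats(isl, terrain, rules)
        tp = total_perimeter(hmap)
        rows.append(
            {
                "island_id": isl.id,
                "tp_m": tp,
                "hdi": habitat_diversity_index(tp, isl.geometry.area),
                "n_habitats": hmap.n_habitats(),
            }
        )
    return pd.DataFrame(rows)
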