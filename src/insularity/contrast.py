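"""The matrix contrast index: classified-NDVI density in a buffer ring.

The index quantifies how strongly an island's surroundings contrast with
the island itself: NDVI is computed from red/NIR reflectance, classified
into five ordinal units with Jenks natural breaks (Fisher's optimal
1-D partitioning), and for each island the class values of all cells whose
centres fall in a 50 m buffer ring around the island are summed and
divided by the ring area.  High values mean the island is surrounded by
dense matrix vegetation — a potential dispersal barrier for the
light-demanding, short-distance-dispersing island flora; low values an
open vicinity.

Breaks are computed once over the whole scene (subsampled with a fixed
seed for large rasters) so the index is comparable across islands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from .geometry import Archipelago, IslandPolygon
from .raster import RasterGrid

__all__ = [
    "compute_ndvi",
    "jenks_breaks",
    "classify_values",
    "classify_grid",
    "scene_breaks",
    "buffer_ring",
    "matrix_contrast_index",
    "matrix_contrast_table",
    "MatrixContrastRecord",
]

DEFAULT_BUFFER_WIDTH = 50.0
DEFAULT_N_CLASSES = 5
_QUAD_SEGS = 64  # buffer arc resolution; ring areas exact to ~0.05%


def compute_ndvi(red: RasterGrid, nir: RasterGrid) -> RasterGrid:
    """(NIR − red) / (NIR + red) per cell; NaN where either band is nodata
    or the denominator is zero."""
    red.require_same_grid(nir, "red and NIR bands")
    r = red.values.astype(float)
    n = nir.values.astype(float)
    denom = n + r
    valid = red.mask() & nir.mask() & (denom != 0)
    out = np.full(r.shape, np.nan)
    out[valid] = (n[valid] - r[valid]) / denom[valid]
    return red.copy_with(out)


def jenks_breaks(values, k: int = DEFAULT_N_CLASSES) -> np.ndarray:
    """Jenks natural breaks: the k-class partition of sorted 1-D data that
    minimises the total within-class sum of squared deviations (Fisher's
    optimal partitioning, exact dynamic programme).

    Returns the k−1 interior thresholds, each the largest value of its
    class; strictly increasing.  Requires at least k distinct values.
    """
    x = np.sort(np.asarray(values, dtype=float).ravel())
    if x.size == 0 or np.isnan(x).any():
        raise ValueError("jenks_breaks needs non-empty, non-NaN data")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return np.empty(0)
    distinct = np.unique(x)
    if distinct.size < k:
        raise ValueError(f"need at least {k} distinct values for {k} classes")

    n = x.size
    S = np.concatenate([[0.0], np.cumsum(x)])
    S2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def seg_cost(i: np.ndarray, j: int) -> np.ndarray:
        # within-segment SSD for x[i..j] inclusive, vectorised over i
        m = j - i + 1
        s = S[j + 1] - S[i]
        return (S2[j + 1] - S2[i]) - s * s / m

    INF = np.inf
    cost = np.empty((k + 1, n))
    arg = np.zeros((k + 1, n), dtype=np.int64)
    cost[1, :] = S2[1:] - S[1:] ** 2 / (np.arange(n) + 1)
    for c in range(2, k + 1):
        cost[c, : c - 1] = INF
        for j in range(c - 1, n):
            i = np.arange(c - 1, j + 1)
            tot = cost[c - 1, i - 1] + seg_cost(i, j)
            best = int(np.argmin(tot))
            cost[c, j] = tot[best]
            arg[c, j] = i[best]
    # backtrack class boundaries
    breaks = []
    j = n - 1
    for c in range(k, 1, -1):
        i = arg[c, j]
        breaks.append(x[i - 1])  # last value of the previous class
        j = i - 1
    return np.array(breaks[::-1])


def classify_values(values: np.ndarray, breaks: np.ndarray) -> np.ndarray:
    """Ordinal class 1..k per value: class c contains values ≤ break c and
    above break c−1, so higher values never get a lower class."""
    v = np.asarray(values, dtype=float)
    return (np.searchsorted(np.asarray(breaks), v, side="left") + 1).astype(np.int64)


def scene_breaks(
    ndvi: RasterGrid,
    k: int = DEFAULT_N_CLASSES,
    max_sample: int = 10_000,
    seed: int = 0,
) -> np.ndarray:
    """Jenks breaks over all valid scene cells, subsampled without
    replacement to ``max_sample`` cells (seeded) when the scene is larger."""
    vals = ndvi.values[ndvi.mask()]
    if vals.size > max_sample:
        rng = np.random.default_rng(seed)
        vals = rng.choice(vals, size=max_sample, replace=False)
    return jenks_breaks(vals, k)


def classify_grid(ndvi: RasterGrid, breaks: np.ndarray) -> RasterGrid:
    """Classified scene: class 1..k per valid cell, NaN elsewhere."""
    out = np.full(ndvi.shape, np.nan)
    m = ndvi.mask()
    out[m] = classify_values(ndvi.values[m], breaks)
    return ndvi.copy_with(out)


def buffer_ring(island: IslandPolygon, width: float = DEFAULT_BUFFER_WIDTH) -> BaseGeometry:
    """The annulus tracing the island outline at distance ``width``:
    (island dilated by width) minus the island itself."""
    if width <= 0:
        raise ValueError("buffer width must be positive")
    return island.geometry.buffer(width, quad_segs=_QUAD_SEGS).difference(island.geometry)


@dataclass(frozen=True)
class MatrixContrastRecord:
    island_id: str
    buffer_area: float
    class_sum: float
    index: float


def matrix_contrast_index(
    cgrid: RasterGrid,
    ring: BaseGeometry,
    island_id: str = "",
    exclude: BaseGeometry | None = None,
) -> MatrixContrastRecord:
    """Sum of cell values (class ranks, or raw NDVI if a raw grid is
    passed) over cells whose centres fall in the ring, divided by the ring
    area.

    ``exclude`` optionally masks out parts of the ring (e.g. other islands'
    pixels) from the sum; the divisor stays the full ring area so islands
    remain comparable.
    """
    if ring.is_empty or ring.area <= 0:
        raise ValueError("buffer ring has zero area")
    xs, ys = cgrid.cell_centers()
    xmin, ymin, xmax, ymax = ring.bounds
    ci = np.nonzero((xs >= xmin - cgrid.cell) & (xs <= xmax + cgrid.cell))[0]
    ri = np.nonzero((ys >= ymin - cgrid.cell) & (ys <= ymax + cgrid.cell))[0]
    if ci.size == 0 or ri.size == 0:
        raise ValueError("ring lies outside the classified raster")
    X, Y = np.meshgrid(xs[ci], ys[ri])
    inside = shapely.contains_xy(ring, X.ravel(), Y.ravel()).reshape(X.shape)
    if exclude is not None:
        inside &= ~shapely.contains_xy(exclude, X.ravel(), Y.ravel()).reshape(X.shape)
    sub = cgrid.values[np.ix_(ri, ci)]
    valid = inside & ~np.isnan(sub)
    if not np.any(valid):
        raise ValueError(f"no valid cells in the buffer ring of island {island_id!r}")
    class_sum = float(np.sum(sub[valid]))
    return MatrixContrastRecord(island_id, float(ring.area), class_sum, class_sum / ring.area)


def matrix_contrast_table(
    cgrid: RasterGrid,
    arch: Archipelago,
    width: float = DEFAULT_BUFFER_WIDTH,
    mask_other_islands: bool = False,
) -> pd.DataFrame:
    """Matrix contrast for every sampled island (columns island_id,
    buffer_area_m2, class_sum, matrix_contrast).

    By default pixels of neighbouring islands inside a ring count as part
    of the focal island's surroundings; ``mask_other_islands`` excludes
    them."""
    rows = []
    for isl in arch.sampled():
        ring = buffer_ring(isl, width)
        exclude = None
        if mask_other_islands:
            others = [o.geometry for o in arch if o.id != isl.id]
            exclude = shapely.union_all(others)
        rec = matrix_contrast_index(cgrid, ring, isl.id, exclude=exclude)
        rows.append(
            {
                "island_id": rec.island_id,
                "buffer_area_m2": rec.buffer_area,
                "class_sum": rec.class_sum,
                "matrix_contrast": rec.index,
            }
        )
    return pd.DataFrame(rows)
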