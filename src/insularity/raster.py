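"""Lightweight georeferenced single-band raster grids.

A :class:`RasterGrid` couples a 2-D numpy array with a north-up affine
geotransform (origin, square cell size) and a nodata sentinel.  Rows run
north to south (row 0 is the top of the scene), matching the usual raster
convention.  Grids serialise to/from the ESRI ASCII grid format (``.asc``),
a plain-text interchange format readable by every GIS.

Cell-centre convention: the value at ``[row, col]`` is located at
``x = xllcorner + (col + 0.5) * cell``, ``y = yllcorner + (nrows - row - 0.5)
* cell``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["RasterGrid", "read_ascii_grid", "write_ascii_grid"]

_DEFAULT_NODATA = -9999.0


@dataclass
class RasterGrid:
    """Single-band raster: values + geotransform + nodata mask."""

    values: np.ndarray
    xll: float
    yll: float
    cell: float
    nodata: float = _DEFAULT_NODATA
    crs: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell <= 0:
            raise ValueError("cell size must be positive")

    # -- geometry ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid's outer edges."""
        nrows, ncols = self.shape
        return (
            self.xll,
            self.yll,
            self.xll + ncols * self.cell,
            self.yll + nrows * self.cell,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """1-D arrays of x (per column) and y (per row, top-down) centres."""
        nrows, ncols = self.shape
        xs = self.xll + (np.arange(ncols) + 0.5) * self.cell
        ys = self.yll + (nrows - np.arange(nrows) - 0.5) * self.cell
        return xs, ys

    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds valid data."""
        v = self.values
        valid = ~np.isnan(v) if np.issubdtype(v.dtype, np.floating) else np.ones(v.shape, bool)
        return valid & (v != self.nodata)

    def same_grid(self, other: "RasterGrid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.xll - other.xll) <= tol
            and abs(self.yll - other.yll) <= tol
            and abs(self.cell - other.cell) <= tol
        )

    def require_same_grid(self, other: "RasterGrid", what: str = "rasters") -> None:
        if not self.same_grid(other):
            raise ValueError(f"{what} are not co-registered (shape/origin/cell mismatch)")

    def index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cells containing points (x, y)."""
        nrows, _ = self.shape
        col = np.floor((np.asarray(x) - self.xll) / self.cell).astype(int)
        row = nrows - 1 - np.floor((np.asarray(y) - self.yll) / self.cell).astype(int)
        return row, col

    def window(self, xmin: float, ymin: float, xmax: float, ymax: float) -> "RasterGrid":
        """Clip to the cells whose extent intersects the given bounds."""
        nrows, ncols = self.shape
        c0 = max(int(np.floor((xmin - self.xll) / self.cell)), 0)
        c1 = min(int(np.ceil((xmax - self.xll) / self.cell)), ncols)
        r_bot = max(int(np.floor((ymin - self.yll) / self.cell)), 0)
        r_top = min(int(np.ceil((ymax - self.yll) / self.cell)), nrows)
        r0 = nrows - r_top
        r1 = nrows - r_bot
        if r0 >= r1 or c0 >= c1:
            raise ValueError("window does not intersect raster extent")
        return RasterGrid(
            self.values[r0:r1, c0:c1],
            xll=self.xll + c0 * self.cell,
            yll=self.yll + r_bot * self.cell,
            cell=self.cell,
            nodata=self.nodata,
            crs=self.crs,
        )

    def copy_with(self, values: np.ndarray) -> "RasterGrid":
        if values.shape != self.shape:
            raise ValueError("replacement values have a different shape")
        return RasterGrid(values, self.xll, self.yll, self.cell, self.nodata, self.crs)


def write_ascii_grid(grid: RasterGrid, path: str | Path, fmt: str = "%.6g") -> None:
    """Write an ESRI ASCII grid (.asc). NaNs are written as the nodata value."""
    v = np.array(grid.values, dtype=float, copy=True)
    v[~grid.mask()] = grid.nodata
    nrows, ncols = v.shape
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {grid.xll!r}\n"
        f"yllcorner {grid.yll!r}\n"
        f"cellsize {grid.cell!r}\n"
        f"NODATA_value {grid.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, v, fmt=fmt)


def read_ascii_grid(path: str | Path, crs: str | None = None) -> RasterGrid:
    """Read an ESRI ASCII grid. Nodata cells become NaN."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        values = np.loadtxt(fh)
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"ASCII grid {path}: missing header field {key}")
    values = np.atleast_2d(values)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"ASCII grid {path}: data shape does not match header")
    nodata = header.get("nodata_value", _DEFAULT_NODATA)
    values = values.astype(float)
    values[values == nodata] = np.nan
    return RasterGrid(values, header["xllcorner"], header["yllcorner"], header["cellsize"], nodata, crs)


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False
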