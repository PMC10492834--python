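"""Georeferenced single-band grids and their on-disk text representation.

Rasters are stored as ESRI ASCII grids (``.asc``): a six-line header
(ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value) followed by the cell
values row-major from the top row down. Values are written with ``%.17g`` so a
write/read round trip is bit-exact for float64. The CRS label travels in an
optional ``.prj`` sidecar and is treated as an opaque string.

Internally the origin is the UPPER-LEFT corner (row 0 is the northernmost
row), cell centres sit at ``origin + (index + 0.5) * cell_size``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np

from .errors import InvalidArgumentError

DEFAULT_NODATA = -9999.0


@dataclass
class RasterGrid:
    values: np.ndarray  # 2-D float array, row 0 = top
    origin: Tuple[float, float] = (0.0, 0.0)  # upper-left corner (x, y)
    cell_size: float = 1.0
    nodata: float = DEFAULT_NODATA
    crs: str = "EPSG:3006"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidArgumentError("raster values must be a 2-D array")
        if self.cell_size <= 0:
            raise InvalidArgumentError("cell size must be positive")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds data."""
        return self.values != self.nodata

    def data(self) -> np.ndarray:
        """Values with nodata replaced by NaN."""
        out = self.values.copy()
        out[~self.mask] = np.nan
        return out

    def cell_of(self, x: float, y: float) -> Tuple[int, int]:
        """(row, col) of the cell containing map point (x, y)."""
        col = int(np.floor((x - self.origin[0]) / self.cell_size))
        row = int(np.floor((self.origin[1] - y) / self.cell_size))
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise InvalidArgumentError(f"point ({x}, {y}) falls outside the raster")
        return row, col

    def value_at(self, x: float, y: float) -> float:
        r, c = self.cell_of(x, y)
        return float(self.values[r, c])

    def aligned_with(self, other: "RasterGrid") -> bool:
        return (
            self.values.shape == other.values.shape
            and self.origin == other.origin
            and self.cell_size == other.cell_size
        )


def write_raster(grid: RasterGrid, path) -> None:
    """Write an ESRI ASCII grid (+ ``.prj`` sidecar when a CRS is set)."""
    path = Path(path)
    yll = grid.origin[1] - grid.n_rows * grid.cell_size
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.origin[0]!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        for row in grid.values:
            fh.write(" ".join("%.17g" % v for v in row))
            fh.write("\n")
    if grid.crs:
        path.with_suffix(".prj").write_text(grid.crs + "\n")


def read_raster(path) -> RasterGrid:
    """Read an ESRI ASCII grid written by :func:`write_raster`."""
    path = Path(path)
    header = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, val = line.strip().partition(" ")
            key = key.lower()
            if key not in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
                raise InvalidArgumentError(f"{path}: unexpected header line {line!r}")
            header[key] = val.strip()
        values = np.loadtxt(fh, dtype=float, ndmin=2)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if values.shape != (nrows, ncols):
        raise InvalidArgumentError(
            f"{path}: grid is {values.shape}, header says ({nrows}, {ncols})"
        )
    cell = float(header["cellsize"])
    origin = (float(header["xllcorner"]), float(header["yllcorner"]) + nrows * cell)
    prj = path.with_suffix(".prj")
    crs = prj.read_text().strip() if prj.exists() else ""
    return RasterGrid(
        values=values,
        origin=origin,
        cell_size=cell,
        nodata=float(header["nodata_value"]),
        crs=crs,
    )
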