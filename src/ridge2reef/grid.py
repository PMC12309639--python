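"""Gridded raster container shared by every pipeline stage.

A :class:`Grid` is a single-band raster: a 2-D array of values, a square
cell size in metres, the coordinate of the outer corner of cell (0, 0),
and a boolean no-data mask. Rows increase southward (row 0 is the
northern edge), matching the usual raster convention. Cell centres sit at
``origin + (index + 0.5) * cell_size`` along each axis.

Grids serialize to the ESRI ASCII grid format (plain text), readable by
any GIS.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["Grid", "read_ascii_grid", "write_ascii_grid"]

_NODATA = -9999.0


@dataclass
class Grid:
    """Single-band raster with a no-data mask.

    Parameters
    ----------
    values
        2-D array of cell values (float or integer).
    cell_size_m
        Side length of the square cells in metres; must be positive.
    origin
        ``(x, y)`` of the outer corner of cell ``(0, 0)`` — the
        north-west corner of the raster.
    nodata_mask
        Boolean array, same shape as ``values``; True marks no-data.
    crs_label
        Free-text description of the coordinate system.
    """

    values: np.ndarray
    cell_size_m: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_mask: np.ndarray | None = None
    crs_label: str = "local-metric"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("Grid values must be 2-D")
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be > 0")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise ValueError("nodata_mask shape must match values shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size_m / 1000.0) ** 2

    def cell_center(self, row: int | np.ndarray, col: int | np.ndarray):
        """Map (row, col) indices to (x, y) cell-centre coordinates."""
        x = self.origin[0] + (np.asarray(col) + 0.5) * self.cell_size_m
        y = self.origin[1] - (np.asarray(row) + 0.5) * self.cell_size_m
        return x, y

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Map a coordinate to the containing cell's (row, col)."""
        col = int(np.floor((x - self.origin[0]) / self.cell_size_m))
        row = int(np.floor((self.origin[1] - y) / self.cell_size_m))
        return row, col

    def valid(self) -> np.ndarray:
        return ~self.nodata_mask

    def like(self, values: np.ndarray, nodata_mask: np.ndarray | None = None) -> "Grid":
        """New grid sharing this grid's geometry."""
        mask = self.nodata_mask.copy() if nodata_mask is None else nodata_mask
        return Grid(np.asarray(values), self.cell_size_m, self.origin, mask, self.crs_label)

    def copy(self) -> "Grid":
        return replace(self, values=self.values.copy(), nodata_mask=self.nodata_mask.copy())


def write_ascii_grid(grid: Grid, path: str | Path) -> None:
    """Write a grid as an ESRI ASCII raster (text)."""
    path = Path(path)
    vals = np.array(grid.values, dtype=float)
    vals[grid.nodata_mask] = _NODATA
    nrows, ncols = vals.shape
    # ESRI convention: xllcorner/yllcorner are the lower-left outer corner.
    xll = grid.origin[0]
    yll = grid.origin[1] - nrows * grid.cell_size_m
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {xll:.6f}\n"
        f"yllcorner {yll:.6f}\n"
        f"cellsize {grid.cell_size_m:.6f}\n"
        f"NODATA_value {_NODATA:.1f}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.8g")


def read_ascii_grid(path: str | Path, crs_label: str = "local-metric") -> Grid:
    """Read an ESRI ASCII raster written by :func:`write_ascii_grid`."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh)
    vals = np.atleast_2d(vals)
    nodata = header.get("nodata_value", _NODATA)
    mask = vals == nodata
    cell = header["cellsize"]
    nrows = int(header["nrows"])
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cell)
    return Grid(vals, cell, origin, mask, crs_label)
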