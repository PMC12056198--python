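"""Minimal single-band raster container with plain-text (Esri ASCII grid) I/O.

Grids here are small synthetic surfaces on a regular geographic lattice with
square cells; rows are stored north-to-south as in the ASCII grid convention.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

__all__ = ["Raster", "read_ascii_grid", "write_ascii_grid"]


@dataclass
class Raster:
    """A single-band raster on a regular lon/lat grid.

    Attributes
    ----------
    data : 2D array, row 0 = northernmost row.
    xll, yll : lower-left corner of the grid (degrees).
    cellsize : cell edge in degrees (square cells).
    nodata : value marking missing cells.
    """

    data: np.ndarray
    xll: float
    yll: float
    cellsize: float
    nodata: float = -9999.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def same_grid(self, other: "Raster", tol: float = 1e-9) -> bool:
        return (
            self.data.shape == other.data.shape
            and abs(self.xll - other.xll) <= tol
            and abs(self.yll - other.yll) <= tol
            and abs(self.cellsize - other.cellsize) <= tol
        )

    def geotransform(self) -> tuple[float, float, float, float]:
        """(xll, yll, cellsize, cellsize) — enough to report grid mismatches."""
        return (self.xll, self.yll, self.cellsize, self.cellsize)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of cell-centre coordinates, matching ``data``."""
        nrow, ncol = self.data.shape
        lon = self.xll + (np.arange(ncol) + 0.5) * self.cellsize
        lat = self.yll + (nrow - np.arange(nrow) - 0.5) * self.cellsize
        return np.meshgrid(lon, lat)

    def index_of(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/column indices of the cells containing the given coordinates."""
        nrow, _ = self.data.shape
        col = np.floor((np.asarray(lon) - self.xll) / self.cellsize).astype(int)
        row_from_bottom = np.floor((np.asarray(lat) - self.yll) / self.cellsize).astype(int)
        return nrow - 1 - row_from_bottom, col


def write_ascii_grid(raster: Raster, path: str | os.PathLike) -> None:
    """Write a :class:`Raster` as an Esri ASCII grid (plain text)."""
    nrow, ncol = raster.data.shape
    header = (
        f"ncols {ncol}\n"
        f"nrows {nrow}\n"
        f"xllcorner {raster.xll!r}\n"
        f"yllcorner {raster.yll!r}\n"
        f"cellsize {raster.cellsize!r}\n"
        f"NODATA_value {raster.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, raster.data, fmt="%g")


def read_ascii_grid(path: str | os.PathLike) -> Raster:
    """Read an Esri ASCII grid written by :func:`write_ascii_grid`."""
    meta: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            meta[key.lower()] = float(value)
        data = np.loadtxt(fh, ndmin=2)
    if data.shape != (int(meta["nrows"]), int(meta["ncols"])):
        raise ValueError(
            f"grid body {data.shape} does not match header "
            f"({int(meta['nrows'])}, {int(meta['ncols'])})"
        )
    return Raster(
        data=data,
        xll=meta["xllcorner"],
        yll=meta["yllcorner"],
        cellsize=meta["cellsize"],
        nodata=meta.get("nodata_value", -9999.0),
    )
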