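"""North-up geographic grids and plain-text (ESRI ASCII) raster I/O.

Cells are addressed by ``(row, col)`` with row 0 the northernmost row; a
cell covers the half-open box ``[west, east) x (south, north]``. Grids are
snapped to the global lattice aligned to integer degrees so that results do
not depend on data layout. 30 arc-second cells (the working resolution for
diversity rasters) are ``1/120`` degree.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

#: 30 arc seconds in decimal degrees
CELL_30_ARCSEC = 1.0 / 120.0


@dataclass(frozen=True)
class Grid:
    """Geometry of a north-up regular lon/lat grid."""

    west: float
    north: float
    cell_size: float
    nrows: int
    ncols: int

    @classmethod
    def snapped(
        cls, west: float, south: float, east: float, north: float, cell_size: float
    ) -> "Grid":
        """Smallest lattice-aligned grid covering the given bounds."""
        w = np.floor(west / cell_size) * cell_size
        n = np.ceil(north / cell_size) * cell_size
        ncols = int(np.ceil((east - w) / cell_size - 1e-9)) or 1
        nrows = int(np.ceil((n - south) / cell_size - 1e-9)) or 1
        return cls(west=float(w), north=float(n), cell_size=cell_size,
                   nrows=nrows, ncols=ncols)

    # ------------------------------------------------------------------
    @property
    def east(self) -> float:
        return self.west + self.ncols * self.cell_size

    @property
    def south(self) -> float:
        return self.north - self.nrows * self.cell_size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def cell_center(self, row, col):
        """(lon, lat) of cell centers; accepts scalars or arrays."""
        lon = self.west + (np.asarray(col) + 0.5) * self.cell_size
        lat = self.north - (np.asarray(row) + 0.5) * self.cell_size
        return lon, lat

    def index_of(self, lon, lat):
        """(row, col) of the cell containing each point."""
        col = np.floor((np.asarray(lon) - self.west) / self.cell_size).astype(int)
        row = np.floor((self.north - np.asarray(lat)) / self.cell_size).astype(int)
        # points exactly on the northern/western edge belong to the first cell
        return np.clip(row, 0, self.nrows - 1), np.clip(col, 0, self.ncols - 1)

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays of shape (nrows, ncols) of center lon and lat."""
        cols, rows = np.meshgrid(np.arange(self.ncols), np.arange(self.nrows))
        return self.cell_center(rows, cols)


@dataclass
class Raster:
    """A single-band grid of float values with explicit no-data."""

    grid: Grid
    values: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    def mask(self) -> np.ndarray:
        """True where the cell holds data."""
        return ~(np.isnan(self.values) | (self.values == self.nodata))


def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    """Write a raster as an ESRI ASCII grid (plain text, georeferenced)."""
    g = raster.grid
    vals = np.where(np.isnan(raster.values), raster.nodata, raster.values)
    header = (
        f"ncols {g.ncols}\n"
        f"nrows {g.nrows}\n"
        f"xllcorner {g.west!r}\n"
        f"yllcorner {g.south!r}\n"
        f"cellsize {g.cell_size!r}\n"
        f"NODATA_value {raster.nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    meta: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, val = line.partition(" ")
            key = key.strip().lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value"}:
                meta[key] = float(val)
                pos = fh.tell()
            else:  # optional NODATA line absent
                break
        fh.seek(pos)
        values = np.loadtxt(fh, ndmin=2)
    nrows, ncols = int(meta["nrows"]), int(meta["ncols"])
    if values.shape != (nrows, ncols):
        raise ValueError(f"{path}: data block shape {values.shape} does not "
                         f"match header ({nrows}, {ncols})")
    cs = meta["cellsize"]
    grid = Grid(west=meta["xllcorner"], north=meta["yllcorner"] + nrows * cs,
                cell_size=cs, nrows=nrows, ncols=ncols)
    nodata = meta.get("nodata_value", -9999.0)
    vals = np.where(values == nodata, np.nan, values)
    return Raster(grid=grid, values=vals, nodata=nodata)
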