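"""Regular-grid raster container and ESRI ASCII grid I/O.

A :class:`Raster` is a single-band grid of floats with square cells. Row 0 of
``values`` is the northernmost row, matching the on-disk layout of the ESRI
ASCII format. Masked (nodata) cells are stored as NaN in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import FormatError, ParameterError

__all__ = ["Raster", "read_ascii_grid", "write_ascii_grid"]


@dataclass
class Raster:
    """Single-band raster with square cells.

    Parameters
    ----------
    values
        2-D float array; NaN marks nodata cells. Row 0 is the top (north) row.
    cell_size
        Cell edge length in map units (meters).
    origin
        ``(x, y)`` of the lower-left corner of the grid.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = field(default=-9999.0, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ParameterError("raster values must be a 2-D array")
        if self.cell_size <= 0:
            raise ParameterError("cell_size must be positive")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell is nodata."""
        return np.isnan(self.values)

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(~self.mask))

    def with_values(self, values: np.ndarray) -> "Raster":
        """Return a new raster on the same grid with different values."""
        values = np.asarray(values, dtype=float)
        if values.shape != self.values.shape:
            raise ParameterError("replacement values must keep the grid shape")
        return replace(self, values=values)

    def copy(self) -> "Raster":
        return replace(self, values=self.values.copy())

    # -- coordinate helpers -------------------------------------------------

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Map coordinates of the center of cell ``(row, col)``."""
        x = self.origin[0] + (col + 0.5) * self.cell_size
        y = self.origin[1] + (self.nrows - row - 0.5) * self.cell_size
        return x, y

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Grid indices of the cell containing map point ``(x, y)``."""
        col = int(np.floor((x - self.origin[0]) / self.cell_size))
        row = self.nrows - 1 - int(np.floor((y - self.origin[1]) / self.cell_size))
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise ParameterError(f"point ({x}, {y}) falls outside the raster extent")
        return row, col

    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid."""
        x0, y0 = self.origin
        return x0, y0, x0 + self.ncols * self.cell_size, y0 + self.nrows * self.cell_size


def read_ascii_grid(path: str | Path) -> Raster:
    """Read a single-band ESRI ASCII grid.

    Accepts ``xllcorner``/``yllcorner`` or the cell-center variants; the
    ``NODATA_value`` line is optional.
    """
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        pos = fh.tell()
        n_header = 0
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner",
                "xllcenter", "yllcenter", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
                n_header += 1
            else:
                fh.seek(pos)
                break
        body = np.loadtxt(fh, ndmin=2)
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise FormatError(f"{path}: missing required header line '{key}'")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if body.shape != (nrows, ncols):
        raise FormatError(
            f"{path}: body is {body.shape}, header says ({nrows}, {ncols})"
        )
    cell = header["cellsize"]
    if "xllcorner" in header:
        x0, y0 = header["xllcorner"], header["yllcorner"]
    elif "xllcenter" in header:
        x0, y0 = header["xllcenter"] - cell / 2, header["yllcenter"] - cell / 2
    else:
        x0 = y0 = 0.0
    nodata = header.get("nodata_value", -9999.0)
    values = body.astype(float)
    values[values == nodata] = np.nan
    return Raster(values=values, cell_size=cell, origin=(x0, y0), nodata=nodata)


def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    """Write a raster as an ESRI ASCII grid (nodata cells as the nodata code)."""
    path = Path(path)
    vals = raster.values.copy()
    vals[np.isnan(vals)] = raster.nodata
    with path.open("w") as fh:
        fh.write(f"ncols {raster.ncols}\n")
        fh.write(f"nrows {raster.nrows}\n")
        fh.write(f"xllcorner {raster.origin[0]:.6f}\n")
        fh.write(f"yllcorner {raster.origin[1]:.6f}\n")
        fh.write(f"cellsize {raster.cell_size:.6f}\n")
        fh.write(f"NODATA_value {raster.nodata}\n")
        for row in vals:
            fh.write(" ".join(format(v, ".10g") for v in row) + "\n")
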