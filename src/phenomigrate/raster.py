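"""Minimal georeferenced raster container with ESRI ASCII-grid I/O.

Grids are stored row-major with row 0 at the *top* (north), matching the
ASCII-grid convention.  The geotransform is axis-aligned: an origin
(x of the left edge, y of the top edge) plus a square cell size.  Units
are whatever the coordinate frame uses (metres for the synthetic local
frames, degrees for EPSG:4326 exports).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np


@dataclass
class Raster:
    """A single-band 2-D grid with an axis-aligned geotransform."""

    data: np.ndarray
    x_origin: float = 0.0
    y_origin: float = 0.0
    cell_size: float = 10.0
    nodata: float = -9999
    crs: str = "local-metres"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid footprint."""
        nrows, ncols = self.data.shape
        return (
            self.x_origin,
            self.y_origin - nrows * self.cell_size,
            self.x_origin + ncols * self.cell_size,
            self.y_origin,
        )

    def cell_of(self, x: float, y: float) -> tuple[int, int] | None:
        """(row, col) containing the point, or None if outside."""
        col = int(np.floor((x - self.x_origin) / self.cell_size))
        row = int(np.floor((self.y_origin - y) / self.cell_size))
        nrows, ncols = self.data.shape
        if 0 <= row < nrows and 0 <= col < ncols:
            return row, col
        return None

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (X, Y) of cell-centre coordinates, shaped like data."""
        nrows, ncols = self.data.shape
        xs = self.x_origin + (np.arange(ncols) + 0.5) * self.cell_size
        ys = self.y_origin - (np.arange(nrows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def copy_with(self, data: np.ndarray) -> "Raster":
        return replace(self, data=np.asarray(data))


def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    """Write as an ESRI ASCII grid (plain text, widely readable)."""
    nrows, ncols = raster.data.shape
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {raster.x_origin}\n"
        f"yllcorner {raster.y_origin - nrows * raster.cell_size}\n"
        f"cellsize {raster.cell_size}\n"
        f"NODATA_value {raster.nodata}\n"
    )
    body = "\n".join(
        " ".join(format(v, "g") for v in row) for row in raster.data
    )
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path: str | Path, *, crs: str = "local-metres") -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    lines = Path(path).read_text().splitlines()
    hdr: dict[str, float] = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in (
        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
    ):
        key, val = lines[i].split()
        hdr[key.lower()] = float(val)
        i += 1
    data = np.loadtxt(lines[i:])
    data = np.atleast_2d(data)
    nrows = int(hdr["nrows"])
    if data.shape[0] != nrows:
        raise ValueError("row count mismatch in ASCII grid")
    cell = hdr["cellsize"]
    return Raster(
        data=data,
        x_origin=hdr["xllcorner"],
        y_origin=hdr["yllcorner"] + nrows * cell,
        cell_size=cell,
        nodata=hdr.get("nodata_value", -9999),
        crs=crs,
    )
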