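"""Minimal ESRI-ASCII grid raster I/O.

The elevation model is exchanged as a plain-text grid: a six-line header
(ncols, nrows, xllcorner, yllcorner, cellsize, NODATA_value) followed by
nrows lines of ncols values, the first line being the northernmost row.
Coordinates are planar (projected) units matching the stem table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["AsciiGrid", "read_ascii_grid", "write_ascii_grid"]


@dataclass
class AsciiGrid:
    values: np.ndarray  # (nrows, ncols); row 0 = northernmost
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata: float = -9999.0

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def cell_bounds(self, row: int, col: int) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of a cell; row 0 is the top (north)."""
        xmin = self.xllcorner + col * self.cellsize
        ymin = self.yllcorner + (self.nrows - 1 - row) * self.cellsize
        return xmin, ymin, xmin + self.cellsize, ymin + self.cellsize


def read_ascii_grid(path: str | Path) -> AsciiGrid:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"ESRI-ASCII header missing {key!r}")
    values = np.array(rows, dtype=float)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"grid body {values.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    return AsciiGrid(
        values=values,
        xllcorner=header["xllcorner"],
        yllcorner=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata=header.get("nodata_value", -9999.0),
    )


def write_ascii_grid(grid: AsciiGrid, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.xllcorner}\n")
        fh.write(f"yllcorner {grid.yllcorner}\n")
        fh.write(f"cellsize {grid.cellsize}\n")
        fh.write(f"NODATA_value {grid.nodata}\n")
        for row in grid.values:
            fh.write(" ".join(format(v, "g") for v in row) + "\n")
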