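"""Equal-area study grid and plain-text raster I/O.

The grid is a planar lattice of square cells (km units, x east, y north).
Cell (row 0, col 0) has its lower-left corner at ``origin``; cell ids are
row-major from that corner.  Cell extents are half-open, ``[x, x + s)`` in
both axes, so any point belongs to exactly one cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

NODATA = -9999.0


@dataclass
class StudyGrid:
    """Lattice of square cells with a sea mask and subregion labels.

    Attributes
    ----------
    origin : (float, float)
        Planar coordinate (km) of the lower-left corner of cell (0, 0).
    cell_size : float
        Cell edge length in km.
    sea_mask : ndarray of bool, shape (n_rows, n_cols)
        True where the cell is sea (part of the study area).
    subregion : ndarray of int, shape (n_rows, n_cols)
        Subregion label per sea cell (0-based); -1 on land.
    """

    origin: tuple[float, float]
    cell_size: float
    sea_mask: np.ndarray
    subregion: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sea_mask = np.asarray(self.sea_mask, dtype=bool)
        if self.sea_mask.ndim != 2:
            raise ValueError("sea_mask must be 2-D (n_rows, n_cols)")
        if self.subregion is None:
            self.subregion = np.where(self.sea_mask, 0, -1)
        self.subregion = np.asarray(self.subregion, dtype=int)
        if self.subregion.shape != self.sea_mask.shape:
            raise ValueError("subregion shape must match sea_mask")

    @property
    def n_rows(self) -> int:
        return self.sea_mask.shape[0]

    @property
    def n_cols(self) -> int:
        return self.sea_mask.shape[1]

    @property
    def n_cells(self) -> int:
        return self.sea_mask.size

    @property
    def n_sea(self) -> int:
        return int(self.sea_mask.sum())

    @property
    def cell_area(self) -> float:
        return self.cell_size ** 2

    @property
    def n_subregions(self) -> int:
        labels = self.subregion[self.sea_mask]
        return int(labels.max()) + 1 if labels.size else 0

    # -- cell id conventions -------------------------------------------------

    def cell_id(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        """Row-major cell id from (row, col)."""
        return np.asarray(row) * self.n_cols + np.asarray(col)

    def rowcol(self, cell_id: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cell_id = np.asarray(cell_id)
        return cell_id // self.n_cols, cell_id % self.n_cols

    def sea_cell_ids(self) -> np.ndarray:
        """Ids of sea cells in row-major order."""
        rows, cols = np.nonzero(self.sea_mask)
        return np.sort(self.cell_id(rows, cols))

    def locate(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the cell containing each point (half-open extents).

        Points outside the lattice get out-of-range indices; callers must
        bound-check (see :meth:`in_bounds`).
        """
        col = np.floor((np.asarray(x, dtype=float) - self.origin[0]) / self.cell_size).astype(int)
        row = np.floor((np.asarray(y, dtype=float) - self.origin[1]) / self.cell_size).astype(int)
        return row, col

    def in_bounds(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) centre coordinate arrays of shape (n_rows, n_cols)."""
        xs = self.origin[0] + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.origin[1] + (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def centre_of(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        x = self.origin[0] + (np.asarray(col) + 0.5) * self.cell_size
        y = self.origin[1] + (np.asarray(row) + 0.5) * self.cell_size
        return x, y


# -- ESRI ASCII grid I/O -----------------------------------------------------
#
# The classic plain-text raster dialect: a 6-line header followed by rows of
# values, top row first.  Internally row 0 is the *bottom* row (y increasing
# with row index), so rows are flipped on read and write.


def write_ascii_grid(path: str | Path, values: np.ndarray, origin: tuple[float, float],
                     cell_size: float, nodata: float = NODATA) -> None:
    """Write a 2-D array (row 0 = bottom) as an ESRI ASCII grid; NaN -> nodata."""
    values = np.asarray(values, dtype=float)
    out = np.where(np.isnan(values), nodata, values)
    header = (
        f"ncols {values.shape[1]}\n"
        f"nrows {values.shape[0]}\n"
        f"xllcorner {origin[0]}\n"
        f"yllcorner {origin[1]}\n"
        f"cellsize {cell_size}\n"
        f"NODATA_value {nodata}\n"
    )
    body = "\n".join(" ".join(repr(float(v)) for v in row) for row in out[::-1])
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, tuple[float, float], float]:
    """Read an ESRI ASCII grid; returns (values with NaN nodata, origin, cell_size)."""
    lines = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    rows = [np.array(line.split(), dtype=float) for line in lines[i:] if line.strip()]
    values = np.vstack(rows)[::-1]
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("ASCII grid body does not match header dimensions")
    nodata = header.get("nodata_value", NODATA)
    values = np.where(values == nodata, np.nan, values)
    return values, (header["xllcorner"], header["yllcorner"]), header["cellsize"]


def write_grid(grid: StudyGrid, directory: str | Path) -> None:
    """Write a StudyGrid as two ASCII rasters (sea mask and subregion labels)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_ascii_grid(directory / "sea_mask.asc", grid.sea_mask.astype(float),
                     grid.origin, grid.cell_size)
    sub = np.where(grid.sea_mask, grid.subregion.astype(float), np.nan)
    write_ascii_grid(directory / "subregion.asc", sub, grid.origin, grid.cell_size)


def read_grid(directory: str | Path) -> StudyGrid:
    directory = Path(directory)
    mask, origin, cs = read_ascii_grid(directory / "sea_mask.asc")
    sea = mask == 1.0
    subpath = directory / "subregion.asc"
    if subpath.exists():
        sub, _, _ = read_ascii_grid(subpath)
        subregion = np.where(np.isnan(sub), -1, sub).astype(int)
    else:
        subregion = None
    return StudyGrid(origin=origin, cell_size=cs, sea_mask=sea, subregion=subregion)
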