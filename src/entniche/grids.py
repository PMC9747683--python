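"""Grid, raster and environment-stack data model with ESRI ASCII I/O.

All geography is WGS84 decimal degrees. A :class:`GridSpec` describes a
north-up regular lon/lat grid; row 0 is the northernmost row. Cells are
half-open: a cell covers ``[west + c*d, west + (c+1)*d)`` in longitude and
``(north - (r+1)*d, north - r*d]`` in latitude, so a point on an east or
south boundary belongs to the next cell. Cell values refer to the whole
cell; coordinates are reported at cell centers.

Rasters carry their nodata as NaN in a float array, which propagates
naturally through arithmetic. Spherical-Earth geometry uses R = 6371 km
throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

#: Spherical Earth radius, km.
EARTH_RADIUS_KM = 6371.0

#: Metres per degree of latitude on the spherical Earth (pi * R / 180).
METRES_PER_DEGREE = 111_195.0


@dataclass(frozen=True)
class GridSpec:
    """A regular north-up WGS84 grid.

    Parameters
    ----------
    west, north
        Coordinates of the grid's north-west corner (degrees).
    cell_size
        Cell edge in arc-minutes (2.5 for the standard analysis grid).
    n_rows, n_cols
        Grid shape; row 0 is the northernmost row.
    """

    west: float
    north: float
    cell_size: float  # arc-minutes
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid shape must be positive")

    @property
    def cell_deg(self) -> float:
        """Cell edge in decimal degrees."""
        return self.cell_size / 60.0

    @property
    def south(self) -> float:
        return self.north - self.n_rows * self.cell_deg

    @property
    def east(self) -> float:
        return self.west + self.n_cols * self.cell_deg

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    # --- indexing ---------------------------------------------------------

    def cell_index(self, lon, lat):
        """Row/col of the cell containing each point (vectorised).

        Points outside the grid get index -1 in both row and col.
        Boundary convention: west/north edges inclusive, east/south edges
        belong to the neighbouring cell; the grid's own top edge is row 0
        and a point exactly on a row's top boundary belongs to that row.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        d = self.cell_deg
        col = np.floor((lon - self.west) / d).astype(int)
        # lat exactly on a cell's top boundary: (north - lat)/d integral -> that row
        fr = (self.north - lat) / d
        row = np.floor(fr).astype(int)
        on_boundary = (fr == np.floor(fr)) & (fr > 0)
        row = np.where(on_boundary, row - 1, row)
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        row = np.where(inside, row, -1)
        col = np.where(inside, col, -1)
        return row, col

    def cell_center(self, row, col):
        """Lon/lat of cell centers (vectorised)."""
        row = np.asarray(row)
        col = np.asarray(col)
        d = self.cell_deg
        lon = self.west + (col + 0.5) * d
        lat = self.north - (row + 0.5) * d
        return lon, lat

    def row_lats(self) -> np.ndarray:
        """Latitudes of row centers, north to south."""
        return self.north - (np.arange(self.n_rows) + 0.5) * self.cell_deg

    def cell_area_km2(self) -> np.ndarray:
        """Spherical area of one cell per row, km^2.

        A = R^2 * dlambda * (sin(phi_top) - sin(phi_bottom)) with dlambda
        the cell width in radians; identical for every cell of a row.
        """
        d = math.radians(self.cell_deg)
        top = np.radians(self.north - np.arange(self.n_rows) * self.cell_deg)
        bottom = top - d
        return EARTH_RADIUS_KM**2 * d * (np.sin(top) - np.sin(bottom))

    def area_raster(self) -> np.ndarray:
        """(n_rows, n_cols) array of per-cell spherical areas, km^2."""
        return np.repeat(self.cell_area_km2()[:, None], self.n_cols, axis=1)


@dataclass
class Raster:
    """A single grid-aligned layer; nodata stored as NaN."""

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"value array shape {self.values.shape} does not match "
                f"grid shape {self.grid.shape}"
            )

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of cells carrying data."""
        return ~np.isnan(self.values)

    def copy_with(self, values: np.ndarray) -> "Raster":
        return Raster(self.grid, np.array(values, dtype=float))

    def sample(self, lon, lat):
        """Values at the cells containing the given points (NaN outside)."""
        row, col = self.grid.cell_index(lon, lat)
        out = np.full(np.shape(row), np.nan)
        inside = row >= 0
        out[inside] = self.values[row[inside], col[inside]]
        return out


@dataclass
class EnvStack:
    """Named, grid-aligned raster layers for one period/GCM/scenario."""

    layers: dict[str, Raster]
    period: str = "current"
    gcm: str = ""
    scenario: str = ""

    def __post_init__(self) -> None:
        grids = {id(r.grid): r.grid for r in self.layers.values()}
        specs = list({(g.west, g.north, g.cell_size, g.n_rows, g.n_cols) for g in grids.values()})
        if len(specs) > 1:
            raise ValueError("all layers of a stack must share one grid")

    @property
    def grid(self) -> GridSpec:
        return next(iter(self.layers.values())).grid

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def subset(self, names: Iterable[str]) -> "EnvStack":
        names = list(names)
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"layers not in stack: {missing}")
        return EnvStack({n: self.layers[n] for n in names}, self.period, self.gcm, self.scenario)

    def joint_valid(self) -> np.ndarray:
        """Cells valid in every layer."""
        m = np.ones(self.grid.shape, dtype=bool)
        for r in self.layers.values():
            m &= r.valid
        return m

    def to_matrix(self, rows, cols, names: Iterable[str] | None = None) -> np.ndarray:
        """Extract an (n_cells, n_layers) covariate matrix at cell indices."""
        names = list(names) if names is not None else self.names
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        out = np.empty((rows.size, len(names)))
        for j, n in enumerate(names):
            out[:, j] = self.layers[n].values[rows, cols]
        return out

    def relabel(self, period=None, gcm=None, scenario=None) -> "EnvStack":
        return EnvStack(
            dict(self.layers),
            period if period is not None else self.period,
            gcm if gcm is not None else self.gcm,
            scenario if scenario is not None else self.scenario,
        )


# --- ESRI ASCII grid I/O --------------------------------------------------

_ASC_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def write_asc(raster: Raster, path: str | Path, nodata: float = -9999.0) -> None:
    """Write a raster as an ESRI ASCII grid.

    Values are printed with 9 significant digits, enough to round-trip
    float32 data bit-exactly.
    """
    g = raster.grid
    path = Path(path)
    vals = np.where(raster.valid, raster.values, nodata)
    with path.open("w") as fh:
        fh.write(f"NCOLS {g.n_cols}\n")
        fh.write(f"NROWS {g.n_rows}\n")
        fh.write(f"XLLCORNER {g.west:.17g}\n")
        fh.write(f"YLLCORNER {g.south:.17g}\n")
        fh.write(f"CELLSIZE {g.cell_deg:.17g}\n")
        fh.write(f"NODATA_VALUE {nodata:.9g}\n")
        for r in range(g.n_rows):
            fh.write(" ".join(f"{v:.9g}" for v in vals[r]) + "\n")


def read_asc(path: str | Path) -> Raster:
    """Read an ESRI ASCII grid written in the convention of :func:`write_asc`."""
    path = Path(path)
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with path.open() as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in _ASC_HEADER_KEYS and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                data_lines.append(line)
    missing = [k for k in _ASC_HEADER_KEYS[:5] if k not in header]
    if missing:
        raise ValueError(f"ESRI ASCII header missing keys: {missing} in {path}")
    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    cell_deg = header["cellsize"]
    nodata = header.get("nodata_value", -9999.0)
    values = np.loadtxt(data_lines, dtype=float).reshape(n_rows, n_cols)
    values = np.where(values == nodata, np.nan, values)
    # snap reconstructed origin/cell size to 1e-9 degrees (~0.1 mm) so a
    # write/read cycle reproduces the original GridSpec exactly
    grid = GridSpec(
        west=round(header["xllcorner"], 9),
        north=round(header["yllcorner"] + n_rows * cell_deg, 9),
        cell_size=round(cell_deg * 60.0, 9),
        n_rows=n_rows,
        n_cols=n_cols,
    )
    return Raster(grid, values)


def write_stack(stack: EnvStack, directory: str | Path) -> list[Path]:
    """Write every layer of a stack as ``<name>.asc`` under *directory*."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, raster in stack.layers.items():
        p = directory / f"{name}.asc"
        write_asc(raster, p)
        paths.append(p)
    return paths


def read_stack(directory: str | Path, period: str = "current", gcm: str = "",
               scenario: str = "") -> EnvStack:
    """Read all ``*.asc`` layers in *directory* into a stack."""
    directory = Path(directory)
    layers = {}
    for p in sorted(directory.glob("*.asc")):
        layers[p.stem] = read_asc(p)
    if not layers:
        raise FileNotFoundError(f"no .asc layers in {directory}")
    return EnvStack(layers, period=period, gcm=gcm, scenario=scenario)


def ensemble_mean(maps: list[Raster]) -> Raster:
    """Cellwise arithmetic mean of rasters on a shared grid.

    A cell is nodata in the mean iff it is nodata in any member, so
    multi-model ensembles share a common support.
    """
    if not maps:
        raise ValueError("ensemble_mean needs at least one raster")
    g0 = maps[0].grid
    for m in maps[1:]:
        if m.grid != g0:
            raise ValueError("ensemble members must share one grid")
    stack = np.stack([m.values for m in maps])
    # cellwise sort before the mean makes the result invariant to member
    # order at floating-point level; NaN sorts last and still propagates
    return Raster(g0, np.sort(stack, axis=0).mean(axis=0))
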