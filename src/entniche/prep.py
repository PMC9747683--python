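"""Layer preparation: resampling, paleo temperature rescaling, terrain.

These are the standard pre-modelling steps for an environmental raster
stack: bringing every layer onto the unified 2.5 arc-minute analysis grid,
converting paleoclimate temperature layers stored in tenths of a degree to
degrees Celsius, and deriving slope and aspect from elevation.
"""

from __future__ import annotations

import math
from typing import Iterable, Literal

import numpy as np
from scipy import ndimage

from .grids import METRES_PER_DEGREE, EnvStack, GridSpec, Raster

#: Layers treated as categorical by default (resampled nearest-neighbour).
DEFAULT_CATEGORICAL = frozenset({"vegetation", "aspect"})

#: Temperature bioclims conventionally stored in tenths of deg C in paleo stacks.
TENTHS_TEMPERATURE_LAYERS = frozenset({f"bio{i}" for i in range(1, 12)})


def _fractional_index(src: GridSpec, dst: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Fractional (row, col) source indices of destination cell centers."""
    rows = np.arange(dst.n_rows)
    cols = np.arange(dst.n_cols)
    lon = dst.west + (cols + 0.5) * dst.cell_deg
    lat = dst.north - (rows + 0.5) * dst.cell_deg
    fc = (lon - src.west) / src.cell_deg - 0.5
    fr = (src.north - lat) / src.cell_deg - 0.5
    return np.meshgrid(fr, fc, indexing="ij")


def _resample(values: np.ndarray, src: GridSpec, dst: GridSpec,
              method: Literal["nearest", "bilinear"]) -> np.ndarray:
    fr, fc = _fractional_index(src, dst)
    outside = (fr < -0.5) | (fr > src.n_rows - 0.5) | (fc < -0.5) | (fc > src.n_cols - 0.5)
    if method == "nearest":
        r = np.clip(np.round(fr).astype(int), 0, src.n_rows - 1)
        c = np.clip(np.round(fc).astype(int), 0, src.n_cols - 1)
        out = values[r, c]
    else:
        # bilinear between source cell centers; contributing-nodata cells
        # poison the result, marked afterwards via the indicator interpolation
        filled = np.where(np.isnan(values), 0.0, values)
        bad = np.isnan(values).astype(float)
        coords = np.stack([fr, fc])
        out = ndimage.map_coordinates(filled, coords, order=1, mode="nearest")
        touch = ndimage.map_coordinates(bad, coords, order=1, mode="nearest")
        out = np.where(touch > 1e-12, np.nan, out)
    out = np.where(outside, np.nan, out)
    return out


def align_stack(stack: EnvStack, target: GridSpec,
                method: Literal["nearest", "bilinear"] = "bilinear",
                categorical: Iterable[str] = DEFAULT_CATEGORICAL) -> EnvStack:
    """Resample every layer of a stack onto *target*.

    Continuous layers use the requested method (default bilinear between
    cell centers); layers named in *categorical* are forced to
    nearest-neighbour. Nodata propagates: a destination cell touching any
    nodata source cell, or falling outside the source extent, is nodata.
    An identical target grid returns the values unchanged.
    """
    if method not in ("nearest", "bilinear"):
        raise ValueError(f"unknown resampling method: {method}")
    src = stack.grid
    if src.west >= target.east or target.west >= src.east or \
       src.south >= target.north or target.south >= src.north:
        raise ValueError("source and target grids do not overlap")
    if src == target:
        return EnvStack({n: r.copy_with(r.values) for n, r in stack.layers.items()},
                        stack.period, stack.gcm, stack.scenario)
    categorical = set(categorical)
    out = {}
    for name, raster in stack.layers.items():
        m = "nearest" if name in categorical else method
        out[name] = Raster(target, _resample(raster.values, src, target, m))
    return EnvStack(out, stack.period, stack.gcm, stack.scenario)


def scale_paleo_temperature(stack: EnvStack,
                            temp_layer_names: Iterable[str] = TENTHS_TEMPERATURE_LAYERS,
                            ) -> EnvStack:
    """Divide the named temperature layers by 10 (tenths of deg C -> deg C).

    Paleoclimate archives store temperature bioclims as integer tenths;
    dividing unifies their units with current/future layers. Layers not
    listed are passed through untouched; a listed layer missing from the
    stack is an error.
    """
    names = set(temp_layer_names)
    missing = names - set(stack.layers)
    if missing:
        raise KeyError(f"temperature layer(s) not in stack: {sorted(missing)}")
    out = {}
    for name, raster in stack.layers.items():
        out[name] = raster.copy_with(raster.values / 10.0 if name in names else raster.values)
    return EnvStack(out, stack.period, stack.gcm, stack.scenario)


def derive_terrain(elevation: Raster) -> tuple[Raster, Raster]:
    """Slope (degrees) and aspect (compass degrees) by Horn's 3x3 method.

    Cell size is converted to metres with 111,195 m/degree, scaled by
    cos(latitude) in the east-west direction. Aspect is the downhill
    compass direction (0 = N, 90 = E); flat cells get the sentinel -1.
    Border cells and cells with any nodata neighbour become nodata.
    """
    g = elevation.grid
    if g.n_rows < 3 or g.n_cols < 3:
        raise ValueError("terrain derivation needs a grid of at least 3x3")
    z = elevation.values
    dy_m = g.cell_deg * METRES_PER_DEGREE
    dx_m = dy_m * np.cos(np.radians(g.row_lats()))[:, None]

    # Horn kernel neighbours; rows: r-1 = north. a b c / d e f / g h i
    a = z[:-2, :-2]; b = z[:-2, 1:-1]; c = z[:-2, 2:]
    d = z[1:-1, :-2];                  f = z[1:-1, 2:]
    gg = z[2:, :-2]; h = z[2:, 1:-1]; i = z[2:, 2:]

    dzdx = ((c + 2 * f + i) - (a + 2 * d + gg)) / (8.0 * dx_m[1:-1])
    dzdy = ((a + 2 * b + c) - (gg + 2 * h + i)) / (8.0 * dy_m)  # northward

    slope_int = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    with np.errstate(invalid="ignore"):
        aspect_int = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0
    flat = (dzdx == 0) & (dzdy == 0)
    aspect_int = np.where(flat, -1.0, aspect_int)

    # any nodata neighbour (or self) -> nodata at the interior cell
    bad = np.isnan(z)
    bad_any = np.zeros_like(slope_int, dtype=bool)
    for rr in range(3):
        for cc in range(3):
            bad_any |= bad[rr:rr + g.n_rows - 2, cc:cc + g.n_cols - 2]
    slope_int = np.where(bad_any, np.nan, slope_int)
    aspect_int = np.where(bad_any, np.nan, aspect_int)

    slope = np.full(g.shape, np.nan)
    aspect = np.full(g.shape, np.nan)
    slope[1:-1, 1:-1] = slope_int
    aspect[1:-1, 1:-1] = aspect_int
    return Raster(g, slope), Raster(g, aspect)
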