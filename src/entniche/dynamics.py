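"""Range-dynamics analytics on suitability rasters.

Everything downstream of a continuous suitability map: four-class
suitability classification, fixed-threshold binary ranges, spherical
area accounting, change maps between periods (stable / expansion /
contraction), area-weighted range centroids and great-circle shifts,
multi-species overlap stacking, and glacial-refugium inference
(cells suitable both at the glacial maximum and today).

Class codes: 0 unsuitable [0, 0.1), 1 low [0.1, 0.3), 2 moderate
[0.3, 0.5), 3 high [0.5, 1]; boundaries belong to the class above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .grids import EARTH_RADIUS_KM, Raster

CLASS_NAMES = {0: "unsuitable", 1: "low", 2: "moderate", 3: "high"}
CHANGE_ABSENT, CHANGE_STABLE, CHANGE_EXPANSION, CHANGE_CONTRACTION = 0, 1, 2, 3
CHANGE_NAMES = {0: "absent", 1: "stable", 2: "expansion", 3: "contraction"}


def classify_suitability(s: Raster, thresholds: tuple[float, float, float] = (0.1, 0.3, 0.5),
                         ) -> Raster:
    """Bin a [0, 1] suitability raster into the four suitability classes."""
    t1, t2, t3 = thresholds
    if not (0 < t1 < t2 < t3 < 1):
        raise ValueError("thresholds must be strictly increasing within (0, 1)")
    v = s.values
    valid = s.valid
    if np.any((v[valid] < 0) | (v[valid] > 1)):
        raise ValueError("suitability values must lie in [0, 1]")
    classes = np.digitize(v, [t1, t2, t3], right=False).astype(float)
    classes[~valid] = np.nan
    return Raster(s.grid, classes)


def to_binary(s: Raster, threshold: float = 0.5) -> Raster:
    """Presence/absence at a fixed threshold: present iff s >= threshold."""
    if not 0 < threshold < 1:
        raise ValueError("binary threshold must lie in (0, 1)")
    v = np.where(s.valid, (s.values >= threshold).astype(float), np.nan)
    return Raster(s.grid, v)


def class_areas(classified: Raster) -> dict[int, float]:
    """Spherical area (km^2) covered by each class value of an integer raster."""
    areas = classified.grid.area_raster()
    valid = classified.valid
    out: dict[int, float] = {}
    vals = classified.values[valid].astype(int)
    cell_a = areas[valid]
    for c in np.unique(vals):
        out[int(c)] = float(cell_a[vals == c].sum())
    return out


def total_valid_area(raster: Raster) -> float:
    return float(raster.grid.area_raster()[raster.valid].sum())


def change_map(before: Raster, after: Raster) -> tuple[Raster, dict[str, float]]:
    """Categorize cells by binary-range transition and return category areas.

    present -> present = stable, present -> absent = contraction,
    absent -> present = expansion, absent -> absent = absent. A cell that
    is nodata in either map is nodata in the change map.
    """
    if before.grid != after.grid:
        raise ValueError("change_map needs maps on one grid")
    b = before.values
    a = after.values
    out = np.full(b.shape, np.nan)
    valid = before.valid & after.valid
    out[valid & (b == 1) & (a == 1)] = CHANGE_STABLE
    out[valid & (b == 1) & (a == 0)] = CHANGE_CONTRACTION
    out[valid & (b == 0) & (a == 1)] = CHANGE_EXPANSION
    out[valid & (b == 0) & (a == 0)] = CHANGE_ABSENT
    cm = Raster(before.grid, out)
    areas = {CHANGE_NAMES[k]: v for k, v in class_areas(cm).items()}
    for name in CHANGE_NAMES.values():
        areas.setdefault(name, 0.0)
    return cm, areas


@dataclass
class CentroidResult:
    lon: float
    lat: float
    elevation: float | None = None


@dataclass
class CentroidShift:
    frm: CentroidResult
    to: CentroidResult
    distance_km: float
    bearing_deg: float


def centroid(binary: Raster, elevation: Raster | None = None) -> CentroidResult:
    """Area-weighted mean center of the present cells of a binary range.

    Weights are spherical cell areas; longitudes average arithmetically
    (study regions here span no antimeridian). Elevation, if given, is
    sampled at the cell containing the centroid.
    """
    present = binary.valid & (binary.values == 1)
    if not present.any():
        raise ValueError("centroid of an empty range is undefined")
    rows, cols = np.nonzero(present)
    w = binary.grid.area_raster()[rows, cols]
    lon, lat = binary.grid.cell_center(rows, cols)
    clon = float(np.average(lon, weights=w))
    clat = float(np.average(lat, weights=w))
    elev = None
    if elevation is not None:
        elev = float(elevation.sample(clon, clat))
    return CentroidResult(clon, clat, elev)


def great_circle_km(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Haversine distance on the R = 6371 km sphere."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def initial_bearing_deg(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Initial great-circle bearing, compass degrees (0 = N, 90 = E)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    x = math.sin(dl) * math.cos(p2)
    y = math.cos(p1) * math.sin(p2) - math.sin(p1) * math.cos(p2) * math.cos(dl)
    return math.degrees(math.atan2(x, y)) % 360.0


def centroid_shift(before: Raster, after: Raster,
                   elevation: Raster | None = None) -> CentroidShift:
    """Centroid displacement between two binary ranges."""
    c1 = centroid(before, elevation)
    c2 = centroid(after, elevation)
    return CentroidShift(
        c1, c2,
        great_circle_km(c1.lon, c1.lat, c2.lon, c2.lat),
        initial_bearing_deg(c1.lon, c1.lat, c2.lon, c2.lat),
    )


def stack_species(maps: Mapping[str, Raster]) -> tuple[Raster, int, list[tuple[int, int]]]:
    """Per-cell count of species present, plus the maximum-overlap cells.

    Returns the count raster (nodata where every member is nodata), the
    maximum count, and the list of (row, col) cells achieving it. Regions
    of maximal overlap under glacial conditions are the candidate species
    differentiation centers.
    """
    if not maps:
        raise ValueError("stack_species needs at least one map")
    rasters = list(maps.values())
    g0 = rasters[0].grid
    for r in rasters[1:]:
        if r.grid != g0:
            raise ValueError("stacked maps must share one grid")
    counts = np.zeros(g0.shape)
    any_valid = np.zeros(g0.shape, dtype=bool)
    for r in rasters:
        counts += np.where(r.valid, r.values, 0.0)
        any_valid |= r.valid
    counts[~any_valid] = np.nan
    out = Raster(g0, counts)
    with np.errstate(invalid="ignore"):
        mx = int(np.nanmax(counts)) if any_valid.any() else 0
    cells = [tuple(rc) for rc in np.argwhere(np.nan_to_num(counts, nan=-1.0) == mx)]
    return out, mx, cells


def infer_refugium(lgm: Raster, current: Raster) -> Raster:
    """Cells occupied in both periods: the stable (refugial) intersection."""
    if lgm.grid != current.grid:
        raise ValueError("refugium inference needs maps on one grid")
    valid = lgm.valid & current.valid
    v = np.where(valid, ((lgm.values == 1) & (current.values == 1)).astype(float), np.nan)
    return Raster(lgm.grid, v)
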