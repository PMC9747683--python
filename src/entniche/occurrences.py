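"""Occurrence records: CSV ingest, validation, and grid thinning.

Occurrence CSVs carry a header ``species,lon,lat[,source]`` (extra columns
ignored), UTF-8, "." decimal separator, WGS84 decimal degrees. Thinning
keeps at most one record per analysis-grid cell to reduce spatial
autocorrelation of presence points before model fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .grids import GridSpec


@dataclass(frozen=True)
class OccurrenceRecord:
    species: str
    lon: float
    lat: float
    source: str = ""

    def __post_init__(self) -> None:
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude out of range: {self.lon}")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude out of range: {self.lat}")


@dataclass
class OccurrenceSet:
    """Ordered collection of occurrence records (order survives I/O)."""

    records: list[OccurrenceRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[OccurrenceRecord]:
        return iter(self.records)

    @property
    def lons(self) -> np.ndarray:
        return np.array([r.lon for r in self.records])

    @property
    def lats(self) -> np.ndarray:
        return np.array([r.lat for r in self.records])

    @property
    def species(self) -> list[str]:
        return sorted({r.species for r in self.records})

    def filter_species(self, species: str) -> "OccurrenceSet":
        return OccurrenceSet([r for r in self.records if r.species == species])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": [r.species for r in self.records],
                "lon": self.lons,
                "lat": self.lats,
                "source": [r.source for r in self.records],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


class OccurrenceFormatError(ValueError):
    """Raised for malformed occurrence files (missing columns, bad rows)."""


def load_occurrences(path: str | Path, species_filter: str | None = None) -> OccurrenceSet:
    """Load an occurrence CSV, validating coordinates row by row.

    Raises
    ------
    OccurrenceFormatError
        If a required column is missing or a row carries an out-of-range
        coordinate (the error names the offending row).
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"species", "lon", "lat"}
    missing = required - set(df.columns)
    if missing:
        raise OccurrenceFormatError(
            f"occurrence file {path} missing required column(s): {sorted(missing)}"
        )
    records = []
    for i, row in df.iterrows():
        if species_filter is not None and str(row["species"]) != species_filter:
            continue
        try:
            rec = OccurrenceRecord(
                species=str(row["species"]),
                lon=float(row["lon"]),
                lat=float(row["lat"]),
                source=str(row.get("source", "")) if "source" in df.columns else "",
            )
        except (TypeError, ValueError) as exc:
            raise OccurrenceFormatError(f"row {i}: {exc}") from exc
        records.append(rec)
    return OccurrenceSet(records)


def thin_occurrences(occ: OccurrenceSet, grid: GridSpec) -> OccurrenceSet:
    """Keep at most one record per grid cell (the first in input order).

    Records falling outside the grid are dropped with a warning. Output
    order follows input order; the operation is idempotent.
    """
    if not occ.records:
        return OccurrenceSet([])
    rows, cols = grid.cell_index(occ.lons, occ.lats)
    kept: list[OccurrenceRecord] = []
    seen: set[tuple[int, int]] = set()
    n_outside = 0
    for rec, r, c in zip(occ.records, rows, cols):
        if r < 0:
            n_outside += 1
            continue
        if (r, c) in seen:
            continue
        seen.add((r, c))
        kept.append(rec)
    if n_outside:
        warnings.warn(
            f"thin_occurrences: dropped {n_outside} record(s) outside the grid",
            stacklevel=2,
        )
    return OccurrenceSet(kept)


def presence_cells(occ: OccurrenceSet, grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Row/col indices of the cells holding each record (inside the grid)."""
    rows, cols = grid.cell_index(occ.lons, occ.lats)
    inside = rows >= 0
    return rows[inside], cols[inside]
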