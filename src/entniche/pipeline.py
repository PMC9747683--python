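"""End-to-end workflow: thin -> screen -> tune -> fit -> project -> dynamics.

A run operates on a workspace holding an occurrence CSV and one raster
stack per period/GCM, driven by a declarative :class:`RunConfig`
(YAML-loadable). Every random draw flows from the master seed through
named sub-seeds (stage:species:replicate), so a rerun with the same
config and seed reproduces byte-identical summary CSVs.

Stage order per species: grid-thin occurrences; sample background cells;
preliminary all-variable fit for percent contributions; correlation +
contribution screening; RM x FC grid search with the configured
partition scheme (spatial block for n >= 25 presences, leave-one-out
jackknife below); final fit as bootstrap replicates whose continuous
suitability rasters are averaged before any thresholding; projection to
every period/GCM with GCM ensembles averaged per period; classification,
binary ranges, spherical areas, change maps against the current period,
centroid shifts; and across species, overlap stacking and refugium
inference for the earliest period.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dynamics import (
    CHANGE_NAMES,
    centroid_shift,
    change_map,
    classify_suitability,
    class_areas,
    infer_refugium,
    stack_species,
    to_binary,
)
from .grids import EnvStack, GridSpec, Raster, ensemble_mean, read_stack, write_asc
from .model import fit_maxent
from .occurrences import load_occurrences, presence_cells, thin_occurrences
from .selection import ContributionTable, correlation_matrix, screen_variables
from .evaluation import make_partition
from .tuning import TuningGrid, run_grid, select_best


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    occurrences: str
    stacks: dict[str, dict[str, str]]          # period -> gcm -> directory
    out_dir: str
    current_period: str = "current"
    species: list[str] | None = None           # default: all in the file
    r_threshold: float = 0.8
    contrib_threshold: float = 10.0            # percent
    rm_values: tuple[float, ...] = (1.0, 2.0)
    fc_sets: tuple[str, ...] = ("L", "LQ", "LQH")
    background_size: int = 10_000
    replicates: int = 10
    block_min_n: int = 25                      # block partition if n >= this
    class_thresholds: tuple[float, float, float] = (0.1, 0.3, 0.5)
    binary_threshold: float = 0.5              # range dynamics
    stacking_threshold: float = 0.1            # multi-species overlap
    hinge_knots: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        t1, t2, t3 = self.class_thresholds
        if not (0 < t1 < t2 < t3 < 1):
            raise ValueError("classification thresholds must be strictly increasing in (0,1)")
        if not 0 < self.binary_threshold < 1 or not 0 < self.stacking_threshold < 1:
            raise ValueError("binary thresholds must lie in (0,1)")
        if self.background_size < 1 or self.replicates < 1:
            raise ValueError("background and replicate counts must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        for key in ("rm_values", "fc_sets", "class_thresholds"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def validate_paths(self) -> None:
        if not Path(self.occurrences).exists():
            raise FileNotFoundError(self.occurrences)
        for period, gcms in self.stacks.items():
            for gcm, d in gcms.items():
                if not Path(d).is_dir():
                    raise FileNotFoundError(f"{period}/{gcm}: {d}")


def subseed(master: int, *labels) -> int:
    """Deterministic sub-seed derived from the master seed and stage labels."""
    text = ":".join(str(x) for x in labels)
    return (master * 1_000_003 + zlib.crc32(text.encode())) % (2**31 - 1)


def sample_background(grid: GridSpec, valid: np.ndarray, n: int, seed: int,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Uniform seeded sample of background cells from the valid study area.

    Presence cells are not excluded. Sampling is with replacement only if
    the study area has fewer valid cells than requested.
    """
    rows, cols = np.nonzero(valid)
    rng = np.random.default_rng(seed)
    replace = rows.size < n
    idx = rng.choice(rows.size, size=min(n, rows.size) if not replace else n,
                     replace=replace)
    return rows[idx], cols[idx]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns (and writes) the run manifest."""
    config.validate_paths()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = config.seed
    manifest: dict = {
        "version": __version__,
        "seed": master,
        "config_hash": zlib.crc32(json.dumps(
            {k: str(v) for k, v in vars(config).items()}, sort_keys=True).encode()),
        "species": {},
        "artifacts": [],
    }

    def register(path: Path) -> str:
        manifest["artifacts"].append(str(path))
        return str(path)

    # ---- load stacks -----------------------------------------------------
    stacks: dict[str, dict[str, EnvStack]] = {}
    for period, gcms in config.stacks.items():
        stacks[period] = {g: read_stack(d, period=period, gcm=g) for g, d in gcms.items()}
    current = next(iter(stacks[config.current_period].values()))
    grid = current.grid

    occ_all = load_occurrences(config.occurrences)
    species_list = config.species or occ_all.species

    binary_current: dict[str, Raster] = {}
    binary_periods: dict[str, dict[str, Raster]] = {}
    summary_rows, centroid_rows, tuning_paths = [], [], {}

    for sp in species_list:
        stage = f"species failed: {sp}"
        try:
            occ = thin_occurrences(occ_all.filter_species(sp), grid)
            n = len(occ)
            if n < 5:
                raise ValueError(f"too few thinned presences for {sp}: {n}")

            valid = current.joint_valid()
            brow, bcol = sample_background(
                grid, valid, config.background_size, subseed(master, "background", sp))
            prow, pcol = presence_cells(occ, grid)
            names = current.names
            bg_env = {v: current.layers[v].values[brow, bcol] for v in names}
            pr_env = {v: current.layers[v].values[prow, pcol] for v in names}

            # preliminary fit -> contributions -> screening
            stage = f"screen: {sp}"
            _, pre_trace = fit_maxent(pr_env, bg_env, rm=1.0, fc="LQ",
                                      hinge_knots=config.hinge_knots)
            contrib = ContributionTable(pre_trace.percent_contributions())
            corr = correlation_matrix(current, (brow, bcol))
            screen = screen_variables(corr, contrib, config.r_threshold,
                                      config.contrib_threshold)
            kept = screen.kept or names
            screen_path = out_dir / f"{sp}_screening.csv"
            screen.write_log(screen_path)
            register(screen_path)
            bg_env = {v: bg_env[v] for v in kept}
            pr_env = {v: pr_env[v] for v in kept}

            # tuning
            stage = f"tune: {sp}"
            scheme = "block" if n >= config.block_min_n else "jackknife"
            part = make_partition(occ.lons, occ.lats, scheme,
                                  seed=subseed(master, "partition", sp))
            result = run_grid(pr_env, bg_env,
                              TuningGrid(config.rm_values, config.fc_sets), part,
                              hinge_knots=config.hinge_knots)
            result = select_best(result)
            rm, fc = result.selected
            tpath = out_dir / f"{sp}_tuning.csv"
            result.table().to_csv(tpath, index=False, float_format="%.6g")
            tuning_paths[sp] = register(tpath)

            # final fit: bootstrap replicates, rasters averaged pre-threshold
            stage = f"fit: {sp}"
            boot = make_partition(occ.lons, occ.lats, "bootstrap_replicate",
                                  seed=subseed(master, "bootstrap", sp),
                                  n_replicates=config.replicates)
            models = []
            for r_i, (tr, _te) in enumerate(boot.splits()):
                m, _ = fit_maxent({v: pr_env[v][tr] for v in kept}, bg_env,
                                  rm=rm, fc=fc, hinge_knots=config.hinge_knots)
                models.append(m)

            # projection: replicate-mean suitability per period/GCM, then
            # GCM ensemble per period
            stage = f"project: {sp}"
            period_suit: dict[str, Raster] = {}
            for period, gcms in stacks.items():
                per_gcm = []
                for gcm, st in gcms.items():
                    reps = [m.predict(st.subset(kept)) for m in models]
                    per_gcm.append(ensemble_mean(reps))
                ens = ensemble_mean(per_gcm)
                period_suit[period] = ens
                spath = out_dir / f"{sp}_{period}_suitability.asc"
                write_asc(ens, spath)
                register(spath)

            # dynamics
            stage = f"dynamics: {sp}"
            cur = period_suit[config.current_period]
            binary_current[sp] = to_binary(cur, config.binary_threshold)
            for period, suit in period_suit.items():
                classified = classify_suitability(suit, config.class_thresholds)
                areas = class_areas(classified)
                for cls, a in areas.items():
                    summary_rows.append({"species": sp, "period": period,
                                         "measure": f"class_{cls}_km2", "value": a})
                binary_periods.setdefault(period, {})[sp] = to_binary(
                    suit, config.stacking_threshold)
                if period != config.current_period:
                    before = to_binary(suit, config.binary_threshold)
                    cmap, careas = change_map(before, binary_current[sp])
                    cpath = out_dir / f"{sp}_{period}_to_current_change.asc"
                    write_asc(cmap, cpath)
                    register(cpath)
                    for cat, a in careas.items():
                        summary_rows.append({"species": sp, "period": period,
                                             "measure": f"change_{cat}_km2", "value": a})
                    shift = centroid_shift(before, binary_current[sp])
                    centroid_rows.append({
                        "species": sp, "from_period": period,
                        "to_period": config.current_period,
                        "from_lon": shift.frm.lon, "from_lat": shift.frm.lat,
                        "to_lon": shift.to.lon, "to_lat": shift.to.lat,
                        "distance_km": shift.distance_km,
                        "bearing_deg": shift.bearing_deg,
                    })

            manifest["species"][sp] = {
                "n_presences": n, "partition": scheme,
                "selected_rm": rm, "selected_fc": fc,
                "kept_variables": kept, "selection_trace": result.trace,
            }
        except Exception as exc:
            manifest["species"][sp] = {"failed": True, "stage": stage, "error": str(exc)}
            raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    # ---- cross-species stacking and refugia ------------------------------
    past_periods = [p for p in stacks if p != config.current_period]
    if past_periods and binary_periods:
        glacial = past_periods[0]
        counts, mx, cells = stack_species(binary_periods[glacial])
        opath = out_dir / f"overlap_{glacial}.asc"
        write_asc(counts, opath)
        register(opath)
        manifest["overlap"] = {"period": glacial, "max_species": mx,
                               "n_max_cells": len(cells)}
        for sp in binary_current:
            ref = infer_refugium(binary_periods[glacial][sp],
                                 binary_periods[config.current_period][sp])
            rpath = out_dir / f"{sp}_refugium.asc"
            write_asc(ref, rpath)
            register(rpath)
            area = class_areas(ref).get(1, 0.0)
            summary_rows.append({"species": sp, "period": glacial,
                                 "measure": "refugium_km2", "value": area})

    # ---- summaries -------------------------------------------------------
    sum_path = out_dir / "summary_areas.csv"
    pd.DataFrame(summary_rows).to_csv(sum_path, index=False, float_format="%.6f")
    register(sum_path)
    cen_path = out_dir / "summary_centroids.csv"
    pd.DataFrame(centroid_rows).to_csv(cen_path, index=False, float_format="%.6f")
    register(cen_path)

    man_path = out_dir / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
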