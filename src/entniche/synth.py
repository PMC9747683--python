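"""Synthetic environment stacks, truth models, and presence samples.

Stands in for downloaded climate/occurrence data so the whole pipeline
runs and is validated at desk scale. Layers are smooth low-frequency
random surfaces (sums of seeded Gaussian bumps) — not white noise — so
hinge features, response curves and spatial block partitions are
meaningfully exercised. Cross-layer correlation is imposed exactly by
orthonormalizing the base fields over cells and mixing them with the
Cholesky factor of the target correlation matrix.

The default fixture scale (100x100 grid, 6 layers, 2,000 background
cells, 200 presences) keeps every test suite run within minutes on one
CPU while preserving the statistical structure the analysis assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .grids import EnvStack, GridSpec, Raster, write_stack
from .occurrences import OccurrenceRecord, OccurrenceSet

#: Default grid: a 100x100 block of 2.5 arc-minute cells in the subtropics.
DEFAULT_GRID = GridSpec(west=100.0, north=28.0, cell_size=2.5, n_rows=100, n_cols=100)


def _smooth_field(grid: GridSpec, rng: np.random.Generator, n_bumps: int = 10,
                  length_scale: float = 0.35) -> np.ndarray:
    """One smooth random surface: a sum of seeded Gaussian bumps.

    *length_scale* is the bump width as a fraction of the grid extent.
    """
    ny, nx = grid.shape
    y, x = np.mgrid[0:ny, 0:nx]
    x = x / max(nx - 1, 1)
    y = y / max(ny - 1, 1)
    f = np.zeros((ny, nx))
    for _ in range(n_bumps):
        cx, cy = rng.uniform(0, 1, size=2)
        amp = rng.normal()
        width = length_scale * rng.uniform(0.5, 1.5)
        f += amp * np.exp(-(((x - cx) ** 2 + (y - cy) ** 2) / (2 * width**2)))
    return f


def _correlation_target(n: int, target) -> np.ndarray:
    if np.isscalar(target):
        C = np.full((n, n), float(target))
        np.fill_diagonal(C, 1.0)
    else:
        C = np.asarray(target, dtype=float)
        if C.shape != (n, n):
            raise ValueError("correlation matrix shape must match layer count")
    try:
        np.linalg.cholesky(C + 1e-12 * np.eye(n))
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation target is not positive semi-definite") from exc
    return C


def make_env_stack(grid: GridSpec = DEFAULT_GRID, n_layers: int = 6,
                   correlation_target=0.0, seed: int = 0,
                   n_bumps: int = 10, length_scale: float = 0.35,
                   include_elevation: bool = True) -> EnvStack:
    """Generate a stack of correlated bioclim-like layers plus elevation.

    Layers are named ``bio1..bioN``; odd layers get temperature-like
    scales (mean 20, s.d. 5), even layers precipitation-like (mean 60,
    s.d. 25). The empirical cross-layer correlation over cells equals the
    target exactly by construction. Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    C = _correlation_target(n_layers, correlation_target)
    ncells = grid.n_rows * grid.n_cols

    B = np.column_stack([
        _smooth_field(grid, rng, n_bumps, length_scale).ravel() for _ in range(n_layers)
    ])
    B = B - B.mean(axis=0)
    Q, _ = np.linalg.qr(B)  # orthonormal, zero-mean columns
    L = np.linalg.cholesky(C + 1e-12 * np.eye(n_layers))
    X = Q @ L.T
    X = X / X.std(axis=0)  # unit s.d. per layer, correlation = C

    layers: dict[str, Raster] = {}
    for i in range(n_layers):
        if i % 2 == 0:
            mean, sd = 20.0, 5.0     # temperature-like
        else:
            mean, sd = 60.0, 25.0    # precipitation-like
        vals = (mean + sd * X[:, i]).reshape(grid.shape)
        layers[f"bio{i + 1}"] = Raster(grid, vals)
    if include_elevation:
        e = _smooth_field(grid, rng, n_bumps, length_scale)
        e = (e - e.min()) / max(e.max() - e.min(), 1e-12)
        layers["elevation"] = Raster(grid, 200.0 + 2300.0 * e)
    return EnvStack(layers, period="current")


@dataclass
class SyntheticTruth:
    """The generating model: coefficients, true suitability, and sample."""

    stack: EnvStack
    form: str
    coefficients: dict[str, tuple[float, float]]  # var -> (linear, quadratic)
    suitability: Raster
    seed: int
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def informative_variables(self) -> list[str]:
        return [v for v, (a, b) in self.coefficients.items() if a != 0 or b != 0]


def make_truth(stack: EnvStack, form: str = "linear+quadratic",
               coefficients: Mapping[str, tuple[float, float]] | None = None,
               seed: int = 0) -> SyntheticTruth:
    """Build a known truth surface from a stack.

    The linear predictor is a linear (+ quadratic) form in standardized
    layer values; true suitability is a cloglog-style squash
    ``1 - exp(-exp(eta))`` rescaled to [0, 1]. With no explicit
    coefficients, two layers are drawn at random: one gets a positive
    linear term, the other a concave quadratic (an interior optimum).
    """
    rng = np.random.default_rng(seed)
    names = [n for n in stack.names if n != "elevation"]
    if coefficients is None:
        chosen = rng.choice(len(names), size=min(2, len(names)), replace=False)
        coefficients = {names[chosen[0]]: (1.5, 0.0)}
        if len(chosen) > 1:
            coefficients[names[chosen[1]]] = (0.0, -1.5)
        if form == "linear":
            coefficients = {v: (a if a else 1.0, 0.0) for v, (a, b) in coefficients.items()}
    unknown = set(coefficients) - set(stack.names)
    if unknown:
        raise KeyError(f"truth references unknown layer(s): {sorted(unknown)}")

    valid = stack.joint_valid()
    eta = np.zeros(stack.grid.shape)
    standardization = {}
    for v, (a, b) in coefficients.items():
        x = stack.layers[v].values
        mu = float(np.nanmean(x))
        sd = float(np.nanstd(x)) or 1.0
        standardization[v] = (mu, sd)
        z = (x - mu) / sd
        eta = eta + a * z + b * z**2
    s = 1.0 - np.exp(-np.exp(eta))
    lo, hi = np.nanmin(s[valid]), np.nanmax(s[valid])
    if hi - lo < 1e-12:
        s = np.full_like(s, 0.5)  # constant predictor -> flat mid suitability
    else:
        s = (s - lo) / (hi - lo)
    s = np.where(valid, s, np.nan)
    return SyntheticTruth(stack, form, dict(coefficients), Raster(stack.grid, s),
                          seed, standardization)


def sample_presences(truth: SyntheticTruth, n: int = 200, seed: int = 0,
                     species: str = "synthetic_sp") -> OccurrenceSet:
    """Draw presence records with probability proportional to
    true suitability x cell area; records sit at drawn cell centers.
    With-replacement draws collapse to one record per cell under thinning."""
    if n < 1:
        raise ValueError("need n >= 1")
    rng = np.random.default_rng(seed)
    s = truth.suitability
    rows, cols = np.nonzero(s.valid)
    w = s.values[rows, cols] * s.grid.area_raster()[rows, cols]
    total = w.sum()
    if total <= 0:
        raise ValueError("cannot sample from an all-zero suitability surface")
    idx = rng.choice(rows.size, size=n, replace=True, p=w / total)
    lon, lat = s.grid.cell_center(rows[idx], cols[idx])
    recs = [OccurrenceRecord(species, float(lo), float(la), source="synthetic")
            for lo, la in zip(lon, lat)]
    return OccurrenceSet(recs)


def make_scenario_series(stack: EnvStack, n_periods: int = 2, n_gcms: int = 1,
                         shifts: "Sequence[Mapping[str, float]] | Mapping[str, float] | None" = None,
                         noise_sd: float = 0.0, seed: int = 0,
                         period_labels: Sequence[str] | None = None) -> list[EnvStack]:
    """Period/GCM variants of a stack: deterministic per-layer shifts per
    period plus seeded smooth per-GCM noise of s.d. *noise_sd*.

    *shifts* is a list of per-layer offset dicts (one per period), or a
    single dict applied cumulatively (period p gets p times the offset;
    period 0 is the unshifted stack). Labels default to period names
    ``period0..`` and GCM names ``gcm1..``.
    """
    if n_periods < 1 or n_gcms < 1:
        raise ValueError("need n_periods >= 1 and n_gcms >= 1")
    if shifts is None:
        shifts = [{} for _ in range(n_periods)]
    elif isinstance(shifts, Mapping):
        shifts = [{k: p * v for k, v in shifts.items()} for p in range(n_periods)]
    if len(shifts) != n_periods:
        raise ValueError("need one shift dict per period")
    labels = list(period_labels) if period_labels else [f"period{p}" for p in range(n_periods)]

    rng = np.random.default_rng(seed)
    out = []
    for p in range(n_periods):
        for g in range(n_gcms):
            layers = {}
            for name, r in stack.layers.items():
                v = r.values + shifts[p].get(name, 0.0)
                if noise_sd > 0:
                    noise = _smooth_field(stack.grid, rng)
                    noise = noise / max(noise.std(), 1e-12) * noise_sd
                    v = v + noise
                layers[name] = Raster(stack.grid, v)
            out.append(EnvStack(layers, period=labels[p], gcm=f"gcm{g + 1}"))
    return out


def make_workspace(directory: str | Path, grid: GridSpec = DEFAULT_GRID,
                   n_layers: int = 5, n_presences: int = 120,
                   correlation_target=0.3, seed: int = 0,
                   periods: Sequence[str] = ("lgm", "current"),
                   n_gcms: int = 2, cooling: float = -4.0,
                   noise_sd: float = 0.5) -> dict:
    """Materialize a complete demo workspace on disk.

    Writes ``occurrences.csv`` and one ``.asc`` stack per period/GCM under
    ``stacks/<period>/<gcm>/`` (the current period has a single "observed"
    stack). The first temperature-like layer is cooled by *cooling*
    degrees in every non-current period. Returns a manifest dict with the
    truth's coefficients and all paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stack = make_env_stack(grid, n_layers, correlation_target, seed=seed)
    truth = make_truth(stack, seed=seed)
    occ = sample_presences(truth, n_presences, seed=seed + 1)
    occ_path = directory / "occurrences.csv"
    occ.to_csv(occ_path)

    stack_paths: dict[str, dict[str, str]] = {}
    current_dir = directory / "stacks" / "current" / "observed"
    write_stack(stack, current_dir)
    stack_paths["current"] = {"observed": str(current_dir)}

    past = [p for p in periods if p != "current"]
    if past:
        shifts = [{"bio1": cooling} for _ in past]
        variants = make_scenario_series(stack, n_periods=len(past), n_gcms=n_gcms,
                                        shifts=shifts, noise_sd=noise_sd,
                                        seed=seed + 2, period_labels=list(past))
        for st in variants:
            d = directory / "stacks" / st.period / st.gcm
            write_stack(st, d)
            stack_paths.setdefault(st.period, {})[st.gcm] = str(d)

    return {
        "occurrences": str(occ_path),
        "stacks": stack_paths,
        "grid": {"west": grid.west, "north": grid.north, "cell_size": grid.cell_size,
                 "n_rows": grid.n_rows, "n_cols": grid.n_cols},
        "truth_coefficients": {k: list(v) for k, v in truth.coefficients.items()},
        "seed": seed,
    }
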