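"""Feature expansion for the maximum-entropy model.

Feature classes follow the standard presence-background vocabulary:

* ``L`` linear — the variable, min-max scaled to [0, 1];
* ``Q`` quadratic — the square of the scaled variable;
* ``P`` product — pairwise products of scaled variables (distinct pairs);
* ``H`` hinge — forward ramps ``max(0, (x - k) / (max - k))`` and reverse
  ramps ``max(0, (k - x) / (k - min))`` at knots placed at empirical
  quantiles of the background sample (default 30 per direction per
  variable);
* ``T`` threshold — step indicators ``x > k`` at the same quantile knots.

Scaling constants come from the combined presence + background sample;
features constant over that sample are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

FEATURE_CLASSES = ("linear", "quadratic", "product", "forward_hinge", "reverse_hinge", "threshold")
FC_LETTERS = {"L", "Q", "H", "P", "T"}


@dataclass(frozen=True)
class FeatureDef:
    """One feature: class, variable(s), optional knot, scaling bounds."""

    cls: str
    variables: tuple[str, ...]
    knot: float | None = None
    scale_min: float = 0.0
    scale_max: float = 1.0
    scale_min2: float = 0.0  # second variable of a product
    scale_max2: float = 1.0

    def __post_init__(self) -> None:
        if self.cls not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class: {self.cls}")
        if self.cls == "product" and len(set(self.variables)) != 2:
            raise ValueError("product features need two distinct variables")
        if self.cls != "product" and len(self.variables) != 1:
            raise ValueError(f"{self.cls} features take exactly one variable")

    def label(self) -> str:
        v = "*".join(self.variables)
        return f"{self.cls}({v})" if self.knot is None else f"{self.cls}({v}@{self.knot:.4g})"


def _scaled(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    span = hi - lo
    if span == 0:
        return np.zeros_like(x)
    return (x - lo) / span


def evaluate_features(features: list[FeatureDef], env: Mapping[str, np.ndarray],
                      clamp: Mapping[str, tuple[float, float]] | None = None) -> np.ndarray:
    """(n_samples, n_features) design matrix for the given environment vectors.

    *clamp* optionally truncates each variable to its training range
    before feature evaluation (projection-time behaviour).
    """
    cols = []
    cache: dict[str, np.ndarray] = {}

    def var(name: str) -> np.ndarray:
        if name not in cache:
            x = np.asarray(env[name], dtype=float)
            if clamp is not None and name in clamp:
                lo, hi = clamp[name]
                x = np.clip(x, lo, hi)
            cache[name] = x
        return cache[name]

    for f in features:
        x = var(f.variables[0])
        if f.cls == "linear":
            cols.append(_scaled(x, f.scale_min, f.scale_max))
        elif f.cls == "quadratic":
            cols.append(_scaled(x, f.scale_min, f.scale_max) ** 2)
        elif f.cls == "product":
            y = var(f.variables[1])
            cols.append(_scaled(x, f.scale_min, f.scale_max)
                        * _scaled(y, f.scale_min2, f.scale_max2))
        elif f.cls == "forward_hinge":
            denom = f.scale_max - f.knot
            cols.append(np.maximum(0.0, (x - f.knot) / denom) if denom > 0
                        else np.zeros_like(x))
        elif f.cls == "reverse_hinge":
            denom = f.knot - f.scale_min
            cols.append(np.maximum(0.0, (f.knot - x) / denom) if denom > 0
                        else np.zeros_like(x))
        elif f.cls == "threshold":
            cols.append((x > f.knot).astype(float))
    return np.column_stack(cols) if cols else np.empty((len(next(iter(env.values()))), 0))


def build_features(presence_env: Mapping[str, np.ndarray],
                   background_env: Mapping[str, np.ndarray],
                   fc: str = "LQH",
                   hinge_knots: int = 30,
                   threshold_knots: int = 30) -> list[FeatureDef]:
    """Build the feature list for a feature-class set such as "LQH".

    Scaling bounds come from the combined presence + background sample;
    hinge and threshold knots sit at empirical quantiles of the
    background. Features constant over the combined sample are dropped.
    """
    fc_set = set(fc.upper())
    unknown = fc_set - FC_LETTERS
    if unknown:
        raise ValueError(f"unknown feature-class letter(s): {sorted(unknown)}")
    if not fc_set:
        raise ValueError("feature-class set must be nonempty")
    names = list(background_env)
    if any(np.asarray(background_env[n]).size < 2 for n in names):
        raise ValueError("need at least 2 background samples")

    combined = {
        n: np.concatenate([np.asarray(presence_env[n], float),
                           np.asarray(background_env[n], float)])
        for n in names
    }
    bounds = {n: (float(np.nanmin(combined[n])), float(np.nanmax(combined[n]))) for n in names}
    feats: list[FeatureDef] = []

    if "L" in fc_set:
        for n in names:
            feats.append(FeatureDef("linear", (n,), None, *bounds[n]))
    if "Q" in fc_set:
        for n in names:
            feats.append(FeatureDef("quadratic", (n,), None, *bounds[n]))
    if "P" in fc_set:
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                feats.append(FeatureDef("product", (a, b), None,
                                        bounds[a][0], bounds[a][1],
                                        bounds[b][0], bounds[b][1]))
    if "H" in fc_set:
        qs = (np.arange(hinge_knots) + 0.5) / hinge_knots
        for n in names:
            knots = np.quantile(np.asarray(background_env[n], float), qs)
            lo, hi = bounds[n]
            for k in knots:
                feats.append(FeatureDef("forward_hinge", (n,), float(k), lo, hi))
                feats.append(FeatureDef("reverse_hinge", (n,), float(k), lo, hi))
    if "T" in fc_set:
        qs = (np.arange(threshold_knots) + 0.5) / threshold_knots
        for n in names:
            knots = np.quantile(np.asarray(background_env[n], float), qs)
            lo, hi = bounds[n]
            for k in knots:
                feats.append(FeatureDef("threshold", (n,), float(k), lo, hi))

    # drop features constant over the combined sample
    X = evaluate_features(feats, combined)
    keep = X.std(axis=0) > 0
    return [f for f, k in zip(feats, keep) if k]


def feature_count(n_vars: int, fc: str, hinge_knots: int = 30, threshold_knots: int = 30) -> int:
    """Expected feature count before constant-dropping (for sanity checks)."""
    fc_set = set(fc.upper())
    n = 0
    if "L" in fc_set:
        n += n_vars
    if "Q" in fc_set:
        n += n_vars
    if "P" in fc_set:
        n += n_vars * (n_vars - 1) // 2
    if "H" in fc_set:
        n += n_vars * hinge_knots * 2
    if "T" in fc_set:
        n += n_vars * threshold_knots
    return n
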