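"""Candidate-variable screening by pairwise correlation and contribution.

The screening rule retains variables whose model contribution exceeds a
threshold (default 10%) and, among strongly correlated pairs
(|r| >= 0.8), drops the member with the smaller contribution. The greedy
procedure is deterministic: pairs are processed in descending |r| with
alphabetical tie-breaks, and every drop is logged with its trigger pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import EnvStack


@dataclass
class CorrelationMatrix:
    names: list[str]
    r: pd.DataFrame  # symmetric, diagonal 1, possibly NaN for degenerate pairs

    def __getitem__(self, pair: tuple[str, str]) -> float:
        return float(self.r.loc[pair[0], pair[1]])


@dataclass
class ContributionTable:
    """Percent contribution per variable; entries >= 0, summing to 100."""

    percent: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.percent.values())
        if self.percent and abs(total - 100.0) > 0.1:
            raise ValueError(f"contributions must sum to 100 (got {total:.3f})")
        if any(v < -1e-9 for v in self.percent.values()):
            raise ValueError("contributions must be non-negative")

    def __getitem__(self, name: str) -> float:
        return self.percent[name]


@dataclass
class ScreenDecision:
    dropped: str
    kept: str
    r: float
    dropped_contrib: float
    kept_contrib: float
    note: str = ""


@dataclass
class ScreenResult:
    kept: list[str]
    log: list[ScreenDecision] = field(default_factory=list)
    conflicts: list[tuple[str, str, float]] = field(default_factory=list)

    def log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "dropped_variable": d.dropped,
                    "kept_variable": d.kept,
                    "r": d.r,
                    "dropped_contribution": d.dropped_contrib,
                    "kept_contribution": d.kept_contrib,
                    "note": d.note,
                }
                for d in self.log
            ]
        )

    def write_log(self, path: str | Path) -> None:
        self.log_frame().to_csv(path, index=False)


def correlation_matrix(stack: EnvStack, sample_cells: tuple[np.ndarray, np.ndarray] | None = None,
                       ) -> CorrelationMatrix:
    """Pairwise Pearson r between layers over jointly valid cells.

    *sample_cells* is an optional (rows, cols) index pair restricting the
    computation (e.g. the background sample); by default all jointly valid
    cells are used. Zero-variance layers yield NaN correlations for their
    pairs, with a warning.
    """
    names = stack.names
    if sample_cells is None:
        rows, cols = np.nonzero(stack.joint_valid())
    else:
        rows, cols = np.asarray(sample_cells[0]), np.asarray(sample_cells[1])
    X = stack.to_matrix(rows, cols, names)
    ok = ~np.isnan(X).any(axis=1)
    X = X[ok]
    if X.shape[0] < 3:
        raise ValueError("correlation needs at least 3 jointly valid cells")
    df = pd.DataFrame(X, columns=names)
    degenerate = [n for n in names if df[n].std() == 0.0]
    if degenerate:
        warnings.warn(
            f"zero-variance layer(s), correlations undefined: {degenerate}",
            stacklevel=2,
        )
    r = df.corr()  # pandas leaves NaN for zero-variance pairs
    np.fill_diagonal(r.values, 1.0)
    return CorrelationMatrix(names, r)


def screen_variables(corr: CorrelationMatrix, contrib: ContributionTable,
                     r_threshold: float = 0.8, contrib_threshold: float = 10.0,
                     always_keep: set[str] | None = None) -> ScreenResult:
    """Greedy correlation/contribution screening.

    Variables with contribution above *contrib_threshold* (percent) are
    protected. Pairs with |r| >= *r_threshold* are visited in descending
    |r| (alphabetical tie-break); for each pair still fully present the
    lower-contribution member is dropped, unless protection says
    otherwise. Two protected members are both kept and the conflict
    logged. *always_keep* names are protected unconditionally (the expert
    escape hatch for "biological significance").
    """
    always_keep = always_keep or set()
    names = [n for n in corr.names if n in contrib.percent]
    if set(names) != set(corr.names) or set(names) != set(contrib.percent):
        raise ValueError("correlation matrix and contribution table must cover the same variables")
    protected = {n for n in names if contrib[n] > contrib_threshold} | (always_keep & set(names))

    pairs = []
    for i, a in enumerate(sorted(names)):
        for b in sorted(names)[i + 1:]:
            r = corr[a, b]
            if np.isnan(r):
                continue
            if abs(r) >= r_threshold:
                pairs.append((abs(r), a, b, r))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))

    present = set(names)
    log: list[ScreenDecision] = []
    conflicts: list[tuple[str, str, float]] = []
    for _, a, b, r in pairs:
        if a not in present or b not in present:
            continue
        pa, pb = a in protected, b in protected
        if pa and pb:
            conflicts.append((a, b, r))
            continue
        if pa != pb:
            drop, keep = (b, a) if pa else (a, b)
            note = "protection override"
        else:
            drop, keep = (a, b) if contrib[a] < contrib[b] else (b, a)
            if contrib[a] == contrib[b]:
                drop, keep = sorted((a, b))[1], sorted((a, b))[0]
            note = ""
        present.discard(drop)
        log.append(
            ScreenDecision(drop, keep, r, contrib[drop], contrib[keep], note)
        )
    kept = [n for n in names if n in present]
    return ScreenResult(kept, log, conflicts)
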