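"""Grid search over regularization multiplier x feature classes.

Mirrors the common model-selection protocol for presence-background
models: evaluate every (RM, FC) combination under a chosen
cross-validation partition, rank by small-sample AICc, and gate on
discrimination (test AUC) and calibration (CBI). The default grid —
RM 0.5 to 4 in steps of 0.5 against the six sets L, LQ, LQH, H, LQHP,
LQHPT — gives 48 combinations; dropping RM = 0.5 gives 42.

Selection rule: among combinations with delta.AICc below the window
(default 2) that pass the AUC and CBI gates, take the smallest
delta.AICc, tie-breaking by smaller AUC.diff, then smaller OR10, then
smaller RM, then fewer feature classes. If no combination passes the
gates, the same ordering is applied to all combinations with a defined
AICc and the relaxation is recorded in the trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .evaluation import EvaluationReport, Partition, evaluate

DEFAULT_RM_VALUES = tuple(np.arange(0.5, 4.01, 0.5))
DEFAULT_FC_SETS = ("L", "LQ", "LQH", "H", "LQHP", "LQHPT")


@dataclass
class TuningGrid:
    rm_values: tuple[float, ...] = DEFAULT_RM_VALUES
    fc_sets: tuple[str, ...] = DEFAULT_FC_SETS

    def __post_init__(self) -> None:
        if not self.rm_values or not self.fc_sets:
            raise ValueError("tuning grid must be nonempty")

    @property
    def size(self) -> int:
        return len(self.rm_values) * len(self.fc_sets)

    def combos(self):
        for rm in self.rm_values:
            for fc in self.fc_sets:
                yield float(rm), fc


@dataclass
class TuningResult:
    reports: dict[tuple[float, str], EvaluationReport]
    selected: tuple[float, str] | None = None
    trace: list[str] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        rows = []
        for (rm, fc), rep in self.reports.items():
            row = {"rm": rm, "fc": fc}
            row.update(rep.as_dict())
            rows.append(row)
        return pd.DataFrame(rows).sort_values(["rm", "fc"]).reset_index(drop=True)


def run_grid(presence_env: Mapping[str, np.ndarray],
             background_env: Mapping[str, np.ndarray],
             grid: TuningGrid, partition: Partition,
             transform: str = "cloglog", **fit_kw) -> TuningResult:
    """Evaluate every grid combination and fill delta.AICc."""
    reports = {}
    for rm, fc in grid.combos():
        reports[(rm, fc)] = evaluate(presence_env, background_env, fc, rm,
                                     partition, transform=transform, **fit_kw)
    aiccs = [r.aicc for r in reports.values() if np.isfinite(r.aicc)]
    best = min(aiccs) if aiccs else float("nan")
    for rep in reports.values():
        rep.delta_aicc = rep.aicc - best if np.isfinite(rep.aicc) else float("nan")
    return TuningResult(reports)


def select_best(result: TuningResult, auc_min: float = 0.9, cbi_min: float = 0.5,
                delta_window: float = 2.0) -> TuningResult:
    """Apply the gated minimum-AICc selection rule; returns the result
    with ``selected`` and a trace of which rules fired."""
    defined = {k: r for k, r in result.reports.items() if np.isfinite(r.delta_aicc)}
    if not defined:
        raise ValueError("no parameter combination has a defined AICc")
    trace = list(result.trace)

    def order_key(item):
        (rm, fc), r = item
        return (r.delta_aicc, r.auc_diff, r.or10, rm, len(fc))

    gated = {
        k: r for k, r in defined.items()
        if r.delta_aicc < delta_window and r.auc_test > auc_min
        and np.isfinite(r.cbi) and r.cbi > cbi_min
    }
    if gated:
        pool = gated
        trace.append(
            f"gates_applied: delta_aicc<{delta_window}, auc_test>{auc_min}, "
            f"cbi>{cbi_min} -> {len(gated)} candidate(s)"
        )
    else:
        pool = defined
        trace.append("gates_relaxed: no combination passed all gates; "
                     "selecting by ordering over all defined-AICc combinations")
    selected = min(pool.items(), key=order_key)[0]
    trace.append(f"selected: rm={selected[0]}, fc={selected[1]}")
    return TuningResult(result.reports, selected, trace)
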