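"""Model families A-E and the incremental misclassification-cost sweep.

Each family fixes which predictors the tree may use and how deep it may
grow.  Family A uses the MPDS dispatch code alone (depth 1, the "usual
state" of a dispatch system); B forces the MPDS code at the root and adds a
small crash-characteristic set at depth <= 3; C uses crash characteristics
only at depth <= 3; D forces the MPDS code at the root over the full
characteristic set with unlimited depth; E is the full characteristic set
with unlimited depth and no forced root.

Because misclassification costs affect only leaf classification, each
family grows one tree which is then swept over integer cost ratios
1:1, 1:2, ... until the under-triage rate reaches 0% (all crashes
dispatched L&S) or a safety cap is hit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chaid import ChaidConfig, ChaidTree, grow
from .evaluate import (AcsCotCriteria, ConfusionMatrix, EvaluationRow,
                       TriageRates, select_model)
from .records import Dataset

#: Crash-characteristic candidate lists per family (schema order).
FAMILY_B_VARS = ["anyone_trapped", "vulnerable_road_user", "airbag_deployed",
                 "atmosphere", "road_surface"]
FAMILY_C_VARS = ["anyone_trapped", "vulnerable_road_user", "anyone_not_ambulant",
                 "atmosphere", "accident_type"]
FAMILY_D_VARS = ["anyone_trapped", "vulnerable_road_user", "older", "day_of_week",
                 "single_v_multi_vehicle", "airbag_deployed", "atmosphere",
                 "road_surface", "lighting", "accident_type"]


@dataclass(frozen=True)
class ModelFamily:
    id: str
    variables: tuple[str, ...]
    forced_first: Optional[str]
    max_depth: Optional[int]  # None = unlimited

    def config(self, base: ChaidConfig) -> ChaidConfig:
        variables = list(self.variables)
        if self.forced_first and self.forced_first not in variables:
            variables = [self.forced_first] + variables
        return replace(base, candidate_variables=variables,
                       forced_first_variable=self.forced_first,
                       max_depth=self.max_depth)


def default_families() -> list[ModelFamily]:
    mpds = Dataset.MPDS
    return [
        ModelFamily("A", (mpds,), forced_first=mpds, max_depth=1),
        ModelFamily("B", tuple([mpds] + FAMILY_B_VARS), forced_first=mpds, max_depth=3),
        ModelFamily("C", tuple(FAMILY_C_VARS), forced_first=None, max_depth=3),
        ModelFamily("D", tuple([mpds] + FAMILY_D_VARS), forced_first=mpds, max_depth=None),
        ModelFamily("E", tuple(FAMILY_D_VARS), forced_first=None, max_depth=None),
    ]


@dataclass
class SweepResult:
    family: ModelFamily
    tree: ChaidTree
    rows: list[EvaluationRow]
    terminated_at: Optional[int]  # first ratio reaching under-triage 0%
    capped: bool = False


def sweep(family: ModelFamily, data: Dataset, config: ChaidConfig,
          max_ratio: int = 100) -> SweepResult:
    """Grow the family's tree once and sweep integer cost ratios.

    Stops at the first ratio with 0% under-triage; if ``max_ratio`` is hit
    first the result is flagged ``capped`` rather than failing silently.
    """
    if max_ratio < 1:
        raise ValueError("max_ratio must be >= 1")
    tree = grow(data, family.config(config))
    leaf_ids = tree.assign_leaves(data)
    y = data.labels()
    # per-node evaluation counts and training positive share
    ids = np.array([n.id for n in tree.nodes])
    e0 = np.array([int(((leaf_ids == i) & (y == 0)).sum()) for i in ids])
    e1 = np.array([int(((leaf_ids == i) & (y == 1)).sum()) for i in ids])
    p_hat = np.array([n.p_ls for n in tree.nodes])

    rows: list[EvaluationRow] = []
    terminated_at: Optional[int] = None
    for k in range(1, max_ratio + 1):
        positive = p_hat * k >= (1.0 - p_hat)  # ties predict L&S
        m = ConfusionMatrix(
            tp=int(e1[positive].sum()), fp=int(e0[positive].sum()),
            tn=int(e0[~positive].sum()), fn=int(e1[~positive].sum()),
        )
        rows.append(EvaluationRow(family.id, tree.depth, k, TriageRates.from_matrix(m)))
        if rows[-1].rates.under_triage_pct == 0.0:
            terminated_at = k
            break
    return SweepResult(family, tree, rows, terminated_at,
                       capped=terminated_at is None)


def _collapse(rows: Sequence[EvaluationRow]) -> list[tuple[str, EvaluationRow]]:
    """Merge consecutive ratios whose rates agree to one decimal place."""
    out: list[tuple[int, int, EvaluationRow]] = []
    for row in rows:
        key = (round(row.rates.over_triage_pct, 1), round(row.rates.under_triage_pct, 1))
        if out:
            lo, hi, head = out[-1]
            head_key = (round(head.rates.over_triage_pct, 1),
                        round(head.rates.under_triage_pct, 1))
            if key == head_key and row.cost_ratio == hi + 1:
                out[-1] = (lo, row.cost_ratio, head)
                continue
        out.append((row.cost_ratio, row.cost_ratio, row))
    return [
        (f"1:{lo}" if lo == hi else f"1:{lo} to 1:{hi}", head)
        for lo, hi, head in out
    ]


def report_frame(results: Sequence[SweepResult],
                 criteria: AcsCotCriteria = AcsCotCriteria()) -> pd.DataFrame:
    """Sweep report: one line per distinct rate pattern per family."""
    lines = []
    for res in results:
        depth = res.tree.depth
        depth_label = str(depth) if res.family.max_depth is not None else f"Unlimited ({depth})"
        for costs, row in _collapse(res.rows):
            lines.append({
                "Depth": depth_label,
                "Model": res.family.id,
                "Misclassification costs": costs,
                "Over triage (%)": round(row.rates.over_triage_pct, 1),
                "Under triage (%)": round(row.rates.under_triage_pct, 1),
                "ACS COT compliant": criteria.compliant(row.rates),
            })
    return pd.DataFrame(lines)


def scatter_frame(results: Sequence[SweepResult]) -> pd.DataFrame:
    """Per-(family, ratio) over/under rates for trade-off scatter plots."""
    return pd.DataFrame([
        {
            "family": res.family.id,
            "cost_ratio": row.cost_ratio,
            "over_triage_pct": row.rates.over_triage_pct,
            "under_triage_pct": row.rates.under_triage_pct,
        }
        for res in results for row in res.rows
    ])


@dataclass
class RunReport:
    results: list[SweepResult]
    report: pd.DataFrame
    scatter: pd.DataFrame
    selected: Optional[EvaluationRow]
    compliance: list[bool]


def run_all_families(data: Dataset, config: ChaidConfig,
                     criteria: AcsCotCriteria = AcsCotCriteria(),
                     families: Optional[Sequence[ModelFamily]] = None,
                     max_ratio: int = 100) -> RunReport:
    """Sweep every model family and select the best row against ACS COT."""
    families = list(families) if families is not None else default_families()
    results = [sweep(f, data, config, max_ratio=max_ratio) for f in families]
    all_rows = [row for res in results for row in res.rows]
    selected, flags = select_model(all_rows, criteria)
    for row, flag in zip(all_rows, flags):
        row.compliant = flag
    return RunReport(results, report_frame(results, criteria),
                     scatter_frame(results), selected, flags)
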