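"""Over/under-triage rates and model selection against the ACS COT benchmark.

Over-triage is the share of predicted-L&S crashes that did not need an L&S
response (1 - positive predictive value); under-triage is the share of
predicted-not-L&S crashes that did need one (1 - negative predictive value).
The American College of Surgeons Committee on Trauma benchmark accepts an
under-triage rate of at most 5% with over-triage between 25% and 35%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts; positive class = L&S needed / predicted."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def degenerate_all_positive(self) -> bool:
        """No record predicted negative (everyone dispatched L&S)."""
        return self.tn + self.fn == 0


def confusion(predictions: Sequence[int], truth: Sequence[int]) -> ConfusionMatrix:
    pred = np.asarray(predictions, dtype=np.int64)
    y = np.asarray(truth, dtype=np.int64)
    if pred.shape != y.shape:
        raise ValueError("predictions and truth differ in length")
    if not (np.isin(pred, (0, 1)).all() and np.isin(y, (0, 1)).all()):
        raise ValueError("labels must be binary 0/1")
    return ConfusionMatrix(
        tp=int(((pred == 1) & (y == 1)).sum()),
        fp=int(((pred == 1) & (y == 0)).sum()),
        tn=int(((pred == 0) & (y == 0)).sum()),
        fn=int(((pred == 0) & (y == 1)).sum()),
    )


def over_triage(m: ConfusionMatrix) -> float:
    """100 * fp / (fp + tp); 0 when nothing is predicted positive."""
    denom = m.fp + m.tp
    return 100.0 * m.fp / denom if denom else 0.0


def under_triage(m: ConfusionMatrix) -> float:
    """100 * fn / (fn + tn); 0 when everything is predicted positive."""
    denom = m.fn + m.tn
    return 100.0 * m.fn / denom if denom else 0.0


@dataclass(frozen=True)
class TriageRates:
    over_triage_pct: float
    under_triage_pct: float
    matrix: ConfusionMatrix

    @classmethod
    def from_matrix(cls, m: ConfusionMatrix) -> "TriageRates":
        return cls(over_triage(m), under_triage(m), m)


@dataclass(frozen=True)
class AcsCotCriteria:
    """ACS COT field-triage benchmark (configurable bounds)."""

    max_under_pct: float = 5.0
    over_range_pct: tuple[float, float] = (25.0, 35.0)

    def __post_init__(self) -> None:
        lo, hi = self.over_range_pct
        if lo > hi:
            raise ValueError("over-triage range bounds out of order")

    def compliant(self, rates: TriageRates) -> bool:
        lo, hi = self.over_range_pct
        return (rates.under_triage_pct <= self.max_under_pct
                and lo <= rates.over_triage_pct <= hi)


@dataclass
class EvaluationRow:
    """One line of the sweep report: a model family at one cost ratio."""

    family: str
    depth: int
    cost_ratio: int
    rates: TriageRates
    compliant: Optional[bool] = field(default=None)


def select_model(rows: Sequence[EvaluationRow],
                 criteria: AcsCotCriteria = AcsCotCriteria(),
                 ) -> tuple[Optional[EvaluationRow], list[bool]]:
    """Pick the row closest to the ACS COT prescription.

    Emergency dispatch is "front loaded": a low under-triage rate outranks
    over-triage.  Degenerate all-positive rows (under-triage 0% only because
    nothing is predicted negative) are excluded; among the rest with
    under-triage within the benchmark, the minimum under-triage wins, ties
    broken by minimum over-triage.  Also returns per-row compliance flags
    against the full benchmark (under <= max AND over within range).
    """
    if not rows:
        raise ValueError("no rows to select from")
    flags = [criteria.compliant(r.rates) for r in rows]
    eligible = [
        r for r in rows
        if not r.rates.matrix.degenerate_all_positive
        and r.rates.under_triage_pct <= criteria.max_under_pct
    ]
    if not eligible:
        return None, flags
    chosen = min(eligible, key=lambda r: (r.rates.under_triage_pct,
                                          r.rates.over_triage_pct))
    return chosen, flags
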