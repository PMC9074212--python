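"""Embedded marginal tables from the source study.

Two marginal tables are shipped as package data and drive both the test
oracles and the synthetic-data generator:

* the MPDS Protocol 29 dispatch-code table — (code x outcome) counts for all
  11,971 crashes, split into 10,200 not needing and 1,771 needing an L&S
  response; these counts sum exactly to the totals;
* the crash-characteristic table — per-variable (category x outcome) counts;
  characteristic blocks may sum to less than the cohort because of
  item-level missing data (e.g. the accident-type block covers only two
  thirds of crashes).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

TOTAL_NOT_LS = 10_200
TOTAL_LS = 1_771
TOTAL_N = 11_971


@dataclass(frozen=True)
class MarginalRow:
    variable: str
    category: str
    not_ls: int
    ls: int

    @property
    def total(self) -> int:
        return self.not_ls + self.ls


@dataclass(frozen=True)
class MarginalFixture:
    """(category x outcome) counts for one or more variables."""

    rows: tuple[MarginalRow, ...]
    totals: tuple[int, int, int] = (TOTAL_NOT_LS, TOTAL_LS, TOTAL_N)

    def block(self, variable: str) -> list[MarginalRow]:
        rows = [r for r in self.rows if r.variable == variable]
        if not rows:
            raise KeyError(f"no fixture block for variable {variable!r}")
        return rows

    def variables(self) -> list[str]:
        seen: list[str] = []
        for r in self.rows:
            if r.variable not in seen:
                seen.append(r.variable)
        return seen

    def block_total(self, variable: str) -> int:
        return sum(r.total for r in self.block(variable))

    def missing_rate(self, variable: str) -> float:
        """Share of the cohort with no recorded value for this variable."""
        return 1.0 - self.block_total(variable) / self.totals[2]

    def row(self, variable: str, category: str) -> MarginalRow:
        for r in self.block(variable):
            if r.category == category:
                return r
        raise KeyError(f"no category {category!r} under {variable!r}")


def _read(name: str) -> pd.DataFrame:
    with resources.files("mvctriage.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_table2_fixture() -> MarginalFixture:
    """MPDS dispatch-code counts; sums exactly to (10,200, 1,771, 11,971)."""
    df = _read("mpds_code_counts.csv")
    rows = tuple(
        MarginalRow("mpds_code", r.code, int(r.not_ls), int(r.ls))
        for r in df.itertuples()
    )
    n0 = sum(r.not_ls for r in rows)
    n1 = sum(r.ls for r in rows)
    assert (n0, n1) == (TOTAL_NOT_LS, TOTAL_LS), "embedded dispatch-code table corrupt"
    return MarginalFixture(rows)


def load_table3_fixture() -> MarginalFixture:
    """Crash-characteristic counts; blocks may undershoot the cohort total."""
    df = _read("crash_characteristic_counts.csv")
    rows = tuple(
        MarginalRow(r.variable, r.category, int(r.not_ls), int(r.ls))
        for r in df.itertuples()
    )
    return MarginalFixture(rows)
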