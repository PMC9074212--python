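"""Synthetic crash datasets with the statistical structure the analysis
assumes.

Three modes are provided:

* ``fixture-faithful`` — exactly 11,971 crashes whose joint (MPDS code x
  outcome) counts equal the embedded dispatch-code table; crash
  characteristics are drawn class-conditionally from the characteristic
  table, including its item-level missingness.  Only row order depends on
  the seed.
* ``marginal-independent`` — n crashes with features drawn from the pooled
  marginals, independent of the outcome (a null dataset: no real signal).
* ``planted-tree`` — features drawn from the marginals and the outcome
  drawn from a per-leaf probability of a user-specified decision tree,
  giving the tree grower a recoverable ground truth.

The real joint dependence between crash characteristics is unknown; the
class-conditional mode reproduces every printed marginal while assuming
characteristics are independent given the outcome.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fixtures import TOTAL_LS, TOTAL_N, TOTAL_NOT_LS, load_table2_fixture, load_table3_fixture
from .records import Dataset, VariableSpec, from_frame, table1_schema

MODES = ("fixture-faithful", "marginal-independent", "planted-tree")

#: Plausible label-independent marginals for variables the characteristic
#: table does not print (urban road network, commuter-peaked call volume).
EXTRA_MARGINALS: dict[str, dict[str, float]] = {
    "raining": {"Raining": 0.09, "Clear": 0.91},
    "speed_limit": {"50": 0.33, "60": 0.28, "70": 0.10, "80": 0.14,
                    "90": 0.05, "100": 0.06, "110": 0.04},
    "traffic_control": {"Traffic lights": 0.25, "Stop sign": 0.08,
                        "Give way sign": 0.12, "Zebra crossing": 0.02,
                        "Railway crossing": 0.01, "School crossing": 0.01,
                        "No signal or control": 0.51},
    "type_of_intersection": {"4-way": 0.35, "3-way (T-junction)": 0.40,
                             "Roundabout": 0.15, "Bridge": 0.02,
                             "Rail Crossing": 0.01, "Driveway": 0.07},
}


@dataclass
class GeneratorConfig:
    n: int = TOTAL_N
    seed: int = 0
    mode: str = "fixture-faithful"
    #: per-variable missing rates; None = derive from the characteristic
    #: table's block deficits (fixture-faithful draws handle this natively).
    missingness: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        for name, rate in (self.missingness or {}).items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missing rate for {name!r} outside [0, 1]")


def default_missingness() -> dict[str, float]:
    """Per-variable missing rates implied by the characteristic-table
    deficits (a block summing to less than the cohort is read as item-level
    missing data)."""
    t3 = load_table3_fixture()
    return {v: t3.missing_rate(v) for v in t3.variables()}


# ---------------------------------------------------------------------------
# Marginal draws

def _draw_time_of_day(rng: np.random.Generator, n: int) -> list[str]:
    """Minutes after midnight with commuter peaks, formatted hh:mm."""
    comp = rng.random(n)
    minutes = np.where(
        comp < 0.3, rng.normal(8.5 * 60, 75, n),
        np.where(comp < 0.65, rng.normal(17 * 60, 90, n), rng.uniform(0, 1440, n)),
    )
    minutes = np.clip(minutes, 0, 1439).astype(int)
    return [f"{m // 60:02d}:{m % 60:02d}" for m in minutes]


def _draw_categorical(rng: np.random.Generator, n: int,
                      categories: Sequence[str], probs: Sequence[float]) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    p = p / p.sum()
    return rng.choice(np.asarray(categories, dtype=object), size=n, p=p)


def _table3_conditional(variable: str, label: int) -> tuple[list[str], list[float]]:
    """Category labels + probabilities given the outcome class, with the
    missing label carrying the block's per-class deficit."""
    t3 = load_table3_fixture()
    block = t3.block(variable)
    class_total = TOTAL_LS if label == 1 else TOTAL_NOT_LS
    counts = [(r.ls if label == 1 else r.not_ls) for r in block]
    observed = sum(counts)
    cats = [r.category for r in block]
    probs = [c / class_total for c in counts]
    miss = 1.0 - observed / class_total
    return cats + [""], probs + [max(miss, 0.0)]


def _table3_pooled(variable: str) -> tuple[list[str], list[float]]:
    t3 = load_table3_fixture()
    block = t3.block(variable)
    cats = [r.category for r in block]
    probs = [r.total / TOTAL_N for r in block]
    miss = 1.0 - sum(probs)
    return cats + [""], probs + [max(miss, 0.0)]


def _fill_extras(df: pd.DataFrame, rng: np.random.Generator, n: int) -> None:
    for name, dist in EXTRA_MARGINALS.items():
        df[name] = _draw_categorical(rng, n, list(dist), list(dist.values()))
    df["time_of_day"] = _draw_time_of_day(rng, n)


# ---------------------------------------------------------------------------
# Samplers

def sample_fixture_faithful(seed: int, schema: Optional[list[VariableSpec]] = None) -> Dataset:
    """Exactly 11,971 crashes with the embedded (code x outcome) joint counts.

    The joint dispatch-code counts are deterministic; the seed controls the
    class-conditional characteristic draws and the final row shuffle.
    """
    rng = np.random.default_rng(seed)
    schema = schema if schema is not None else table1_schema()
    t2 = load_table2_fixture()

    codes, labels = [], []
    for row in t2.rows:
        codes += [row.category] * row.not_ls + [row.category] * row.ls
        labels += [0] * row.not_ls + [1] * row.ls
    codes = np.asarray(codes, dtype=object)
    labels = np.asarray(labels, dtype=np.int64)
    n = len(labels)

    df = pd.DataFrame({Dataset.MPDS: codes, Dataset.LABEL: labels})
    t3 = load_table3_fixture()
    for variable in t3.variables():
        col = np.empty(n, dtype=object)
        for lab in (0, 1):
            mask = labels == lab
            cats, probs = _table3_conditional(variable, lab)
            col[mask] = _draw_categorical(rng, int(mask.sum()), cats, probs)
        df[variable] = col
    _fill_extras(df, rng, n)

    order = rng.permutation(n)
    df = df.iloc[order].reset_index(drop=True)
    return from_frame(df, schema, unknown="error")


def sample_marginal_independent(config: GeneratorConfig,
                                schema: Optional[list[VariableSpec]] = None) -> Dataset:
    """n crashes whose features carry no information about the outcome."""
    rng = np.random.default_rng(config.seed)
    schema = schema if schema is not None else table1_schema()
    n = config.n
    t2 = load_table2_fixture()
    code_probs = [r.total / TOTAL_N for r in t2.rows]
    df = pd.DataFrame({
        Dataset.MPDS: _draw_categorical(rng, n, [r.category for r in t2.rows], code_probs),
        Dataset.LABEL: (rng.random(n) < TOTAL_LS / TOTAL_N).astype(np.int64),
    })
    t3 = load_table3_fixture()
    for variable in t3.variables():
        cats, probs = _table3_pooled(variable)
        df[variable] = _draw_categorical(rng, n, cats, probs)
    _fill_extras(df, rng, n)
    data = from_frame(df, schema, unknown="error")
    if config.missingness:
        data = apply_missingness(data, config)
    return data


# ---------------------------------------------------------------------------
# Planted trees

@dataclass
class PlantedBranch:
    categories: list[str]
    leaf_prob: Optional[float] = None
    subtree: Optional["PlantedTreeSpec"] = None

    def __post_init__(self) -> None:
        if (self.leaf_prob is None) == (self.subtree is None):
            raise ValueError("branch needs exactly one of leaf_prob / subtree")
        if self.leaf_prob is not None and not 0.0 <= self.leaf_prob <= 1.0:
            raise ValueError("leaf probability outside [0, 1]")


@dataclass
class PlantedTreeSpec:
    """Ground-truth decision tree: per-leaf outcome probabilities.

    Branches must partition the variable's declared categories, so every
    sampled (non-missing) feature vector reaches exactly one leaf.
    """

    variable: str
    branches: list[PlantedBranch] = field(default_factory=list)

    def validate(self, schema: Sequence[VariableSpec]) -> None:
        by_name = {v.name: v for v in schema}
        if self.variable not in by_name:
            raise ValueError(f"planted tree references unknown variable {self.variable!r}")
        declared = set(by_name[self.variable].categories)
        seen: set[str] = set()
        for b in self.branches:
            cats = set(b.categories)
            if cats & seen:
                raise ValueError(f"overlapping branch categories under {self.variable!r}")
            if not cats <= declared:
                raise ValueError(f"undeclared categories {cats - declared} under {self.variable!r}")
            seen |= cats
            if b.subtree is not None:
                b.subtree.validate(schema)
        if seen != declared:
            raise ValueError(f"branches do not cover all categories of {self.variable!r}")

    def variables(self) -> set[str]:
        out = {self.variable}
        for b in self.branches:
            if b.subtree is not None:
                out |= b.subtree.variables()
        return out

    def leaf_prob(self, features: dict[str, str]) -> float:
        value = features[self.variable]
        for b in self.branches:
            if value in b.categories:
                return b.leaf_prob if b.leaf_prob is not None else b.subtree.leaf_prob(features)
        raise KeyError(f"value {value!r} not covered under {self.variable!r}")

    def level1_splits(self) -> dict[tuple[str, ...], Optional[str]]:
        """Per root branch, the variable split directly beneath it (None for
        a leaf); used to check parameter recovery."""
        return {
            tuple(b.categories): (b.subtree.variable if b.subtree else None)
            for b in self.branches
        }

    # -- JSON --------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "branches": [
                {"categories": b.categories,
                 **({"leaf_prob": b.leaf_prob} if b.leaf_prob is not None
                    else {"subtree": b.subtree.to_dict()})}
                for b in self.branches
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "PlantedTreeSpec":
        branches = [
            PlantedBranch(
                categories=list(b["categories"]),
                leaf_prob=b.get("leaf_prob"),
                subtree=cls.from_dict(b["subtree"]) if "subtree" in b else None,
            )
            for b in payload["branches"]
        ]
        return cls(payload["variable"], branches)

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTreeSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


def sample_planted(spec: PlantedTreeSpec, config: GeneratorConfig,
                   schema: Optional[list[VariableSpec]] = None) -> Dataset:
    """Features from the marginals, outcome from the planted tree's leaves."""
    rng = np.random.default_rng(config.seed)
    schema = schema if schema is not None else table1_schema()
    spec.validate(schema)
    n = config.n
    t2 = load_table2_fixture()
    t3 = load_table3_fixture()
    t3_vars = set(t3.variables())

    df = pd.DataFrame({
        Dataset.MPDS: _draw_categorical(
            rng, n, [r.category for r in t2.rows], [r.total / TOTAL_N for r in t2.rows]),
    })
    for variable in t3.variables():
        cats, probs = _table3_pooled(variable)
        # planted draws are fully observed; missingness is applied afterwards
        df[variable] = _draw_categorical(rng, n, cats[:-1], probs[:-1])
    _fill_extras(df, rng, n)
    for variable in spec.variables():
        if variable not in df.columns:
            raise ValueError(f"planted variable {variable!r} not generated")
        if variable not in t3_vars and variable not in EXTRA_MARGINALS \
                and variable != Dataset.MPDS:
            raise ValueError(f"no marginal distribution for {variable!r}")

    probs = np.empty(n, dtype=float)

    def assign(node: PlantedTreeSpec, idx: np.ndarray) -> None:
        col = df[node.variable].to_numpy()
        for branch in node.branches:
            sub = idx[np.isin(col[idx], branch.categories)]
            if branch.leaf_prob is not None:
                probs[sub] = branch.leaf_prob
            else:
                assign(branch.subtree, sub)

    assign(spec, np.arange(n))
    df[Dataset.LABEL] = (rng.random(n) < probs).astype(np.int64)
    data = from_frame(df, schema, unknown="error")
    if config.missingness:
        data = apply_missingness(data, config)
    return data


def apply_missingness(data: Dataset, config: GeneratorConfig) -> Dataset:
    """Independently blank each feature at its configured rate.

    Labels and the MPDS code are never blanked.  The seed stream is offset
    from the sampling seed so the same config does not reuse draws.
    """
    rates = config.missingness if config.missingness is not None else default_missingness()
    rng = np.random.default_rng((config.seed, 0x6D697373))
    records = []
    n = len(data)
    masks = {
        name: rng.random(n) < rate
        for name, rate in rates.items() if rate > 0
    }
    for i, rec in enumerate(data.records):
        feats = dict(rec.features)
        for name, mask in masks.items():
            if mask[i] and name in feats:
                feats[name] = data.variable(name).missing_label
        records.append(type(rec)(rec.mpds_code, feats, rec.clinical, rec.label))
    return Dataset(data.schema, records, validate=False)


def sample(config: GeneratorConfig,
           spec: Optional[PlantedTreeSpec] = None,
           schema: Optional[list[VariableSpec]] = None) -> Dataset:
    """Dispatch on ``config.mode``."""
    if config.mode == "fixture-faithful":
        return sample_fixture_faithful(config.seed, schema=schema)
    if config.mode == "marginal-independent":
        return sample_marginal_independent(config, schema=schema)
    if spec is None:
        raise ValueError("planted-tree mode needs a PlantedTreeSpec")
    return sample_planted(spec, config, schema=schema)
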