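"""Chi-square Automatic Interaction Detection (CHAID) with misclassification
costs.

CHAID grows a multi-way decision tree over categorical predictors.  At each
node, every candidate variable's categories are first greedily merged:
the pair of groups whose 2x2 (group x outcome) subtable is least
significant is merged while its Pearson chi-square p-value exceeds
``alpha_merge`` (adjacent groups only for ordinal variables; a floating
missing-value group may merge with any group).  Each merged grouping is then
scored by the Pearson chi-square of its r x 2 table against the binary
outcome, with a Bonferroni multiplier counting the number of ways the
original categories could have produced an r-group split.  The variable
with the smallest adjusted p-value splits the node, provided it clears
``alpha_split`` and the minimum child size.

Misclassification costs enter only at classification time: a leaf with
outcome-positive share p predicts the positive class whenever
``p * c_fn >= (1 - p) * c_fp``, i.e. whenever the expected cost of a missed
positive outweighs the expected cost of a false alarm.  Ties predict
positive (safety-first).  Growth itself is cost-free, so a single tree per
model family can be swept over cost ratios.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from fractions import Fraction
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.stats import chi2 as _chi2_dist

from .records import MISSING, CrashRecord, Dataset, SchemaError


# ---------------------------------------------------------------------------
# Configuration and costs

@dataclass(frozen=True)
class CostMatrix:
    """Misclassification costs: predicting L&S when not needed (``c_fp``)
    versus missing a needed L&S response (``c_fn``).

    The ratio notation "1:k" of the sweep means ``CostMatrix(1, k)``.
    """

    c_fp: float = 1.0
    c_fn: float = 1.0

    def __post_init__(self) -> None:
        if self.c_fp <= 0 or self.c_fn <= 0:
            raise ValueError("misclassification costs must be positive")

    @classmethod
    def from_ratio(cls, k: float) -> "CostMatrix":
        return cls(1.0, float(k))

    @property
    def ratio(self) -> float:
        return self.c_fn / self.c_fp


@dataclass
class ChaidConfig:
    """Growth controls.

    Defaults follow the common SPSS Decision Trees settings: merge and split
    significance 0.05, minimum parent node 100, minimum child node 50.
    ``max_depth=None`` means unlimited.  When ``forced_first_variable`` is
    set, the root may split only on that variable (deeper nodes use the full
    candidate list).
    """

    alpha_merge: float = 0.05
    alpha_split: float = 0.05
    max_depth: Optional[int] = None
    min_parent: int = 100
    min_child: int = 50
    forced_first_variable: Optional[str] = None
    candidate_variables: Optional[list[str]] = None

    def __post_init__(self) -> None:
        for a in (self.alpha_merge, self.alpha_split):
            if not (0 < a <= 1):
                raise ValueError("significance levels must be in (0, 1]")
        if self.min_child > self.min_parent:
            raise ValueError("min_child must not exceed min_parent")
        if self.max_depth is not None and self.max_depth < 1:
            raise ValueError("max_depth must be positive")


# ---------------------------------------------------------------------------
# Chi-square machinery

def pearson_chi_square(table) -> tuple[float, int, float]:
    """Pearson chi-square of an r x 2 contingency table.

    Returns ``(statistic, df, p)`` with ``df = r - 1`` and the upper-tail
    chi-square probability.  Cells whose expected count is zero (an all-zero
    column or row) contribute nothing; a table with no association at all
    returns ``(0.0, df, 1.0)``.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 1 or t.shape[1] != 2:
        raise ValueError("expected an r x 2 table with r >= 1")
    if np.any(t < 0):
        raise ValueError("negative counts")
    total = t.sum()
    if total <= 0:
        raise ValueError("empty contingency table")
    row = t.sum(axis=1, keepdims=True)
    col = t.sum(axis=0, keepdims=True)
    expected = row @ col / total
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(expected > 0, (t - expected) ** 2 / expected, 0.0)
    x2 = float(contrib.sum())
    df = t.shape[0] - 1
    if df == 0 or x2 == 0.0:
        return x2, df, 1.0
    return x2, df, float(_chi2_dist.sf(x2, df))


def _p_2x2(a: np.ndarray, b: np.ndarray) -> float:
    """Raw p of the 2x2 table stacking two (n0, n1) count pairs."""
    n1, n2 = a.sum(), b.sum()
    c0, c1 = a[0] + b[0], a[1] + b[1]
    total = n1 + n2
    if n1 == 0 or n2 == 0 or c0 == 0 or c1 == 0:
        return 1.0
    x2 = total * (a[0] * b[1] - a[1] * b[0]) ** 2 / (n1 * n2 * c0 * c1)
    if x2 == 0.0:
        return 1.0
    return float(_chi2_dist.sf(x2, 1))


def bonferroni_multiplier(c: int, r: int, kind: str) -> int:
    """Number of distinct reductions of ``c`` observed categories to ``r``
    groups, used as the Bonferroni multiplier for a split's p-value.

    ``nominal``: the Stirling number of the second kind S(c, r) via the
    alternating sum ``sum_i (-1)^i (r-i)^c / (i! (r-i)!)``.
    ``ordinal``: contiguous partitions only, ``C(c-1, r-1)``.
    """
    if not 1 <= r <= c:
        raise ValueError(f"need 1 <= r <= c, got r={r}, c={c}")
    if kind == "ordinal":
        return math.comb(c - 1, r - 1)
    if kind == "nominal":
        total = Fraction(0)
        for i in range(r):
            term = Fraction((r - i) ** c, math.factorial(i) * math.factorial(r - i))
            total += -term if i % 2 else term
        assert total.denominator == 1
        return int(total)
    raise ValueError(f"unknown kind {kind!r}")


# ---------------------------------------------------------------------------
# Category merging

@dataclass(frozen=True)
class MergedGrouping:
    """A partition of a variable's observed categories into merged groups.

    Groups are ordered by their first category's declared position; for an
    ordinal variable every group is a contiguous run of the category order
    (the floating missing-value category is exempt from adjacency).
    """

    variable: str
    groups: tuple[tuple[str, ...], ...]
    ordinal_contiguous: bool = False

    @property
    def r(self) -> int:
        return len(self.groups)


@dataclass(frozen=True)
class SplitCandidate:
    grouping: MergedGrouping
    chi2: float
    df: int
    raw_p: float
    bonferroni: int
    adjusted_p: float


class _Group:
    __slots__ = ("cats", "counts", "floating", "lo", "hi")

    def __init__(self, cat: int, counts: np.ndarray, floating: bool):
        self.cats = [cat]
        self.counts = counts
        self.floating = floating
        self.lo = self.hi = cat

    def absorb(self, other: "_Group") -> None:
        self.cats += other.cats
        self.counts = self.counts + other.counts
        if not other.floating:
            if self.floating:
                self.lo, self.hi = other.lo, other.hi
            else:
                self.lo, self.hi = min(self.lo, other.lo), max(self.hi, other.hi)
            self.floating = False


def _allowable_pairs(groups: list[_Group], is_ordinal: bool):
    """Index pairs that may merge, in a deterministic order."""
    ordered = sorted(range(len(groups)), key=lambda g: (groups[g].floating, groups[g].lo))
    for ai in range(len(ordered)):
        for bi in range(ai + 1, len(ordered)):
            i, j = ordered[ai], ordered[bi]
            if is_ordinal and not (groups[i].floating or groups[j].floating):
                # adjacency: consecutive non-floating groups in span order
                if bi != ai + 1:
                    continue
            yield i, j


def _merge_engine(counts: np.ndarray, is_ordinal: bool, missing_row: Optional[int],
                  alpha_merge: float, min_group: int = 0) -> list[list[int]]:
    """Greedy agglomeration over observed category rows of an r x 2 table.

    Returns groups as lists of row indices.  At each step the allowable pair
    with the largest raw 2x2 p-value merges, while that p exceeds
    ``alpha_merge``.  Ordinal variables only merge groups adjacent in
    category order; the missing-value group floats and may pair with any.
    After the significance-driven phase, any group smaller than
    ``min_group`` is merged with its most similar allowable partner so that
    rare categories cannot block a split on child-size grounds.
    """
    groups = [
        _Group(i, counts[i].astype(float), floating=(is_ordinal and i == missing_row))
        for i in range(counts.shape[0])
    ]
    while len(groups) > 1:
        best_pair, best_p = None, -1.0
        for i, j in _allowable_pairs(groups, is_ordinal):
            p = _p_2x2(groups[i].counts, groups[j].counts)
            if p > best_p:
                best_pair, best_p = (i, j), p
        if best_pair is None or best_p <= alpha_merge:
            break
        i, j = best_pair
        groups[i].absorb(groups[j])
        del groups[j]
    while min_group > 0 and len(groups) > 1:
        small = min(range(len(groups)), key=lambda g: (groups[g].counts.sum(), g))
        if groups[small].counts.sum() >= min_group:
            break
        best_pair, best_p = None, -1.0
        for i, j in _allowable_pairs(groups, is_ordinal):
            if small not in (i, j):
                continue
            p = _p_2x2(groups[i].counts, groups[j].counts)
            if p > best_p:
                best_pair, best_p = (i, j), p
        if best_pair is None:
            break
        i, j = best_pair
        groups[i].absorb(groups[j])
        del groups[j]
    groups.sort(key=lambda g: (g.floating, g.lo))
    return [sorted(g.cats) for g in groups]


def merge_categories(variable: str, categories: Sequence[str], counts,
                     kind: str, config: ChaidConfig,
                     missing_label: str = MISSING,
                     min_group: int = 0) -> MergedGrouping:
    """Merge one variable's observed categories at a node.

    ``categories`` are the observed category labels (ordinals in declared
    order) and ``counts`` the parallel (not-positive, positive) pairs.
    ``min_group`` > 0 additionally merges undersized groups with their most
    similar allowable partner (tree growth passes ``config.min_child``).
    """
    counts = np.asarray(counts, dtype=np.int64)
    if counts.shape != (len(categories), 2):
        raise ValueError("counts must be (n_categories, 2)")
    is_ordinal = kind in ("ordinal", "continuous")
    missing_row = None
    if missing_label in categories:
        missing_row = list(categories).index(missing_label)
    idx_groups = _merge_engine(counts, is_ordinal, missing_row, config.alpha_merge,
                               min_group=min_group)
    groups = tuple(tuple(categories[i] for i in g) for g in idx_groups)
    return MergedGrouping(variable, groups, ordinal_contiguous=is_ordinal)


# ---------------------------------------------------------------------------
# Tree structures

@dataclass
class TreeNode:
    id: int
    depth: int
    n0: int
    n1: int
    variable: Optional[str] = None
    groups: Optional[list[list[str]]] = None
    children: Optional[list[int]] = None
    adjusted_p: Optional[float] = None
    chi2: Optional[float] = None

    @property
    def is_leaf(self) -> bool:
        return self.variable is None

    @property
    def n(self) -> int:
        return self.n0 + self.n1

    @property
    def p_ls(self) -> float:
        return self.n1 / self.n if self.n else 0.0


class ChaidTree:
    """A grown CHAID tree: nodes in breadth-first order, node 0 the root."""

    def __init__(self, nodes: list[TreeNode], config: ChaidConfig):
        if not nodes:
            raise ValueError("a tree has at least one node")
        self.nodes = nodes
        self.config = config

    # -- structure ---------------------------------------------------------
    @property
    def root(self) -> TreeNode:
        return self.nodes[0]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def leaves(self) -> list[TreeNode]:
        return [n for n in self.nodes if n.is_leaf]

    @property
    def depth(self) -> int:
        return max(n.depth for n in self.nodes)

    # -- routing and prediction -------------------------------------------
    def route(self, features: dict[str, str]) -> TreeNode:
        """Walk a record to its leaf.

        A value not covered by any merged group (missing, or unseen at
        training time) follows the group containing the missing label; if
        no group holds it, routing stops at the current node and its class
        distribution is used.
        """
        node = self.nodes[0]
        while not node.is_leaf:
            value = features.get(node.variable, MISSING)
            nxt = None
            for gi, group in enumerate(node.groups):
                if value in group:
                    nxt = node.children[gi]
                    break
            if nxt is None:
                for gi, group in enumerate(node.groups):
                    if MISSING in group:
                        nxt = node.children[gi]
                        break
            if nxt is None:
                break
            node = self.nodes[nxt]
        return node

    def _features_of(self, record: CrashRecord) -> dict[str, str]:
        feats = dict(record.features)
        feats[Dataset.MPDS] = record.mpds_code
        return feats

    def classify(self, record: CrashRecord, costs: CostMatrix) -> int:
        """Cost-sensitive prediction: positive iff p*c_fn >= (1-p)*c_fp."""
        node = self.route(self._features_of(record))
        return int(node.p_ls * costs.c_fn >= (1.0 - node.p_ls) * costs.c_fp)

    def assign_leaves(self, data: Dataset) -> np.ndarray:
        """Node id each record routes to (vector form of :meth:`route`)."""
        return np.array(
            [self.route(self._features_of(r)).id for r in data.records], dtype=np.int64
        )

    def predict(self, data: Dataset, costs: CostMatrix) -> np.ndarray:
        node_pred = {
            n.id: int(n.p_ls * costs.c_fn >= (1.0 - n.p_ls) * costs.c_fp)
            for n in self.nodes
        }
        return np.array([node_pred[i] for i in self.assign_leaves(data)], dtype=np.int64)

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "config": asdict(self.config),
            "nodes": [
                {
                    "id": n.id, "depth": n.depth, "n0": n.n0, "n1": n.n1,
                    "variable": n.variable, "groups": n.groups,
                    "children": n.children, "adjusted_p": n.adjusted_p,
                    "chi2": n.chi2,
                }
                for n in self.nodes
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ChaidTree":
        payload = json.loads(text)
        config = ChaidConfig(**payload["config"])
        nodes = [TreeNode(**entry) for entry in payload["nodes"]]
        return cls(nodes, config)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "ChaidTree":
        return cls.from_json(Path(path).read_text())

    def to_dot(self) -> str:
        """Graphviz DOT rendering with class counts and merged-group edges."""
        lines = ["digraph chaid {", "  node [shape=box];"]
        for n in self.nodes:
            label = f"node {n.id}\\nn={n.n} (L&S {n.n1})\\np(L&S)={n.p_ls:.3f}"
            if not n.is_leaf:
                label += f"\\nsplit: {n.variable}"
            lines.append(f'  n{n.id} [label="{label}"];')
        for n in self.nodes:
            if n.is_leaf:
                continue
            for group, child in zip(n.groups, n.children):
                edge = ", ".join(group)
                edge = edge.replace('"', "'")
                lines.append(f'  n{n.id} -> n{child} [label="{edge}"];')
        lines.append("}")
        return "\n".join(lines)


def export_tree(tree: ChaidTree, format: str = "json") -> str:
    if format == "json":
        return tree.to_json()
    if format == "dot":
        return tree.to_dot()
    raise ValueError(f"unknown export format {format!r}")


# ---------------------------------------------------------------------------
# Growth

class _Prep:
    """Integer-coded feature matrix for fast per-node contingency counts."""

    def __init__(self, data: Dataset, variables: Sequence[str]):
        frame = data.frame()
        self.y = data.labels()
        self.variables = list(variables)
        self.codes: dict[str, np.ndarray] = {}
        self.cats: dict[str, list[str]] = {}
        self.kinds: dict[str, str] = {}
        for name in variables:
            spec = data.variable(name)
            cats = list(spec.categories) + [spec.missing_label]
            lookup = {c: i for i, c in enumerate(cats)}
            col = frame[name].to_numpy()
            try:
                self.codes[name] = np.array([lookup[v] for v in col], dtype=np.int64)
            except KeyError as exc:
                raise SchemaError(f"undeclared category {exc} in variable {name!r}") from None
            self.cats[name] = cats
            self.kinds[name] = spec.kind

    def node_counts(self, name: str, idx: np.ndarray) -> np.ndarray:
        ncat = len(self.cats[name])
        flat = np.bincount(self.codes[name][idx] * 2 + self.y[idx], minlength=2 * ncat)
        return flat.reshape(ncat, 2)


def _candidate_for(prep: _Prep, name: str, idx: np.ndarray,
                   config: ChaidConfig) -> Optional[SplitCandidate]:
    counts = prep.node_counts(name, idx)
    observed = np.flatnonzero(counts.sum(axis=1) > 0)
    if observed.size < 2:
        return None
    cats = [prep.cats[name][i] for i in observed]
    grouping = merge_categories(name, cats, counts[observed], prep.kinds[name], config,
                                min_group=config.min_child)
    if grouping.r < 2:
        return None
    lookup = {c: i for i, c in enumerate(cats)}
    grouped = np.array([
        counts[observed][[lookup[c] for c in group]].sum(axis=0)
        for group in grouping.groups
    ])
    if grouped.sum(axis=1).min() < config.min_child:
        return None
    x2, df, raw_p = pearson_chi_square(grouped)
    kind = "ordinal" if prep.kinds[name] in ("ordinal", "continuous") else "nominal"
    b = bonferroni_multiplier(len(cats), grouping.r, kind)
    adjusted = min(1.0, b * raw_p)
    return SplitCandidate(grouping, x2, df, raw_p, b, adjusted)


def best_split(prep: _Prep, idx: np.ndarray, depth: int,
               config: ChaidConfig) -> Optional[SplitCandidate]:
    """Most significant admissible split at a node, or None.

    Candidates violating the minimum child size are dropped; the remaining
    candidate with the smallest Bonferroni-adjusted p-value wins if it
    clears ``alpha_split``.  Ties break in declared candidate order.
    """
    if depth == 0 and config.forced_first_variable is not None:
        names = [config.forced_first_variable]
    else:
        names = config.candidate_variables or prep.variables
    best: Optional[SplitCandidate] = None
    for name in names:
        cand = _candidate_for(prep, name, idx, config)
        if cand is None or cand.adjusted_p > config.alpha_split:
            continue
        if best is None or cand.adjusted_p < best.adjusted_p:
            best = cand
    return best


def grow(data: Dataset, config: ChaidConfig) -> ChaidTree:
    """Grow a CHAID tree; deterministic given data and configuration."""
    if not data.labelled:
        raise ValueError("cannot grow a tree on unlabelled data")
    variables = config.candidate_variables or [v.name for v in data.schema]
    if config.forced_first_variable and config.forced_first_variable not in variables:
        variables = [config.forced_first_variable] + list(variables)
    prep = _Prep(data, variables)
    y = prep.y
    n1 = int(y.sum())
    nodes = [TreeNode(0, 0, len(y) - n1, n1)]
    queue: list[tuple[int, np.ndarray]] = [(0, np.arange(len(y), dtype=np.int64))]
    while queue:
        node_id, idx = queue.pop(0)
        node = nodes[node_id]
        if config.max_depth is not None and node.depth >= config.max_depth:
            continue
        if node.n < config.min_parent or node.n0 == 0 or node.n1 == 0:
            continue
        cand = best_split(prep, idx, node.depth, config)
        if cand is None:
            continue
        name = cand.grouping.variable
        lookup = {}
        for gi, group in enumerate(cand.grouping.groups):
            for cat in group:
                lookup[prep.cats[name].index(cat)] = gi
        membership = np.array([lookup.get(c, -1) for c in range(len(prep.cats[name]))])
        assignment = membership[prep.codes[name][idx]]
        node.variable = name
        node.groups = [list(g) for g in cand.grouping.groups]
        node.children = []
        node.adjusted_p = cand.adjusted_p
        node.chi2 = cand.chi2
        for gi in range(cand.grouping.r):
            child_idx = idx[assignment == gi]
            yc = y[child_idx]
            c1 = int(yc.sum())
            child = TreeNode(len(nodes), node.depth + 1, len(yc) - c1, c1)
            nodes.append(child)
            node.children.append(child.id)
            queue.append((child.id, child_idx))
    return ChaidTree(nodes, config)
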