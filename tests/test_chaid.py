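"""CHAID internals: chi-square, merging, Bonferroni, growth, cost rule."""

import itertools
import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

import mvctriage as mt
from mvctriage.chaid import _Prep, _candidate_for

from conftest import make_dataset, toy_schema


# ---------------------------------------------------------------------------
# Independent oracles

def oracle_merge(counts, kind, alpha):
    """Step-by-step re-execution of the greedy merge rule, coded separately
    from the implementation (scipy contingency test, explicit group lists)."""
    counts = np.asarray(counts)

    def table(g1, g2):
        return np.vstack([counts[g1].sum(axis=0), counts[g2].sum(axis=0)])

    def pval(t):
        if t[0].sum() == 0 or t[1].sum() == 0 or t[:, 0].sum() == 0 or t[:, 1].sum() == 0:
            return 1.0
        res = chi2_contingency(t, correction=False)
        return 1.0 if res.statistic == 0 else float(res.pvalue)

    groups = [[i] for i in range(len(counts))]
    while len(groups) > 1:
        groups.sort(key=min)
        best, best_p = None, -1.0
        for x in range(len(groups)):
            for y in range(x + 1, len(groups)):
                if kind == "ordinal" and y != x + 1:
                    continue
                p = pval(table(groups[x], groups[y]))
                if p > best_p:
                    best, best_p = (x, y), p
        if best is None or best_p <= alpha:
            break
        x, y = best
        groups[x] = sorted(groups[x] + groups[y])
        del groups[y]
    return sorted([sorted(g) for g in groups], key=min)


def set_partitions(elems):
    if not elems:
        yield []
        return
    first, rest = elems[0], elems[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [first]] + part[i + 1:]
        yield part + [[first]]


def run_merge(counts, kind, alpha=0.05):
    cats = [f"c{i}" for i in range(len(counts))]
    grouping = mt.merge_categories("v", cats, counts, kind,
                                   mt.ChaidConfig(alpha_merge=alpha, min_parent=2,
                                                  min_child=1))
    return sorted([sorted(int(c[1:]) for c in g) for g in grouping.groups], key=min)


# ---------------------------------------------------------------------------
# Chi-square

class TestPearsonChiSquare:
    def test_perfect_independence(self):
        x2, df, p = mt.pearson_chi_square([[10, 10], [10, 10]])
        assert x2 == 0.0 and df == 1 and p == 1.0

    def test_hand_expanded_2x2(self):
        # margins 40/40 and 40/40: every expected count is 20,
        # X2 = 4 * (30-20)^2/20 = 20
        x2, df, p = mt.pearson_chi_square([[30, 10], [10, 30]])
        assert x2 == pytest.approx(20.0, abs=1e-12)
        assert df == 1

    def test_zero_column_is_no_association(self):
        x2, df, p = mt.pearson_chi_square([[5, 0], [9, 0]])
        assert x2 == 0.0 and p == 1.0

    def test_empty_table_is_an_error(self):
        with pytest.raises(ValueError):
            mt.pearson_chi_square([[0, 0], [0, 0]])

    def test_matches_independent_routine_on_random_tables(self):
        rng = np.random.default_rng(20)
        for _ in range(300):
            r = rng.integers(2, 6)
            t = rng.integers(0, 40, size=(r, 2))
            t[t.sum(axis=1) == 0, 0] = 1
            if t[:, 0].sum() == 0 or t[:, 1].sum() == 0:
                continue
            x2, df, p = mt.pearson_chi_square(t)
            ref = chi2_contingency(t, correction=False)
            assert df == ref.dof
            assert x2 == pytest.approx(ref.statistic, abs=1e-10, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)


# ---------------------------------------------------------------------------
# Bonferroni multipliers

class TestBonferroni:
    @pytest.mark.parametrize("c, r, kind, expected", [
        (3, 2, "nominal", 3),    # S(3,2)
        (4, 2, "ordinal", 3),    # C(3,1)
        (5, 3, "nominal", 25),   # S(5,3) via brute-force enumeration
        (1, 1, "nominal", 1),
        (6, 1, "ordinal", 1),
    ])
    def test_known_values(self, c, r, kind, expected):
        assert mt.bonferroni_multiplier(c, r, kind) == expected

    def test_r_above_c_rejected(self):
        with pytest.raises(ValueError):
            mt.bonferroni_multiplier(3, 4, "nominal")

    def test_matches_partition_enumeration(self):
        for c in range(1, 8):
            parts = list(set_partitions(list(range(c))))
            for r in range(1, c + 1):
                nominal = sum(1 for p in parts if len(p) == r)
                contiguous = sum(
                    1 for p in parts
                    if len(p) == r and all(
                        sorted(block) == list(range(min(block), max(block) + 1))
                        for block in p)
                )
                assert mt.bonferroni_multiplier(c, r, "nominal") == nominal
                assert mt.bonferroni_multiplier(c, r, "ordinal") == contiguous

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(c=st.integers(1, 12), data=st.data())
    def test_multiplier_at_least_one(self, c, data):
        r = data.draw(st.integers(1, c))
        assert mt.bonferroni_multiplier(c, r, "nominal") >= 1
        assert mt.bonferroni_multiplier(c, r, "ordinal") >= 1


# ---------------------------------------------------------------------------
# Category merging

class TestMergeCategories:
    def test_identical_proportions_merge(self):
        assert run_merge([[10, 10], [5, 5]], "nominal") == [[0, 1]]

    def test_ordinal_extremes_never_merge_without_the_middle(self):
        # outer speed bands similar, middle one very different
        counts = [[20, 20], [40, 5], [22, 21]]
        groups = run_merge(counts, "ordinal", alpha=0.5)
        for g in groups:
            assert g == list(range(min(g), max(g) + 1)), "non-contiguous ordinal group"

    def test_single_category_is_trivial(self):
        assert run_merge([[7, 3]], "nominal") == [[0]]

    def test_missing_category_floats_across_ordinal_gaps(self):
        cats = ["50", "60", "70", mt.MISSING]
        # missing resembles the lowest band; '70' stands apart
        counts = [[30, 3], [28, 4], [5, 30], [29, 3]]
        grouping = mt.merge_categories(
            "speed", cats, counts, "ordinal",
            mt.ChaidConfig(alpha_merge=0.05, min_parent=2, min_child=1))
        merged_with_missing = [g for g in grouping.groups if mt.MISSING in g]
        assert merged_with_missing and set(merged_with_missing[0]) != {mt.MISSING}

    @pytest.mark.parametrize("kind", ["nominal", "ordinal"])
    def test_matches_independent_greedy_oracle(self, kind):
        rng = np.random.default_rng(99)
        for _ in range(60):
            c = rng.integers(3, 7)
            counts = rng.integers(0, 30, size=(c, 2))
            counts[counts.sum(axis=1) == 0, 0] = 1
            assert run_merge(counts, kind) == oracle_merge(counts, kind, 0.05)

    def test_undersized_groups_absorbed_when_requested(self):
        cats = ["a", "b", "c"]
        counts = [[200, 100], [3, 0], [50, 180]]
        grouping = mt.merge_categories(
            "v", cats, counts, "nominal",
            mt.ChaidConfig(min_parent=100, min_child=50), min_group=50)
        sizes = [sum(counts[cats.index(c)][0] + counts[cats.index(c)][1] for c in g)
                 for g in grouping.groups]
        assert min(sizes) >= 50


# ---------------------------------------------------------------------------
# Split selection and growth

def two_signal_dataset(n_strong=40, seed=3):
    """Variable 'a' separates the outcome sharply, 'b' only weakly."""
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_strong):
        a = rng.choice(["a0", "a1"])
        b = rng.choice(["b0", "b1"])
        label = int(rng.random() < (0.9 if a == "a0" else 0.1))
        if rng.random() < 0.6:
            b = "b0" if label else "b1"
        rows.append(("X1", {"a": a, "b": b, "speed": "50"}, label))
    return make_dataset(toy_schema(), rows)


SMALL = mt.ChaidConfig(min_parent=8, min_child=2)


class TestBestSplit:
    def test_strongest_variable_wins(self):
        data = two_signal_dataset(80)
        prep = _Prep(data, ["a", "b"])
        idx = np.arange(len(data))
        cand_a = _candidate_for(prep, "a", idx, SMALL)
        cand_b = _candidate_for(prep, "b", idx, SMALL)
        assert cand_a.adjusted_p < cand_b.adjusted_p
        best = mt.best_split(prep, idx, depth=1, config=mt.ChaidConfig(
            min_parent=8, min_child=2, candidate_variables=["a", "b"]))
        assert best.grouping.variable == "a"

    def test_adjusted_p_never_below_raw(self):
        data = two_signal_dataset(80)
        prep = _Prep(data, ["a", "b"])
        for name in ("a", "b"):
            cand = _candidate_for(prep, name, np.arange(len(data)), SMALL)
            assert cand.adjusted_p >= cand.raw_p
            assert cand.bonferroni >= 1

    def test_pure_node_has_no_split(self):
        data = make_dataset(toy_schema(), [("X1", {"a": "a0"}, 1)] * 30
                            + [("X1", {"a": "a1"}, 1)] * 30)
        tree = mt.grow(data, SMALL)
        assert tree.n_nodes == 1 and tree.root.is_leaf

    def test_forced_first_variable_is_used_at_root(self):
        rows = []
        rng = np.random.default_rng(5)
        for _ in range(200):
            code = rng.choice(["X1", "X2"])
            a = rng.choice(["a0", "a1"])
            # 'a' is the stronger predictor, but the code is forced first
            label = int(rng.random() < (0.95 if a == "a0" else 0.05))
            if rng.random() < 0.25:
                code = "X1" if label else "X2"
            rows.append((code, {"a": a}, label))
        data = make_dataset(toy_schema(), rows)
        config = mt.ChaidConfig(min_parent=8, min_child=2,
                                forced_first_variable="mpds_code",
                                candidate_variables=["a", "mpds_code"])
        tree = mt.grow(data, config)
        assert tree.root.variable == "mpds_code"


class TestGrow:
    def test_depth_one_forced_mpds_partitions_all_codes(self, faithful):
        family_a = mt.default_families()[0]
        tree = mt.grow(faithful, family_a.config(mt.ChaidConfig()))
        assert tree.depth == 1
        covered = sorted(c for leaf_group in tree.root.groups for c in leaf_group)
        codes = sorted(r.category for r in mt.load_table2_fixture().rows)
        assert covered == codes
        assert sum(n.n for n in tree.leaves) == 11_971

    def test_count_conservation_at_every_split(self, faithful_run):
        for result in faithful_run.results:
            tree = result.tree
            for node in tree.nodes:
                if node.is_leaf:
                    continue
                children = [tree.nodes[c] for c in node.children]
                assert sum(c.n0 for c in children) == node.n0
                assert sum(c.n1 for c in children) == node.n1

    def test_depth_limits_respected(self, faithful_run):
        for result in faithful_run.results:
            limit = result.family.max_depth
            if limit is not None:
                assert result.tree.depth <= limit

    def test_unlabelled_data_rejected(self):
        data = mt.Dataset(toy_schema(), [mt.CrashRecord("X1", {"a": "a0"})])
        with pytest.raises(ValueError):
            mt.grow(data, SMALL)

    def test_deterministic_given_data_and_config(self, faithful):
        family_b = mt.default_families()[1]
        config = family_b.config(mt.ChaidConfig())
        t1 = mt.grow(faithful, config)
        t2 = mt.grow(faithful, config)
        assert t1.to_json() == t2.to_json()


# ---------------------------------------------------------------------------
# Cost-sensitive classification

def leaf_tree(n0, n1):
    return mt.ChaidTree([mt.TreeNode(0, 0, n0, n1)], mt.ChaidConfig())


class TestClassify:
    @pytest.mark.parametrize("n0, n1, ratio, expected", [
        (90, 10, 21, 1),   # 0.10 * 21 = 2.1 > 0.90
        (96, 4, 21, 0),    # 0.04 * 21 = 0.84 < 0.96
        (21, 1, 21, 1),    # exact tie predicts L&S (safety-first)
        (100, 0, 10**6, 0),  # a zero-positive leaf never flips at finite cost
    ])
    def test_threshold_algebra(self, n0, n1, ratio, expected):
        tree = leaf_tree(n0, n1)
        record = mt.CrashRecord("X1", {})
        assert tree.classify(record, mt.CostMatrix.from_ratio(ratio)) == expected

    def test_cost_monotonicity_over_a_fixed_tree(self, faithful_run):
        tree = faithful_run.results[3].tree  # the deep MPDS-forced family
        previous: set = set()
        for k in range(1, 31):
            positive = {
                n.id for n in tree.leaves
                if n.p_ls * k >= (1 - n.p_ls)
            }
            assert previous <= positive
            previous = positive

    def test_missing_value_routes_to_missing_group_or_stalls(self):
        nodes = [
            mt.TreeNode(0, 0, 50, 50, variable="a",
                        groups=[["a0"], ["a1", "a2"]], children=[1, 2]),
            mt.TreeNode(1, 1, 40, 10),
            mt.TreeNode(2, 1, 10, 40),
        ]
        tree = mt.ChaidTree(nodes, mt.ChaidConfig())
        # no group holds the missing label: routing stays at the root
        stalled = tree.route({"a": mt.MISSING})
        assert stalled.id == 0
        nodes[0].groups = [["a0", mt.MISSING], ["a1", "a2"]]
        assert tree.route({"a": mt.MISSING}).id == 1
        assert tree.route({"a": "unseen-category"}).id == 1


class TestExport:
    def test_json_roundtrip_predicts_identically(self, faithful, faithful_run):
        tree = faithful_run.results[1].tree
        clone = mt.ChaidTree.from_json(tree.to_json())
        rng = np.random.default_rng(12)
        sample = [faithful.records[i] for i in rng.choice(len(faithful), 100)]
        costs = mt.CostMatrix.from_ratio(7)
        for record in sample:
            assert clone.classify(record, costs) == tree.classify(record, costs)

    def test_node_counts_in_json_match_traversal(self, faithful_run):
        tree = faithful_run.results[0].tree
        payload = json.loads(mt.export_tree(tree, "json"))
        assert len(payload["nodes"]) == tree.n_nodes
        leaves = [n for n in payload["nodes"] if n["variable"] is None]
        assert len(leaves) == len(tree.leaves)
        assert sum(n["n0"] + n["n1"] for n in leaves) == 11_971

    def test_single_node_dot(self):
        dot = mt.export_tree(leaf_tree(3, 1), "dot")
        assert dot.count("n0 [") == 1 and "->" not in dot

    def test_unknown_format_rejected(self):
        with pytest.raises(ValueError):
            mt.export_tree(leaf_tree(1, 1), "xml")
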