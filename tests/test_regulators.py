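"""Regression-tree regulator assignment, ranking and passenger filter."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from omidriver import (
    Association,
    ValidationError,
    build_tree,
    passenger_filter,
    rank_top,
    score_association,
    table2_fixture,
)
from omidriver.regulators import score_all
from omidriver.simulate import planted_regulator_benchmark


def series(vals, prefix="S"):
    return pd.Series(np.asarray(vals, float),
                     index=[f"{prefix}{i+1:02d}" for i in range(len(vals))])


class TestBuildTree:
    def test_bimodal_profile_perfect_split(self):
        prof = series([-1.0] * 10 + [1.0] * 10)
        tree = build_tree(prof)
        root = tree.root
        assert not root.is_leaf
        assert sorted(root.left.samples) == [f"S{i+1:02d}" for i in range(10)]
        total_ss = float(((prof - prof.mean()) ** 2).sum())
        assert root.variance_reduction == pytest.approx(total_ss)

    def test_constant_profile_single_leaf(self):
        tree = build_tree(series([2.0] * 12))
        assert tree.root.is_leaf and tree.root.sd == 0.0

    def test_root_split_matches_brute_force(self):
        rng = np.random.default_rng(3)
        prof = series(rng.normal(size=40))
        tree = build_tree(prof, min_leaf=5, max_depth=1)
        v = np.sort(prof.to_numpy())
        total = ((v - v.mean()) ** 2).sum()
        best = -np.inf
        for i in range(5, 36):
            if v[i - 1] == v[i]:
                continue
            l, r = v[:i], v[i:]
            best = max(best, total - ((l - l.mean()) ** 2).sum() - ((r - r.mean()) ** 2).sum())
        assert tree.root.variance_reduction == pytest.approx(best)
        for leaf in tree.leaves():
            assert len(leaf.samples) >= 5

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            build_tree(series([1.0, 2.0, 3.0]), min_leaf=5)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=12, max_size=40),
           st.integers(min_value=2, max_value=5))
    def test_partition_invariants(self, vals, min_leaf):
        prof = series(vals)
        tree = build_tree(prof, min_leaf=min_leaf, max_depth=3)
        leaves = tree.leaves()
        covered = [s for leaf in leaves for s in leaf.samples]
        assert sorted(covered) == sorted(prof.index)          # disjoint cover
        for node in tree.internal_nodes():
            assert sorted(node.left.samples + node.right.samples) == sorted(node.samples)
            assert node.variance_reduction >= 0


class TestScoreAssociation:
    def test_self_regulation_is_maximal(self):
        prof = series([-1.0] * 10 + [1.0] * 10)
        tree = build_tree(prof)
        rng = np.random.default_rng(0)
        self_score = score_association(tree, prof)
        for _ in range(20):
            decoy = series(rng.normal(size=20))
            assert score_association(tree, decoy) <= self_score

    def test_constant_regulator_scores_zero(self):
        tree = build_tree(series([-1.0] * 10 + [1.0] * 10))
        assert score_association(tree, series([3.0] * 20)) == 0.0

    def test_depth_zero_tree_scores_zero(self):
        tree = build_tree(series([1.0] * 12))
        assert score_association(tree, series(np.arange(12.0))) == 0.0

    def test_affine_invariance(self):
        rng = np.random.default_rng(8)
        prof = series(np.concatenate([rng.normal(-1, 0.3, 10), rng.normal(1, 0.3, 10)]))
        tree = build_tree(prof)
        reg = series(rng.normal(size=20))
        s = score_association(tree, reg)
        assert score_association(tree, 5.0 * reg + 3.0) == pytest.approx(s)

    def test_planted_regulator_ranks_first(self):
        profiles, pool, true_id = planted_regulator_benchmark(seed=5)
        for mid, prof in profiles.items():
            top = rank_top(score_all({mid: prof}, pool), top_k=1)[0]
            assert top.regulator_id == true_id


class TestRankTop:
    def assoc(self, scores):
        return [Association(f"R{i:04d}", f"M{i:04d}", s) for i, s in enumerate(scores)]

    def test_one_percent_of_full_grid(self):
        kept = rank_top(self.assoc(np.linspace(0, 1, 6561)), top_percent=1.0)
        assert len(kept) == math.ceil(0.01 * 6561) == 66
        assert [a.rank for a in kept] == list(range(1, 67))

    def test_ceil_rule_small_n(self):
        assert len(rank_top(self.assoc([0.1] * 5), top_percent=1.0)) == 1

    def test_deterministic_tie_break_by_ids(self):
        a = Association("R2", "M1", 1.0)
        b = Association("R1", "M1", 1.0)
        kept = rank_top([a, b], top_k=1)
        assert kept[0].regulator_id == "R1"

    def test_prefix_property(self):
        assocs = self.assoc(np.linspace(0, 1, 500))
        small = [(a.regulator_id, a.module_id) for a in rank_top(assocs, top_percent=2.0)]
        big = [(a.regulator_id, a.module_id) for a in rank_top(assocs, top_percent=10.0)]
        assert big[:len(small)] == small

    def test_invalid_percent_rejected(self):
        with pytest.raises(ValidationError):
            rank_top(self.assoc([1.0]), top_percent=0.0)


class TestPassengerFilter:
    def test_passenger_rich_module_retained(self):
        members = {f"M48": {f"G{i}" for i in range(70)}}
        passengers = {f"G{i}" for i in range(17)}
        a = Association("TNFSF10", "M48", 68.6)
        kept = passenger_filter([a], passengers, members)
        assert kept == [a]
        assert a.passenger_fraction == pytest.approx(17 / 70)

    def test_passenger_free_module_dropped(self):
        members = {"M1": {"G1", "G2", "G3", "G4", "G5"}}
        a = Association("R", "M1", 1.0)
        assert passenger_filter([a], set(), members) == []

    def test_empty_module_is_an_error(self):
        with pytest.raises(ValidationError, match="empty or unknown"):
            passenger_filter([Association("R", "MX", 1.0)], set(), {"MX": set()})

    def test_published_association_table_consistency(self):
        t2 = table2_fixture()
        assert len(t2) == 22
        assert t2["module"].nunique() == 19
        assert t2["regulator"].nunique() == 16
        dual = t2["module"].value_counts()
        assert sorted(dual[dual == 2].index) == [49, 55, 97]
        fractions = t2["n_passengers"] / t2["n_genes"]
        assert (fractions >= 0.10).all()
        m48 = t2.loc[t2["module"] == 48].iloc[0]
        assert round(100 * m48.n_passengers / m48.n_genes) == 24
        assert t2["assignment_score"].min() == pytest.approx(30.11)
        assert t2["assignment_score"].max() == pytest.approx(119.19)
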