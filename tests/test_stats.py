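"""Downstream statistics against brute-force / hand-computed oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from omidriver import (
    InteractionTable,
    ValidationError,
    dichotomize_by_outlier,
    logrank_test,
    mannwhitney,
    ora_test,
    pfaffl_ratio,
    ppi_degree,
    table2_fixture,
)
from omidriver.stats import enrich_modules


class TestOra:
    def test_exact_enumeration_oracle(self):
        # P(drawing exactly the 3-gene set in a 3-gene module) = 1/C(10,3)
        universe = {f"G{i}" for i in range(10)}
        module = {"G0", "G1", "G2"}
        res = ora_test(module, module, universe)
        assert res.p_value == pytest.approx(1 / math.comb(10, 3))
        assert res.overlap == 3

    def test_zero_overlap_p_one(self):
        universe = {f"G{i}" for i in range(10)}
        res = ora_test({"G0"}, {"G5", "G6"}, universe)
        assert res.p_value == pytest.approx(1.0)

    def test_complement_set_p_one(self):
        universe = {f"G{i}" for i in range(8)}
        module = {"G0", "G1"}
        res = ora_test(module, universe - module, universe)
        assert res.p_value == pytest.approx(1.0)

    def test_pmf_sums_to_one_small_sizes(self):
        N, K, n = 12, 5, 4
        total = sum(sps.hypergeom.pmf(k, N, K, n) for k in range(0, min(K, n) + 1))
        assert total == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValidationError):
            ora_test(set(), set(), set())

    def test_joint_bh_correction(self):
        universe = {f"G{i}" for i in range(30)}
        modules = {"M1": {"G0", "G1", "G2"}, "M2": {"G10", "G11"}}
        sets = {"S1": ("d", frozenset({"G0", "G1", "G2"})),
                "S2": ("d", frozenset({"G20", "G21"}))}
        results = enrich_modules(modules, sets, universe)
        assert len(results) == 4
        assert all(r.q_value >= r.p_value - 1e-12 for r in results)


class TestPpiDegree:
    def test_star_graph(self):
        edges = InteractionTable(edges=frozenset(
            frozenset(("HUB", f"L{i}")) for i in range(5)))
        deg = ppi_degree(["HUB", "L0"], edges)
        assert deg == {"HUB": 5, "L0": 1}

    def test_empty_edges(self):
        assert ppi_degree(["A", "B"], InteractionTable(edges=frozenset())) == {"A": 0, "B": 0}

    def test_bipartite_degrees_from_association_table(self):
        t2 = table2_fixture()
        edges = {(r.regulator, f"module{r.module}") for r in t2.itertuples(index=False)}
        deg = ppi_degree(sorted(t2.regulator.unique()), edges)
        assert deg["BIRC5"] == 4
        counts = t2.regulator.value_counts()
        assert all(deg[g] == counts[g] for g in deg)


class TestDichotomize:
    def test_hand_computed_fences(self):
        labels = dichotomize_by_outlier(
            pd.Series([9.0, 0.0, -3.0], index=["T1", "T2", "T3"]),
            [1, 2, 3, 4, 5],
        )
        assert list(labels) == ["high", "neither", "low"]

    def test_all_within_fences(self):
        labels = dichotomize_by_outlier(pd.Series([2.0, 3.0], index=["T1", "T2"]),
                                        [1, 2, 3, 4, 5])
        assert set(labels) == {"neither"}

    def test_constant_reference_collapsed_fences(self):
        labels = dichotomize_by_outlier(pd.Series([2.0, 3.0], index=["T1", "T2"]),
                                        [2, 2, 2])
        assert list(labels) == ["neither", "high"]

    def test_needs_three_reference_values(self):
        with pytest.raises(ValidationError):
            dichotomize_by_outlier(pd.Series([1.0], index=["T1"]), [1, 2])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        times = [1, 2, 3, 1, 2, 3]
        events = [1, 1, 1, 1, 1, 1]
        groups = ["a", "a", "a", "b", "b", "b"]
        res = logrank_test(times, events, groups)
        assert res.logrank_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_two_by_two_tables(self):
        # A deaths at {1,2}, B deaths at {3,4}: U = 7/6, V = 17/36
        res = logrank_test([1, 2, 3, 4], [1, 1, 1, 1], ["A", "A", "B", "B"])
        expected = (7 / 6) ** 2 / (17 / 36)
        assert res.logrank_statistic == pytest.approx(expected)
        assert res.p_value == pytest.approx(1 - sps.chi2.cdf(expected, df=1))

    def test_all_censored_statistic_zero(self):
        res = logrank_test([5, 6, 7, 8], [0, 0, 0, 0], ["A", "A", "B", "B"])
        assert res.logrank_statistic == 0.0 and res.p_value == 1.0

    def test_time_rescaling_invariance(self):
        times = [1.0, 2.5, 3.0, 4.0, 6.0, 7.5]
        events = [1, 0, 1, 1, 0, 1]
        groups = ["A", "A", "A", "B", "B", "B"]
        a = logrank_test(times, events, groups)
        b = logrank_test([t * 12 for t in times], events, groups)
        assert a.logrank_statistic == pytest.approx(b.logrank_statistic)

    def test_km_without_censoring_is_empirical_survival(self):
        times = [1, 2, 3, 4]
        res = logrank_test(times + times, [1] * 8, ["A"] * 4 + ["B"] * 4)
        curve = res.km_curves["A"]
        surv = dict(zip(curve.time, curve.survival))
        for i, t in enumerate(times):
            assert surv[t] == pytest.approx(1 - (i + 1) / 4)
        assert (curve.survival.diff().dropna() <= 1e-12).all()  # non-increasing
        assert surv[0.0] == pytest.approx(1.0)

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            logrank_test([1, 2], [1, 1], ["A", "A"])


class TestMannWhitney:
    def test_full_separation_u_zero(self):
        u, _ = mannwhitney([1, 2, 3], [4, 5, 6])
        assert min(u, 9 - u) == 0.0

    def test_identical_samples_p_near_one(self):
        _, p = mannwhitney([1, 2, 3], [1, 2, 3])
        assert p > 0.9

    def test_brute_force_pair_count(self):
        x, y = [1, 2, 5], [3, 4]
        u_brute = sum((xi > yi) + 0.5 * (xi == yi)
                      for xi, yi in itertools.product(x, y))
        u, _ = mannwhitney(x, y)
        assert u == pytest.approx(u_brute)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            mannwhitney([], [1.0])


class TestPfaffl:
    @pytest.mark.parametrize("args,expected", [
        ((2.0, 3.0, 2.0, 0.0), 8.0),
        ((2.0, 0.0, 2.0, 0.0), 1.0),
        ((1.9, 2.0, 2.0, 1.0), 1.9**2 / 2.0),
    ])
    def test_ratio_arithmetic(self, args, expected):
        assert pfaffl_ratio(*args) == pytest.approx(expected)

    def test_nonpositive_efficiency_rejected(self):
        with pytest.raises(ValidationError):
            pfaffl_ratio(0.0, 1.0, 2.0, 1.0)
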