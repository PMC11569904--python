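"""Two-sample tests, pooling, sum-preserving rounding, weight-table assembly."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mcda_hta import (
    build_weight_table,
    compare_all_nodes,
    compare_samples,
    pool_means,
    round_preserving_sum,
    summarize_sample,
    weight_table_from_integers,
)
from mcda_hta.rounding import naive_round
from mcda_hta.tree import ROOT_GROUP

from conftest import allocation_set, make_tree


def two_sample_allocs(tree, a_values, b_values, node="d1"):
    """Two-domain allocations where `node` takes the listed values."""
    other = "d2" if node == "d1" else "d1"
    data = {"A": {}, "B": {}}
    for i, v in enumerate(a_values):
        data["A"][f"a{i}"] = {ROOT_GROUP: {node: v, other: 100 - v}}
    for i, v in enumerate(b_values):
        data["B"][f"b{i}"] = {ROOT_GROUP: {node: v, other: 100 - v}}
    return allocation_set(tree, data)


class TestCompareSamples:
    def test_welch_textbook_example(self, two_domain_tree):
        allocs = two_sample_allocs(two_domain_tree, [10, 20, 30], [40, 50, 60])
        res = compare_samples(allocs, "d1", "A", "B")
        # hand computation: t = −30/sqrt(100/3+100/3), Welch–Satterthwaite df = 4
        assert res.mean_diff == pytest.approx(-30.0)
        assert res.t_stat == pytest.approx(-30.0 / np.sqrt(200.0 / 3.0), abs=1e-12)
        assert res.t_df == pytest.approx(4.0, abs=1e-9)
        assert res.t_pvalue == pytest.approx(0.0213, abs=5e-4)
        assert not res.degenerate

    def test_rank_sum_u_zero_on_separated_samples(self, two_domain_tree):
        allocs = two_sample_allocs(two_domain_tree, [1, 2, 3], [4, 5, 6])
        res = compare_samples(allocs, "d1", "A", "B")
        # brute-force rank enumeration: no pair (a, b) has a > b
        assert res.u_stat == 0.0

    def test_identical_samples_symmetric(self, two_domain_tree):
        allocs = two_sample_allocs(two_domain_tree, [10, 20, 30], [10, 20, 30])
        res = compare_samples(allocs, "d1", "A", "B")
        assert res.mean_diff == 0.0
        assert res.u_pvalue == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_constant_equal_samples(self, two_domain_tree):
        allocs = two_sample_allocs(two_domain_tree, [30, 30, 30], [30, 30])
        res = compare_samples(allocs, "d1", "A", "B")
        assert res.degenerate
        assert res.t_pvalue == 1.0
        assert res.u_pvalue == 1.0

    def test_degenerate_constant_unequal_samples(self, two_domain_tree):
        allocs = two_sample_allocs(two_domain_tree, [30, 30], [40, 40])
        res = compare_samples(allocs, "d1", "A", "B")
        assert res.degenerate
        assert res.t_pvalue == 0.0

    def test_too_few_respondents_errors(self, two_domain_tree):
        allocs = two_sample_allocs(two_domain_tree, [30], [40, 50])
        with pytest.raises(ValueError, match="≥2 respondents"):
            compare_samples(allocs, "d1", "A", "B")

    def test_holm_adjustment_monotone(self, two_domain_tree):
        allocs = two_sample_allocs(two_domain_tree, [10, 20, 30], [40, 50, 60])
        table = compare_all_nodes(allocs, "A", "B", holm=True)
        assert (table["t_pvalue_holm"] >= table["t_pvalue"] - 1e-15).all()
        assert (table["t_pvalue_holm"] <= 1.0).all()


class TestPoolMeans:
    def test_published_pair_pools_to_midpoint(self, two_domain_tree):
        # the two samples' mean weights for the top domain: 28.1 and 23.7
        allocs = two_sample_allocs(two_domain_tree, [28.1], [23.7])
        a = summarize_sample(allocs, "A")
        b = summarize_sample(allocs, "B")
        pooled = pool_means(a, b, 0.5)
        assert pooled["d1"] == pytest.approx(25.9, abs=1e-12)

    def test_lambda_one_is_identity(self, two_domain_tree):
        allocs = two_sample_allocs(two_domain_tree, [35, 45], [10, 20])
        a = summarize_sample(allocs, "A")
        b = summarize_sample(allocs, "B")
        pooled = pool_means(a, b, 1.0)
        pd.testing.assert_series_equal(pooled, a.table["mean"], check_names=False)

    def test_equal_means_invariant_to_lambda(self, two_domain_tree):
        allocs = two_sample_allocs(two_domain_tree, [30, 40], [30, 40])
        a = summarize_sample(allocs, "A")
        b = summarize_sample(allocs, "B")
        for lam in (0.0, 0.25, 0.9):
            assert pool_means(a, b, lam)["d1"] == pytest.approx(35.0)

    def test_affine_symmetry(self, two_domain_tree):
        allocs = two_sample_allocs(two_domain_tree, [20, 40], [60, 80])
        a = summarize_sample(allocs, "A")
        b = summarize_sample(allocs, "B")
        lam = 0.3
        pd.testing.assert_series_equal(
            pool_means(a, b, lam), pool_means(b, a, 1 - lam).reindex(a.table.index),
            check_names=False,
        )

    def test_node_mismatch_lists_difference(self, two_domain_tree, tiny_tree):
        allocs_a = two_sample_allocs(two_domain_tree, [20, 40], [60, 80])
        a = summarize_sample(allocs_a, "A")
        allocs_b = allocation_set(tiny_tree, {
            "B": {"r1": {ROOT_GROUP: {"d1": 100}}, "r2": {ROOT_GROUP: {"d1": 100}}},
        })
        b = summarize_sample(allocs_b, "B")
        with pytest.raises(ValueError, match="d2"):
            pool_means(a, b)

    def test_lambda_out_of_range(self, two_domain_tree):
        allocs = two_sample_allocs(two_domain_tree, [20, 40], [60, 80])
        a = summarize_sample(allocs, "A")
        with pytest.raises(ValueError, match="lambda"):
            pool_means(a, a, 1.5)


class TestRoundPreservingSum:
    @pytest.mark.parametrize("values,expected", [
        ([25.9, 23.85, 19.25, 16.5, 14.5], [26, 24, 19, 17, 14]),  # .5 tie → order
        ([50.0, 50.0], [50, 50]),
        ([33.33, 33.33, 33.34], [33, 33, 34]),
        ([100.0], [100]),
        ([0.0, 100.0], [0, 100]),
    ])
    def test_hand_computed_cases(self, values, expected):
        assert round_preserving_sum(values).tolist() == expected

    def test_negative_input_errors(self):
        with pytest.raises(ValueError, match="non-negative"):
            round_preserving_sum([-1.0, 101.0])

    def test_wrong_sum_errors(self):
        with pytest.raises(ValueError, match="sum"):
            round_preserving_sum([30.0, 30.0])

    def test_matches_minimal_deviation_brute_force(self):
        """Largest remainder attains the minimal total |deviation| (500 cases).

        Any L1-optimal integer apportionment takes each coordinate to its
        floor or ceiling, so the brute force enumerates those 2^k corners.
        """
        rng = np.random.default_rng(2024)
        for _ in range(500):
            k = int(rng.integers(2, 6))
            vals = rng.dirichlet(np.full(k, rng.uniform(0.3, 5.0))) * 100.0
            ours = round_preserving_sum(vals)
            assert ours.sum() == 100
            assert (ours >= 0).all()
            best = min(
                abs(np.array(c) - vals).sum()
                for c in itertools.product(*[
                    (int(np.floor(v)), int(np.ceil(v))) for v in vals
                ])
                if sum(c) == 100
            )
            assert abs(ours - vals).sum() == pytest.approx(best, abs=1e-9)

    def test_never_off_by_one_without_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            k = int(rng.integers(2, 6))
            vals = rng.dirichlet(np.ones(k)) * 100.0
            out = round_preserving_sum(vals)
            assert (np.abs(out - vals) < 1.0).all()


class TestWeightTable:
    def test_identical_sample_means(self, two_domain_tree):
        allocs = two_sample_allocs(two_domain_tree, [30, 30], [30, 30])
        wt = build_weight_table(allocs)
        assert wt.table.loc["d1", "pooled"] == 30
        assert wt.table.loc["d1", "rounded"] == 30
        assert wt.table.loc["d1", "normalized"] == pytest.approx(0.3)
        assert wt.table.loc["d2", "normalized"] == pytest.approx(0.7)

    def test_rounded_groups_sum_to_100_and_fractions_to_1(self, default_tree):
        from mcda_hta import default_survey_profiles, simulate_allocations
        allocs = simulate_allocations(default_tree, default_survey_profiles(
            default_tree, 12, 20), seed=11)
        wt = build_weight_table(allocs)
        for gid, block in wt.table.groupby("group_id"):
            assert int(block["rounded"].sum()) == 100
            assert block["normalized"].sum() == pytest.approx(1.0, abs=1e-12)
            assert block["pooled"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_single_child_group_normalizes_to_one(self, default_tree):
        from mcda_hta import default_survey_profiles, simulate_allocations
        allocs = simulate_allocations(default_tree, default_survey_profiles(
            default_tree, 5, 5), seed=2)
        wt = build_weight_table(allocs)
        # d4.c1 has a single subcriterion in the packaged tree
        assert wt.table.loc["d4.c1.s1", "normalized"] == 1.0
        assert wt.table.loc["d4.c1.s1", "rounded"] == 100

    def test_naive_rounding_flags_broken_groups(self, two_domain_tree):
        allocs = two_sample_allocs(two_domain_tree, [30, 31], [30, 30])
        # pooled means {30.25, 69.75} → naive rounding gives 30 + 70 = 100 (ok)
        wt = build_weight_table(allocs, rounding="naive")
        assert wt.broken_sum_groups == ()
        tree3 = make_tree({"A": {"c": []}, "B": {"c": []}, "C": {"c": []}})
        data = {"A": {}, "B": {}}
        for i, v in enumerate([33, 34]):
            data["A"][f"a{i}"] = {ROOT_GROUP: {"d1": v, "d2": v, "d3": 100 - 2 * v}}
            data["B"][f"b{i}"] = {ROOT_GROUP: {"d1": v, "d2": v, "d3": 100 - 2 * v}}
        wt3 = build_weight_table(allocation_set(tree3, data), rounding="naive")
        # all three pooled means end in .5 → naive rounds every one up
        assert wt3.broken_sum_groups == (ROOT_GROUP,)

    def test_requires_exactly_two_samples(self, two_domain_tree):
        allocs = two_sample_allocs(two_domain_tree, [30, 40], [50, 60])
        allocs2 = allocation_set(two_domain_tree, {
            "C": {"c1": {ROOT_GROUP: {"d1": 10, "d2": 90}}}})
        allocs.records += allocs2.records
        with pytest.raises(ValueError, match="exactly two samples"):
            build_weight_table(allocs)

    def test_from_published_integers(self, two_domain_tree):
        wt = weight_table_from_integers(two_domain_tree, {
            "d1": 26, "d2": 74, "d1.c1": 100, "d2.c1": 100})
        assert wt.normalized("d1") == pytest.approx(0.26)
        assert wt.broken_sum_groups == ()

    def test_from_integers_repairs_off_budget_groups(self, two_domain_tree):
        wt = weight_table_from_integers(two_domain_tree, {
            "d1": 26, "d2": 75, "d1.c1": 100, "d2.c1": 100})
        assert ROOT_GROUP in wt.broken_sum_groups
        assert wt.table.loc[["d1", "d2"], "rounded"].sum() == 100


class TestStatisticalAgreement:
    def test_welch_and_rank_sum_match_textbook_oracle(self):
        """scipy-backed tests agree with hand-coded formulas to 1e−8."""
        rng = np.random.default_rng(99)
        tree = make_tree({"A": {"c": []}, "B": {"c": []}})
        for _ in range(25):
            na, nb = rng.integers(3, 15, size=2)
            a = np.round(rng.uniform(0, 100, na), 1)
            b = np.round(rng.uniform(0, 100, nb), 1)
            allocs = two_sample_allocs(tree, a, b)
            res = compare_samples(allocs, "d1", "A", "B")
            t_ref, p_ref, df_ref = welch_oracle(a, b)
            assert res.t_stat == pytest.approx(t_ref, abs=1e-8)
            assert res.t_pvalue == pytest.approx(p_ref, abs=1e-8)
            assert res.t_df == pytest.approx(df_ref, abs=1e-6)
            u_ref, pu_ref = rank_sum_oracle(a, b)
            assert res.u_stat == pytest.approx(u_ref, abs=1e-9)
            assert res.u_pvalue == pytest.approx(pu_ref, abs=1e-8)


def welch_oracle(a, b):
    """Textbook Welch t: statistic, two-sided p, Welch–Satterthwaite df."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, p, df


def rank_sum_oracle(a, b):
    """Mann–Whitney U by direct pair counting; normal approx with tie correction."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    u = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
    mu = na * nb / 2.0
    combined = np.concatenate([a, b])
    _, counts = np.unique(combined, return_counts=True)
    n = na + nb
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
    sigma = np.sqrt(na * nb / 12.0 * (n + 1 - tie_term))
    z = (u - mu) / sigma
    p = 2.0 * stats.norm.sf(abs(z))
    return u, min(1.0, p)


def test_naive_round_half_away_from_zero():
    assert naive_round([0.5, 1.5, 2.4]).tolist() == [1, 2, 2]
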