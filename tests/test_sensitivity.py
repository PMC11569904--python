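"""One-way weight sweeps and probabilistic (bootstrap / Dirichlet) sensitivity."""

import numpy as np
import pandas as pd
import pytest

from mcda_hta import (
    ScoreSheet,
    aggregate_value,
    dirichlet_params_from_summary,
    one_way_weight_sensitivity,
    probabilistic_sensitivity,
    summarize_sample,
    weight_table_from_integers,
)
from mcda_hta.tree import ROOT_GROUP

from conftest import allocation_set, make_tree


@pytest.fixture
def toy():
    """Two-domain tree, 60/40 weights, two technologies with opposed profiles."""
    tree = make_tree({"A": {"a": []}, "B": {"b": []}})
    wt = weight_table_from_integers(tree, {"d1": 60, "d2": 40,
                                           "d1.c1": 100, "d2.c1": 100})
    sheets = [
        ScoreSheet("strong_on_A", {"d1.c1": 0.9, "d2.c1": 0.2}),
        ScoreSheet("strong_on_B", {"d1.c1": 0.3, "d2.c1": 0.8}),
    ]
    return tree, wt, sheets


def bootstrap_allocs(tree, n_a=6, n_b=8, seed=0, spread=10):
    rng = np.random.default_rng(seed)
    data = {"A": {}, "B": {}}
    for sid, n, centre in (("A", n_a, 60), ("B", n_b, 45)):
        for i in range(n):
            # continuous points: exact pooled-weight ties then have measure zero
            d1 = float(np.clip(centre + rng.uniform(-spread, spread), 0, 100))
            data[sid][f"{sid}{i}"] = {
                ROOT_GROUP: {"d1": d1, "d2": 100 - d1},
                "d1": {"d1.c1": 100.0},
                "d2": {"d2.c1": 100.0},
            }
    return allocation_set(tree, data)


class TestOneWay:
    def test_baseline_grid_point_reproduces_value_exactly(self, toy):
        tree, wt, sheets = toy
        curve = one_way_weight_sensitivity(wt, sheets, "d1", [0, 60, 100])
        base = {s.technology_id: aggregate_value(wt, s).value for s in sheets}
        for tech, expected in base.items():
            assert curve.values.loc[tech, 60.0] == expected  # bit-exact

    def test_full_weight_collapses_to_subtree_score(self, toy):
        tree, wt, sheets = toy
        curve = one_way_weight_sensitivity(wt, sheets, "d1", [100])
        assert curve.values.loc["strong_on_A", 100.0] == pytest.approx(0.9)
        assert curve.values.loc["strong_on_B", 100.0] == pytest.approx(0.3)

    def test_zero_weight_collapses_to_other_domain(self, toy):
        tree, wt, sheets = toy
        curve = one_way_weight_sensitivity(wt, sheets, "d1", [0])
        assert curve.values.loc["strong_on_A", 0.0] == pytest.approx(0.2)

    def test_curves_are_linear_in_the_varied_weight(self, toy):
        tree, wt, sheets = toy
        curve = one_way_weight_sensitivity(wt, sheets, "d1", [10, 35, 60])
        vals = curve.values.to_numpy()
        # three collinear grid points: midpoint equals the average of the ends
        assert vals[:, 1] == pytest.approx((vals[:, 0] + vals[:, 2]) / 2, abs=1e-12)

    def test_crossover_matches_closed_form(self, toy):
        tree, wt, sheets = toy
        # V_A(g) = 0.9 g/100 + 0.2 (1−g/100); V_B(g) = 0.3 g/100 + 0.8 (1−g/100)
        # equal where 0.2 + 0.7 g/100 = 0.8 − 0.5 g/100 → g = 50
        curve = one_way_weight_sensitivity(wt, sheets, "d1", range(0, 101, 5))
        assert len(curve.crossovers) == 1
        assert curve.crossovers[0] == pytest.approx(50.0, abs=1e-9)

    def test_subcriterion_rejected(self, default_tree):
        wt = weight_table_from_integers(
            default_tree,
            {c: 100.0 / len(default_tree.children(g))
             for g in default_tree.sibling_groups() for c in default_tree.children(g)},
            normalize_on="pooled")
        sheet = ScoreSheet("t", {l: 0.5 for l in default_tree.leaves()})
        with pytest.raises(ValueError, match="domains or criteria"):
            one_way_weight_sensitivity(wt, [sheet], "d1.c1.s1", [10, 20])

    def test_varying_a_criterion_within_its_domain(self, default_tree):
        wt = weight_table_from_integers(
            default_tree,
            {c: 100.0 / len(default_tree.children(g))
             for g in default_tree.sibling_groups() for c in default_tree.children(g)},
            normalize_on="pooled")
        rng = np.random.default_rng(3)
        sheet = ScoreSheet("t", {l: float(rng.uniform()) for l in default_tree.leaves()})
        base_pct = wt.normalized("d1.c1") * 100.0
        curve = one_way_weight_sensitivity(wt, [sheet], "d1.c1", [base_pct, 80.0])
        assert curve.values.iloc[0, 0] == aggregate_value(wt, sheet).value


class TestProbabilistic:
    def test_single_technology_always_rank_one(self, toy):
        tree, _, sheets = toy
        allocs = bootstrap_allocs(tree)
        psa = probabilistic_sensitivity(sheets[:1], n_draws=40, seed=1, allocs=allocs)
        assert psa.rank_fractions.loc["strong_on_A", 1] == 1.0

    def test_zero_variance_allocations_collapse_intervals(self, toy):
        tree, _, sheets = toy
        allocs = bootstrap_allocs(tree, seed=0, spread=0)
        psa = probabilistic_sensitivity(sheets, n_draws=60, seed=5, allocs=allocs)
        width = psa.value_stats["p97.5"] - psa.value_stats["p2.5"]
        assert (width == 0).all()

    def test_row_and_column_stochasticity(self, toy):
        tree, _, sheets = toy
        allocs = bootstrap_allocs(tree, seed=2)
        psa = probabilistic_sensitivity(sheets, n_draws=250, seed=9, allocs=allocs)
        rows = psa.rank_fractions.sum(axis=1)
        cols = psa.rank_fractions.sum(axis=0)
        assert np.allclose(rows, 1.0, atol=1e-9)
        assert np.allclose(cols, 1.0, atol=1e-9)
        assert psa.n_ties == 0

    def test_seed_determinism_bit_exact(self, toy):
        tree, _, sheets = toy
        allocs = bootstrap_allocs(tree, seed=4)
        a = probabilistic_sensitivity(sheets, n_draws=80, seed=17, allocs=allocs)
        b = probabilistic_sensitivity(sheets, n_draws=80, seed=17, allocs=allocs)
        pd.testing.assert_frame_equal(a.rank_fractions, b.rank_fractions)
        pd.testing.assert_frame_equal(a.value_stats, b.value_stats)

    def test_clear_separation_gives_full_acceptability(self, toy):
        """|ΔV| ≫ weight-sampling noise ⇒ the better technology is always first."""
        tree, _, _ = toy
        allocs = bootstrap_allocs(tree, seed=6, spread=3)
        sheets = [
            ScoreSheet("dominant", {"d1.c1": 0.95, "d2.c1": 0.95}),
            ScoreSheet("weak", {"d1.c1": 0.05, "d2.c1": 0.05}),
        ]
        psa = probabilistic_sensitivity(sheets, n_draws=400, seed=21, allocs=allocs)
        assert psa.rank_fractions.loc["dominant", 1] == 1.0
        assert psa.rank_fractions.loc["weak", 2] == 1.0

    def test_requires_two_respondents_per_sample(self, toy):
        tree, _, sheets = toy
        allocs = bootstrap_allocs(tree, n_a=1, n_b=5)
        with pytest.raises(ValueError, match="<2 respondents"):
            probabilistic_sensitivity(sheets, n_draws=5, seed=0, allocs=allocs)

    def test_exactly_one_uncertainty_source(self, toy):
        tree, _, sheets = toy
        with pytest.raises(ValueError, match="exactly one"):
            probabilistic_sensitivity(sheets, n_draws=5, seed=0)

    def test_dirichlet_route_runs_and_is_deterministic(self, toy):
        tree, _, sheets = toy
        allocs = bootstrap_allocs(tree, seed=10)
        params = {
            sid: dirichlet_params_from_summary(summarize_sample(allocs, sid), tree)
            for sid in ("A", "B")
        }
        a = probabilistic_sensitivity(sheets, n_draws=100, seed=33,
                                      dirichlet_params=params, tree=tree)
        b = probabilistic_sensitivity(sheets, n_draws=100, seed=33,
                                      dirichlet_params=params, tree=tree)
        pd.testing.assert_frame_equal(a.rank_fractions, b.rank_fractions)
        assert np.allclose(a.rank_fractions.sum(axis=1), 1.0, atol=1e-9)

    def test_dirichlet_tracks_bootstrap_uncertainty(self, toy):
        """Moment-matched Dirichlet gives interval widths near the bootstrap's."""
        tree, _, sheets = toy
        allocs = bootstrap_allocs(tree, n_a=30, n_b=30, seed=12)
        boot = probabilistic_sensitivity(sheets, n_draws=500, seed=1, allocs=allocs)
        params = {
            sid: dirichlet_params_from_summary(summarize_sample(allocs, sid), tree)
            for sid in ("A", "B")
        }
        diri = probabilistic_sensitivity(sheets, n_draws=500, seed=2,
                                         dirichlet_params=params, tree=tree)
        w_boot = (boot.value_stats["p97.5"] - boot.value_stats["p2.5"]).mean()
        w_diri = (diri.value_stats["p97.5"] - diri.value_stats["p2.5"]).mean()
        assert w_diri == pytest.approx(w_boot, rel=0.5)
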