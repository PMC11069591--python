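"""Lagged design, penalized scoring, hill-climbing, MLE fit, penalty tuning."""

import math

import numpy as np
import pandas as pd
import pytest

from infodbn import (
    PanelData,
    TwoSliceDAG,
    build_lag_pairs,
    exhaustive_search,
    fit_mle,
    hill_climb,
    make_ground_truth,
    predict_r2,
    score,
    simulate_panel,
    tune_penalty,
)
from infodbn.dbn import GaussianScorer, LagPairs
from infodbn.errors import DegenerateDesignError, EmptyResultError, ParameterError


def _panel_one_county(n_weeks, p=2, seed=0):
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame({"state": "S1", "county": "S1C1", "week": np.arange(n_weeks)})
    for i in range(p):
        frame[f"C{i}"] = rng.uniform(0, 1, n_weeks)
    return PanelData(frame)


class TestBuildLagPairs:
    def test_one_county_pair_count(self):
        lp = build_lag_pairs(_panel_one_county(100))
        assert lp.n == 99

    def test_many_counties_pair_count(self, default_panel):
        lp = build_lag_pairs(default_panel)
        assert lp.n == 200 * 99

    def test_two_weeks_single_row(self):
        panel = _panel_one_county(2)
        lp = build_lag_pairs(panel)
        assert lp.n == 1
        np.testing.assert_array_equal(lp.t0[0], panel.values[0])
        np.testing.assert_array_equal(lp.t1[0], panel.values[1])

    def test_single_week_counties_contribute_nothing(self):
        frame = pd.DataFrame(
            {"state": "S1", "county": "S1C1", "week": [0], "A": [1.0]}
        )
        with pytest.raises(EmptyResultError):
            build_lag_pairs(PanelData(frame))


class TestScore:
    def test_gaussian_mle_closed_form(self):
        """No-parent node with residuals [-1, 0, 1] has the textbook profile
        log-likelihood -(n/2)(ln(2 pi sigma2) + 1) with sigma2 = 2/3."""
        t1 = np.array([[-1.0], [0.0], [1.0]])
        t0 = np.zeros((3, 1))
        lp = LagPairs(("A",), t0, t1)
        dag = TwoSliceDAG(("A",))
        res = score(dag, lp, w=1.0, include_t0=False)
        expected = -1.5 * (math.log(2 * math.pi * (2 / 3)) + 1)
        assert res.loglik == pytest.approx(expected, rel=1e-12)

    def test_zero_penalty_equals_loglik(self, small_panel):
        lp = build_lag_pairs(small_panel)
        dag = TwoSliceDAG(lp.conditions)
        res = score(dag, lp, w=0.0)
        assert res.penalized == pytest.approx(res.loglik)

    def test_adding_a_parent_never_decreases_loglik(self, small_panel):
        lp = build_lag_pairs(small_panel)
        conds = lp.conditions
        empty = TwoSliceDAG(conds)
        for s in conds:
            richer = TwoSliceDAG(conds, {(s, conds[0])})
            assert (
                score(richer, lp, w=0).loglik >= score(empty, lp, w=0).loglik - 1e-9
            )

    def test_score_decomposability_is_exact(self, small_panel):
        """DAGs differing in one node's parents differ only in that local term."""
        lp = build_lag_pairs(small_panel)
        conds = lp.conditions
        a = TwoSliceDAG(conds, {(conds[0], conds[1]), (conds[2], conds[3])})
        b = TwoSliceDAG(conds, {(conds[0], conds[1]), (conds[1], conds[3]), (conds[2], conds[3])})
        ra, rb = score(a, lp, w=1.0), score(b, lp, w=1.0)
        local_diff = rb.per_node[conds[3]] - ra.per_node[conds[3]]
        assert rb.loglik - ra.loglik == pytest.approx(local_diff, rel=1e-12)

    def test_collinear_parents_raise_named_degeneracy(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        t0 = np.column_stack([x, x, rng.normal(size=50)])  # duplicated column
        t1 = rng.normal(size=(50, 3))
        lp = LagPairs(("A", "B", "C"), t0, t1)
        dag = TwoSliceDAG(("A", "B", "C"), {("A", "C"), ("B", "C")})
        with pytest.raises(DegenerateDesignError, match="C"):
            score(dag, lp)


class TestHillClimb:
    def test_independent_white_noise_gives_empty_graph(self):
        panel = _panel_one_county(300, p=3, seed=1)
        lp = build_lag_pairs(panel)
        dag = hill_climb(lp, w=16.0)
        assert dag.n_arcs == 0

    def test_matches_exhaustive_search_on_small_system(self):
        gt = make_ground_truth(3, 1, 1, seed=2)
        panel = simulate_panel(gt, 1, 2, 1001, seed=3)
        lp = build_lag_pairs(panel)  # 2000 rows
        hc = hill_climb(lp, w=1.0)
        ex = exhaustive_search(lp, w=1.0)
        assert score(hc, lp, 1.0).penalized == pytest.approx(
            score(ex, lp, 1.0).penalized
        )

    def test_arc_count_nonincreasing_in_w(self, small_panel):
        lp = build_lag_pairs(small_panel)
        counts = [hill_climb(lp, w).n_arcs for w in (1, 2, 4, 8, 16, 32, 64, 128)]
        assert counts == sorted(counts, reverse=True)

    def test_whitelist_and_blacklist_respected(self, small_panel):
        lp = build_lag_pairs(small_panel)
        conds = lp.conditions
        forced = (conds[2], conds[0])
        banned = (conds[0], conds[0])
        dag = hill_climb(lp, w=128.0, whitelist=[forced], blacklist=[banned])
        assert dag.has_arc(*forced)
        assert not dag.has_arc(*banned)

    def test_deterministic(self, small_panel):
        lp = build_lag_pairs(small_panel)
        assert hill_climb(lp, 2.0) == hill_climb(lp, 2.0)


class TestFitMle:
    def test_recovers_generating_coefficients(self):
        """X_t1 = 2 + 0.5 X_t0 + eps, sigma = 0.1, n = 5000."""
        rng = np.random.default_rng(4)
        x0 = rng.normal(10, 1, 5000)
        x1 = 2.0 + 0.5 * x0 + rng.normal(0, 0.1, 5000)
        lp = LagPairs(("A",), x0[:, None], x1[:, None])
        fit = fit_mle(TwoSliceDAG(("A",), {("A", "A")}), lp)
        assert 0.48 <= fit.nodes["A"].coefficients["A"] <= 0.52
        assert 1.9 <= fit.nodes["A"].intercept <= 2.1

    def test_noiseless_system_fits_exactly(self):
        rng = np.random.default_rng(5)
        x0 = rng.normal(size=1000)
        x1 = 1.0 + 0.7 * x0
        lp = LagPairs(("A",), x0[:, None], x1[:, None])
        fit = fit_mle(TwoSliceDAG(("A",), {("A", "A")}), lp)
        assert fit.nodes["A"].sigma2 < 1e-10
        assert fit.nodes["A"].coefficients["A"] == pytest.approx(0.7)

    def test_empty_parent_set_gives_marginal_gaussian(self):
        rng = np.random.default_rng(6)
        y = rng.normal(3, 2, 400)
        lp = LagPairs(("A",), np.zeros((400, 1)), y[:, None])
        fit = fit_mle(TwoSliceDAG(("A",)), lp)
        assert fit.nodes["A"].intercept == pytest.approx(y.mean())
        assert fit.nodes["A"].sigma2 == pytest.approx(np.var(y))


class TestPredictR2:
    def test_noiseless_training_r2_is_one(self):
        rng = np.random.default_rng(7)
        x0 = rng.normal(size=(500, 2))
        t1 = np.column_stack([2 + 0.5 * x0[:, 0], 1 - 0.3 * x0[:, 1]])
        lp = LagPairs(("A", "B"), x0, t1)
        dag = TwoSliceDAG(("A", "B"), {("A", "A"), ("B", "B")})
        r2 = predict_r2(fit_mle(dag, lp), lp)
        assert r2["A"] == pytest.approx(1.0)
        assert r2["B"] == pytest.approx(1.0)

    def test_pure_noise_out_of_sample_r2_near_zero(self):
        rng = np.random.default_rng(8)
        lp_train = LagPairs(("A",), rng.normal(size=(2000, 1)), rng.normal(size=(2000, 1)))
        lp_test = LagPairs(("A",), rng.normal(size=(2000, 1)), rng.normal(size=(2000, 1)))
        fit = fit_mle(TwoSliceDAG(("A",), {("A", "A")}), lp_train)
        assert abs(predict_r2(fit, lp_test)["A"]) <= 0.05

    def test_designed_r2_recovered(self):
        """sigma chosen from the signal variance for R^2 ~ 0.6."""
        rng = np.random.default_rng(9)
        beta, n = 0.8, 20000
        x0 = rng.normal(0, 1, n)
        signal_var = beta**2
        sigma = math.sqrt(signal_var * (1 - 0.6) / 0.6)
        x1 = beta * x0 + rng.normal(0, sigma, n)
        lp = LagPairs(("A",), x0[:, None], x1[:, None])
        fit = fit_mle(TwoSliceDAG(("A",), {("A", "A")}), lp)
        assert abs(predict_r2(fit, lp)["A"] - 0.6) < 0.05


@pytest.fixture(scope="module")
def tuned(default_panel):
    return tune_penalty(default_panel)


class TestTunePenalty:

    def test_reference_accuracy_ratio_is_one(self, tuned):
        assert tuned.table["accuracy_ratio"].iloc[0] == pytest.approx(1.0)

    def test_chosen_w_recovers_truth_arc_count(self, tuned, default_gt):
        """Sparse truth: arc count at the chosen w within 20% of the truth's."""
        truth_arcs = default_gt.dag.n_arcs
        row = tuned.table[tuned.table["w"] == tuned.chosen_w].iloc[0]
        assert abs(row["n_arcs"] - truth_arcs) <= 0.2 * truth_arcs

    def test_no_overfitting_signature(self, tuned):
        """Validation R^2 does not trail training R^2 by more than 0.05."""
        assert (tuned.table["valid_r2"] >= tuned.table["train_r2"] - 0.05).all()

    def test_bad_split_rejected(self, default_panel):
        with pytest.raises(ParameterError):
            tune_penalty(default_panel, split_week=99)
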