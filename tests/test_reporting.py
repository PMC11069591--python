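"""Variance-share attribution and generative stratified inference."""

import numpy as np
import pytest

from infodbn import (
    TwoSliceDAG,
    fit_mle,
    parent_variance_shares,
    simulate_from_dbn,
    stratified_share,
)
from infodbn.dbn import FittedDBN, LagPairs, NodeModel
from infodbn.errors import ParameterError


def _orthogonal_lp(betas, sigma=1.0, n=20000, seed=21):
    """t1 target driven by independent standardized t0 parents."""
    rng = np.random.default_rng(seed)
    p = len(betas)
    names = tuple(f"P{i}" for i in range(p)) + ("Y",)
    t0 = rng.normal(size=(n, p + 1))
    y1 = t0[:, :p] @ np.array(betas) + rng.normal(0, sigma, n)
    t1 = np.column_stack([rng.normal(size=(n, p)), y1])
    return LagPairs(names, t0, t1), names


class TestParentVarianceShares:
    def test_equal_orthogonal_parents_split_evenly(self):
        lp, names = _orthogonal_lp([0.5, 0.5])
        dag = TwoSliceDAG(names, {("P0", "Y"), ("P1", "Y")})
        rep = parent_variance_shares(fit_mle(dag, lp), lp, "Y")
        assert rep.shares["P0"] == pytest.approx(0.5, abs=0.02)
        assert rep.shares["P1"] == pytest.approx(0.5, abs=0.02)

    def test_share_ratio_follows_beta_squared(self):
        """Orthogonal regressors: explained variance scales with beta^2."""
        lp, names = _orthogonal_lp([0.6, 0.3])
        dag = TwoSliceDAG(names, {("P0", "Y"), ("P1", "Y")})
        rep = parent_variance_shares(fit_mle(dag, lp), lp, "Y")
        assert rep.shares["P0"] / rep.shares["P1"] == pytest.approx(4.0, rel=0.15)

    def test_shares_sum_to_one(self, default_gt, default_panel):
        from infodbn import build_lag_pairs

        lp = build_lag_pairs(default_panel)
        fit = fit_mle(default_gt.dag, lp)
        for target in default_gt.conditions:
            nonself = [p for p in default_gt.dag.parents(target) if p != target]
            if not nonself:
                continue
            rep = parent_variance_shares(fit, lp, target)
            assert sum(rep.shares.values()) == pytest.approx(1.0, abs=1e-9)

    def test_only_self_parent_reports_note(self):
        rng = np.random.default_rng(22)
        x0 = rng.normal(size=(500, 1))
        x1 = 0.5 * x0 + rng.normal(0, 1, (500, 1))
        lp = LagPairs(("A",), x0, x1)
        dag = TwoSliceDAG(("A",), {("A", "A")})
        rep = parent_variance_shares(fit_mle(dag, lp), lp, "A")
        assert rep.shares == {}
        assert "self" in rep.note

    def test_parentless_target_rejected(self):
        lp, names = _orthogonal_lp([0.5])
        dag = TwoSliceDAG(names)
        with pytest.raises(ParameterError):
            parent_variance_shares(fit_mle(dag, lp), lp, "Y")


@pytest.fixture(scope="module")
def fitted_system():
    rng = np.random.default_rng(23)
    n = 4000
    a0 = rng.normal(size=n)
    b0 = rng.normal(size=n)
    a1 = 1.0 + 0.6 * a0 + rng.normal(0, 0.8, n)
    b1 = -0.5 + 0.4 * a0 + 0.3 * b0 + rng.normal(0, 0.6, n)
    lp = LagPairs(("A", "B"), np.column_stack([a0, b0]), np.column_stack([a1, b1]))
    dag = TwoSliceDAG(("A", "B"), {("A", "A"), ("A", "B"), ("B", "B")})
    return fit_mle(dag, lp), lp


class TestSimulateFromDbn:
    def test_t1_means_match_fitted_conditional_means(self, fitted_system):
        fit, lp = fitted_system
        sim = simulate_from_dbn(fit, lp, 100_000, seed=1)
        for c in ("A", "B"):
            nm = fit.nodes[c]
            expected = nm.intercept + sum(
                beta * sim.t0[p].mean() for p, beta in nm.coefficients.items()
            )
            se = np.sqrt(sim.t1[c].var() / len(sim.t1))
            assert abs(sim.t1[c].mean() - expected) < 3 * se + 1e-3

    def test_no_coefficients_means_no_cross_slice_correlation(self):
        dag = TwoSliceDAG(("A",))
        fit = FittedDBN(dag, {"A": NodeModel(0.0, {}, 1.0)}, {"A": (0.0, 1.0)})
        rng = np.random.default_rng(24)
        lp = LagPairs(("A",), rng.normal(size=(1000, 1)), rng.normal(size=(1000, 1)))
        sim = simulate_from_dbn(fit, lp, 100_000, seed=2)
        r = np.corrcoef(sim.t0["A"], sim.t1["A"])[0, 1]
        assert abs(r) < 0.02

    def test_regression_on_samples_recovers_fitted_betas(self, fitted_system):
        fit, lp = fitted_system
        sim = simulate_from_dbn(fit, lp, 100_000, seed=3)
        X = np.column_stack([np.ones(len(sim.t0)), sim.t0["A"], sim.t0["B"]])
        beta, *_ = np.linalg.lstsq(X, sim.t1["B"].to_numpy(), rcond=None)
        assert beta[1] == pytest.approx(fit.nodes["B"].coefficients["A"], abs=0.02)
        assert beta[2] == pytest.approx(fit.nodes["B"].coefficients["B"], abs=0.02)

    def test_gaussian_t0_source_matches_marginals(self, fitted_system):
        fit, lp = fitted_system
        sim = simulate_from_dbn(fit, lp, 50_000, t0_source="gaussian", seed=4)
        mean, var = fit.t0_marginals["A"]
        assert sim.t0["A"].mean() == pytest.approx(mean, abs=0.02)
        assert sim.t0["A"].var() == pytest.approx(var, rel=0.05)

    def test_deterministic_given_seed(self, fitted_system):
        fit, lp = fitted_system
        a = simulate_from_dbn(fit, lp, 1000, seed=5)
        b = simulate_from_dbn(fit, lp, 1000, seed=5)
        assert a.t1.equals(b.t1)


def _confounded_system():
    """STR drives both TGT and FOC; FOC has no direct path to TGT."""
    conds = ("TGT", "FOC", "STR")
    dag = TwoSliceDAG(
        conds,
        {("TGT", "TGT"), ("STR", "TGT"), ("FOC", "FOC"), ("STR", "FOC"), ("STR", "STR")},
    )
    nodes = {
        "TGT": NodeModel(0.0, {"TGT": 0.1, "STR": 0.8}, 1.0),
        "FOC": NodeModel(0.0, {"FOC": 0.1, "STR": 0.45}, 2.25),
        "STR": NodeModel(0.0, {"STR": 0.6}, 1.0),
    }
    rng = np.random.default_rng(25)
    n0 = 5000
    levels = rng.choice([-3.0, 0.0, 3.0], size=n0, p=[0.25, 0.5, 0.25])
    s0 = levels + rng.normal(0, 0.2, n0)
    f0 = 0.45 * s0 + rng.normal(0, 1.5, n0)
    t0 = 0.8 * s0 + rng.normal(0, 1.0, n0)
    lp = LagPairs(conds, np.column_stack([t0, f0, s0]), np.zeros((n0, 3)))
    fit = FittedDBN(dag, nodes, {c: (0.0, 1.0) for c in conds})
    return fit, lp


class TestStratifiedShare:
    def test_confounded_share_collapses_within_strata(self):
        """Association running only through the stratifier vanishes once the
        stratifier level is held to a quartile band."""
        fit, lp = _confounded_system()
        res = stratified_share(fit, lp, "TGT", "FOC", "STR", n_sim=100_000, seed=6)
        for name, share in res.per_stratum.items():
            assert share <= res.unstratified / 3, name

    def test_independent_focal_has_negligible_share(self):
        conds = ("TGT", "FOC", "STR")
        dag = TwoSliceDAG(
            conds, {("TGT", "TGT"), ("FOC", "FOC"), ("STR", "STR"), ("STR", "TGT")}
        )
        nodes = {
            "TGT": NodeModel(0.0, {"TGT": 0.3, "STR": 0.5}, 1.0),
            "FOC": NodeModel(0.0, {"FOC": 0.3}, 1.0),
            "STR": NodeModel(0.0, {"STR": 0.5}, 1.0),
        }
        rng = np.random.default_rng(26)
        lp = LagPairs(conds, rng.normal(size=(4000, 3)), np.zeros((4000, 3)))
        fit = FittedDBN(dag, nodes, {c: (0.0, 1.0) for c in conds})
        res = stratified_share(fit, lp, "TGT", "FOC", "STR", n_sim=100_000, seed=7)
        assert res.unstratified < 0.01
        for share in res.per_stratum.values():
            assert share < 0.01

    def test_monte_carlo_reproducibility(self):
        fit, lp = _confounded_system()
        a = stratified_share(fit, lp, "TGT", "FOC", "STR", n_sim=100_000, seed=8)
        b = stratified_share(fit, lp, "TGT", "FOC", "STR", n_sim=100_000, seed=9)
        assert a.unstratified == pytest.approx(b.unstratified, rel=0.2)

    def test_distinct_roles_required(self):
        fit, lp = _confounded_system()
        with pytest.raises(ParameterError):
            stratified_share(fit, lp, "TGT", "TGT", "STR", n_sim=100, seed=0)
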