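"""Two-slice Gaussian dynamic Bayesian network learning.

The model regresses every condition in week t1 on a subset of the
conditions in week t0 (its parents), within the same county:

    X[i, t1] = mu_i + sum_j beta_ij * X[j, t0] + eps_i,   eps_i ~ N(0, sigma_i^2)

Arcs point forward in time only, so the two-slice graph is acyclic by
construction and the penalized log-likelihood score decomposes over t1
nodes.  Structure search is plain greedy hill-climbing over single-arc
additions and deletions; for small systems an exhaustive per-node
best-subset search provides an exact optimum to compare against.

Scoring uses sufficient statistics (Gram matrices), so evaluating a parent
set costs O(k^3) regardless of the number of rows.

The penalized score is ``log L - w * penalty_unit * n_params``.  With
``penalty_unit = log(n)/2`` (the default) a penalty coefficient of w=1 is
exactly the Bayesian Information Criterion; ``penalty_unit = log(n)``
gives the harsher literal reading of the same formula.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .errors import DegenerateDesignError, EmptyResultError, ParameterError
from .graphs import TwoSliceDAG
from .panel import PanelData

logger = logging.getLogger(__name__)

DEFAULT_W_GRID = (1, 2, 4, 8, 16, 32, 64, 128)
_EPS_IMPROVE = 1e-9


@dataclass
class LagPairs:
    """Stacked (t0, t1) rows: one per (county, consecutive week pair)."""

    conditions: tuple
    t0: np.ndarray  # (n, p)
    t1: np.ndarray  # (n, p)

    @property
    def n(self) -> int:
        return self.t0.shape[0]

    @property
    def p(self) -> int:
        return len(self.conditions)

    def subset_rows(self, idx: np.ndarray) -> "LagPairs":
        return LagPairs(self.conditions, self.t0[idx], self.t1[idx])

    def permute_conditions(self, order: np.ndarray) -> "LagPairs":
        conds = tuple(self.conditions[i] for i in order)
        return LagPairs(conds, self.t0[:, order], self.t1[:, order])


def build_lag_pairs(panel: PanelData, weeks: tuple | None = None) -> LagPairs:
    """Pair consecutive weeks within each county into regression rows.

    ``weeks=(lo, hi)`` restricts to week indices in ``[lo, hi)`` before
    pairing (used by the train/validation split of the penalty tuner).
    The panel must be complete on the retained rows.
    """
    f = panel.frame
    if weeks is not None:
        lo, hi = weeks
        f = f[(f["week"] >= lo) & (f["week"] < hi)]
    conds = panel.conditions
    t0_blocks, t1_blocks = [], []
    for _county, grp in f.groupby("county", sort=True):
        grp = grp.sort_values("week")
        vals = grp[conds].to_numpy()
        if len(vals) < 2:
            continue
        t0_blocks.append(vals[:-1])
        t1_blocks.append(vals[1:])
    if not t0_blocks:
        raise EmptyResultError("no county contributes a consecutive week pair")
    t0 = np.vstack(t0_blocks)
    t1 = np.vstack(t1_blocks)
    if np.isnan(t0).any() or np.isnan(t1).any():
        raise ParameterError("panel has missing values; impute before building lag pairs")
    return LagPairs(tuple(conds), t0, t1)


@dataclass
class ScoreResult:
    """A penalized log-likelihood evaluation of one two-slice DAG."""

    loglik: float
    n_params: int
    n: int
    w: float
    penalty_unit: float
    penalized: float
    per_node: dict = field(default_factory=dict, repr=False)


class GaussianScorer:
    """Penalized Gaussian log-likelihood over cached sufficient statistics.

    ``penalty_unit``: ``"half_log_n"`` (default; w=1 is BIC) or ``"log_n"``.
    ``include_t0``: add the marginal Gaussian terms of the t0 slice to the
    total score (a structure-independent constant).
    """

    def __init__(
        self,
        lag_pairs: LagPairs,
        w: float = 1.0,
        penalty_unit: str = "half_log_n",
        include_t0: bool = True,
    ):
        if w < 0:
            raise ParameterError("penalty coefficient w must be >= 0")
        self.lp = lag_pairs
        self.w = float(w)
        self.include_t0 = include_t0
        n, p = lag_pairs.t0.shape
        self.n = n
        self.p = p
        if penalty_unit == "half_log_n":
            self.unit = math.log(n) / 2.0
        elif penalty_unit == "log_n":
            self.unit = math.log(n)
        else:
            raise ParameterError(f"unknown penalty_unit {penalty_unit!r}")
        Z = np.column_stack([np.ones(n), lag_pairs.t0])
        self.G = Z.T @ Z          # (p+1, p+1)
        self.C = Z.T @ lag_pairs.t1  # (p+1, p)
        self.yy = np.einsum("ij,ij->j", lag_pairs.t1, lag_pairs.t1)
        self._cache: dict = {}

    # -- local terms -------------------------------------------------------

    def _solve(self, target: int, parents: tuple):
        idx = [0] + [j + 1 for j in parents]
        G = self.G[np.ix_(idx, idx)]
        c = self.C[idx, target]
        try:
            cho = linalg.cho_factor(G, lower=True, check_finite=False)
        except linalg.LinAlgError as exc:
            raise DegenerateDesignError(self.lp.conditions[target], str(exc)) from exc
        beta = linalg.cho_solve(cho, c, check_finite=False)
        rss = float(self.yy[target] - c @ beta)
        return beta, max(rss, 1e-300)

    def local_loglik(self, target: int, parents: tuple) -> float:
        """Profile Gaussian log-likelihood of one t1 node's OLS fit."""
        key = (target, parents)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        _, rss = self._solve(target, parents)
        sigma2 = rss / self.n
        ll = -0.5 * self.n * (math.log(2 * math.pi * sigma2) + 1.0)
        self._cache[key] = ll
        return ll

    def local_score(self, target: int, parents: tuple) -> float:
        n_params = len(parents) + 2  # coefficients + intercept + residual variance
        return self.local_loglik(target, parents) - self.w * self.unit * n_params

    def t0_marginal_loglik(self) -> tuple:
        """(loglik, n_params) of the marginal Gaussian fits of the t0 slice."""
        ll = 0.0
        for j in range(self.p):
            x = self.lp.t0[:, j]
            sigma2 = max(float(np.var(x)), 1e-300)
            ll += -0.5 * self.n * (math.log(2 * math.pi * sigma2) + 1.0)
        return ll, 2 * self.p

    # -- whole-graph score -------------------------------------------------

    def score_dag(self, dag: TwoSliceDAG) -> ScoreResult:
        cond_idx = {c: i for i, c in enumerate(self.lp.conditions)}
        loglik = 0.0
        n_params = 0
        per_node = {}
        for c in self.lp.conditions:
            t = cond_idx[c]
            parents = tuple(sorted(cond_idx[s] for s in dag.parents(c)))
            ll = self.local_loglik(t, parents)
            per_node[c] = ll
            loglik += ll
            n_params += len(parents) + 2
        if self.include_t0:
            ll0, k0 = self.t0_marginal_loglik()
            loglik += ll0
            n_params += k0
        penalized = loglik - self.w * self.unit * n_params
        return ScoreResult(loglik, n_params, self.n, self.w, self.unit, penalized, per_node)


def score(
    dag: TwoSliceDAG,
    lag_pairs: LagPairs,
    w: float = 1.0,
    penalty_unit: str = "half_log_n",
    include_t0: bool = True,
) -> ScoreResult:
    """Penalized log-likelihood of a two-slice DAG on the given rows."""
    if set(dag.conditions) != set(lag_pairs.conditions):
        raise ParameterError("DAG conditions do not match the lag-pair columns")
    return GaussianScorer(lag_pairs, w, penalty_unit, include_t0).score_dag(dag)


def _normalize_arc_set(arcs, conditions) -> set:
    idx = {c: i for i, c in enumerate(conditions)}
    out = set()
    for s, t in arcs or ():
        if s not in idx or t not in idx:
            raise ParameterError(f"arc ({s!r}, {t!r}) references unknown condition")
        out.add((idx[s], idx[t]))
    return out


def hill_climb(
    lag_pairs: LagPairs,
    w: float = 1.0,
    whitelist=None,
    blacklist=None,
    penalty_unit: str = "half_log_n",
    scorer: GaussianScorer | None = None,
) -> TwoSliceDAG:
    """Greedy structure search over t0->t1 arc additions and deletions.

    Starts from the empty graph (plus any whitelisted arcs), applies the
    single best score-improving move per step and stops when no move
    improves the score.  Ties are broken by (target, source) position in
    the column order of ``lag_pairs``, so permuting the columns (as the
    bootstrap does) perturbs tie resolution but nothing else.  Arc
    reversal is not a move: a reversed arc would point backward in time.
    """
    if scorer is None:
        scorer = GaussianScorer(lag_pairs, w, penalty_unit)
    conds = lag_pairs.conditions
    p = len(conds)
    white = _normalize_arc_set(whitelist, conds)
    black = _normalize_arc_set(blacklist, conds)
    if white & black:
        raise ParameterError("whitelist and blacklist overlap")

    parent_sets = [set() for _ in range(p)]
    for s, t in white:
        parent_sets[t].add(s)
    current = [
        scorer.local_score(t, tuple(sorted(parent_sets[t]))) for t in range(p)
    ]

    while True:
        best_delta = _EPS_IMPROVE
        best_move = None
        for t in range(p):
            base = current[t]
            ps = parent_sets[t]
            for s in range(p):
                if s in ps:
                    if (s, t) in white:
                        continue
                    cand = tuple(sorted(ps - {s}))
                else:
                    if (s, t) in black:
                        continue
                    cand = tuple(sorted(ps | {s}))
                delta = scorer.local_score(t, cand) - base
                if delta > best_delta:
                    best_delta = delta
                    best_move = (t, s)
        if best_move is None:
            break
        t, s = best_move
        if s in parent_sets[t]:
            parent_sets[t].discard(s)
        else:
            parent_sets[t].add(s)
        current[t] = scorer.local_score(t, tuple(sorted(parent_sets[t])))

    arcs = frozenset(
        (conds[s], conds[t]) for t in range(p) for s in parent_sets[t]
    )
    return TwoSliceDAG(conds, arcs)


def exhaustive_search(
    lag_pairs: LagPairs,
    w: float = 1.0,
    penalty_unit: str = "half_log_n",
    max_p: int = 12,
) -> TwoSliceDAG:
    """Exact optimum by enumerating every parent subset of every t1 node.

    Feasible because the score decomposes over t1 nodes and forward-only
    arcs can never form a cycle, so the per-node optima are independent.
    """
    p = lag_pairs.p
    if p > max_p:
        raise ParameterError(f"exhaustive search limited to p <= {max_p}")
    scorer = GaussianScorer(lag_pairs, w, penalty_unit)
    conds = lag_pairs.conditions
    arcs = set()
    for t in range(p):
        best = None
        best_sc = -np.inf
        for size in range(p + 1):
            for subset in itertools.combinations(range(p), size):
                sc = scorer.local_score(t, subset)
                if sc > best_sc + _EPS_IMPROVE:
                    best_sc = sc
                    best = subset
        for s in best:
            arcs.add((conds[s], conds[t]))
    return TwoSliceDAG(conds, frozenset(arcs))


@dataclass
class NodeModel:
    intercept: float
    coefficients: dict  # parent name -> coefficient
    sigma2: float


@dataclass
class FittedDBN:
    """Maximum-likelihood parameters attached to a two-slice DAG."""

    dag: TwoSliceDAG
    nodes: dict  # condition -> NodeModel (t1 local models)
    t0_marginals: dict  # condition -> (mean, variance)

    @property
    def conditions(self) -> tuple:
        return self.dag.conditions


def fit_mle(dag: TwoSliceDAG, lag_pairs: LagPairs) -> FittedDBN:
    """Per-node OLS coefficients and MLE residual variances (denominator n)."""
    if set(dag.conditions) != set(lag_pairs.conditions):
        raise ParameterError("DAG conditions do not match the lag-pair columns")
    scorer = GaussianScorer(lag_pairs)
    cond_idx = {c: i for i, c in enumerate(lag_pairs.conditions)}
    nodes = {}
    for c in lag_pairs.conditions:
        t = cond_idx[c]
        parent_names = dag.parents(c)
        parents = tuple(cond_idx[s] for s in parent_names)
        beta, rss = scorer._solve(t, parents)
        nodes[c] = NodeModel(
            intercept=float(beta[0]),
            coefficients={s: float(b) for s, b in zip(parent_names, beta[1:])},
            sigma2=rss / lag_pairs.n,
        )
    t0_marg = {
        c: (float(lag_pairs.t0[:, i].mean()), float(np.var(lag_pairs.t0[:, i])))
        for i, c in enumerate(lag_pairs.conditions)
    }
    return FittedDBN(dag, nodes, t0_marg)


def predict(fit: FittedDBN, lag_pairs: LagPairs) -> np.ndarray:
    """Fitted conditional means of the t1 slice on the given rows."""
    cond_idx = {c: i for i, c in enumerate(lag_pairs.conditions)}
    out = np.empty((lag_pairs.n, len(fit.conditions)))
    for j, c in enumerate(lag_pairs.conditions):
        nm = fit.nodes[c]
        yhat = np.full(lag_pairs.n, nm.intercept)
        for parent, beta in nm.coefficients.items():
            yhat += beta * lag_pairs.t0[:, cond_idx[parent]]
        out[:, j] = yhat
    return out


def predict_r2(fit: FittedDBN, lag_pairs: LagPairs) -> pd.Series:
    """Per-condition R^2 of the fitted predictor on the given rows.

    Returns a series indexed by condition, with an ``average`` entry
    (undefined R^2 for zero-variance targets is NaN and excluded from the
    average).
    """
    if set(fit.conditions) != set(lag_pairs.conditions):
        raise ParameterError("fit conditions do not match the lag-pair columns")
    yhat = predict(fit, lag_pairs)
    out = {}
    for j, c in enumerate(lag_pairs.conditions):
        y = lag_pairs.t1[:, j]
        tss = float(np.sum((y - y.mean()) ** 2))
        if tss <= 0:
            out[c] = np.nan
            continue
        rss = float(np.sum((y - yhat[:, j]) ** 2))
        out[c] = 1.0 - rss / tss
    vals = [v for v in out.values() if not np.isnan(v)]
    out["average"] = float(np.mean(vals)) if vals else np.nan
    return pd.Series(out)


@dataclass
class TuningResult:
    """Penalty-coefficient tuning table and the selected w."""

    chosen_w: float
    table: pd.DataFrame  # w, n_arcs, train_r2, valid_r2, accuracy_ratio
    ratio_floor: float

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def tune_penalty(
    panel: PanelData,
    w_grid=DEFAULT_W_GRID,
    split_week: int = 52,
    ratio_floor: float = 0.999,
    penalty_unit: str = "half_log_n",
    whitelist=None,
    blacklist=None,
) -> TuningResult:
    """Choose the arc penalty by a temporal train/validation split.

    Learns a DBN per penalty w on weeks before ``split_week``, evaluates
    average validation R^2 on the remaining weeks, and selects the largest
    w whose validation accuracy is at least ``ratio_floor`` times that of
    the smallest-w model (sparsest model with essentially undiminished
    predictive accuracy).
    """
    weeks = sorted(panel.frame["week"].unique())
    if split_week <= weeks[0] + 1 or split_week >= weeks[-1]:
        raise ParameterError(
            f"split_week={split_week} leaves fewer than 2 weeks on one side"
        )
    train_lp = build_lag_pairs(panel, weeks=(weeks[0], split_week))
    valid_lp = build_lag_pairs(panel, weeks=(split_week, weeks[-1] + 1))

    rows = []
    ref_valid = None
    for w in w_grid:
        dag = hill_climb(train_lp, w, whitelist, blacklist, penalty_unit)
        fit = fit_mle(dag, train_lp)
        train_r2 = float(predict_r2(fit, train_lp)["average"])
        valid_r2 = float(predict_r2(fit, valid_lp)["average"])
        if ref_valid is None:
            ref_valid = valid_r2
        ratio = valid_r2 / ref_valid if ref_valid else np.nan
        rows.append(
            {
                "w": w,
                "n_arcs": dag.n_arcs,
                "train_r2": train_r2,
                "valid_r2": valid_r2,
                "accuracy_ratio": ratio,
            }
        )
    table = pd.DataFrame(rows)
    ok = table[table["accuracy_ratio"] >= ratio_floor]
    chosen = float(ok["w"].max()) if len(ok) else float(table["w"].iloc[0])
    return TuningResult(chosen_w=chosen, table=table, ratio_floor=ratio_floor)
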