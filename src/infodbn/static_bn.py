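"""Static-BN misspecification audit.

A classical (static) Gaussian Bayesian network treats each county-week row
as an independent observation and does not replicate variables across time.
On panel data with strong spatio-temporal structure this model is
misspecified: its coefficients are inflated by the shared county baselines,
and its arcs conflate feedback loops, reversed directions and spurious
associations.  The audit quantifies this by (1) comparing coefficients
learned from raw vs. de-structured (residualized) data and (2) classifying
each static arc against the folded dynamic network taken as ground truth.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .baseline import SpatioTemporalBaseline
from .errors import DegenerateDesignError, ParameterError
from .graphs import FoldedGraph
from .panel import PanelData

logger = logging.getLogger(__name__)

_EPS_IMPROVE = 1e-9


@dataclass(frozen=True)
class StaticDAG:
    """Acyclic directed graph over single-slice condition nodes."""

    conditions: tuple
    arcs: frozenset = field(default_factory=frozenset)

    @property
    def n_arcs(self) -> int:
        return len(self.arcs)

    def parents(self, target: str) -> tuple:
        ps = {s for s, t in self.arcs if t == target}
        return tuple(c for c in self.conditions if c in ps)

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.conditions)
        g.add_edges_from(sorted(self.arcs))
        return g

    def skeleton(self) -> frozenset:
        return frozenset(tuple(sorted(a)) for a in self.arcs)


class _StaticScorer:
    """Penalized Gaussian score over single-slice rows, via sufficient stats."""

    def __init__(self, X: np.ndarray, conditions, w: float, penalty_unit: str):
        n, p = X.shape
        self.n, self.p = n, p
        self.conditions = tuple(conditions)
        self.w = float(w)
        if penalty_unit == "half_log_n":
            self.unit = math.log(n) / 2.0
        elif penalty_unit == "log_n":
            self.unit = math.log(n)
        else:
            raise ParameterError(f"unknown penalty_unit {penalty_unit!r}")
        Z = np.column_stack([np.ones(n), X])
        self.G = Z.T @ Z
        self.C = Z.T @ X
        self.yy = np.einsum("ij,ij->j", X, X)
        self._cache: dict = {}

    def solve(self, target: int, parents: tuple):
        idx = [0] + [j + 1 for j in parents]
        G = self.G[np.ix_(idx, idx)]
        c = self.C[idx, target]
        try:
            cho = linalg.cho_factor(G, lower=True, check_finite=False)
        except linalg.LinAlgError as exc:
            raise DegenerateDesignError(self.conditions[target], str(exc)) from exc
        beta = linalg.cho_solve(cho, c, check_finite=False)
        rss = float(self.yy[target] - c @ beta)
        return beta, max(rss, 1e-300)

    def local_score(self, target: int, parents: tuple) -> float:
        key = (target, parents)
        hit = self._cache.get(key)
        if hit is None:
            _, rss = self.solve(target, parents)
            sigma2 = rss / self.n
            ll = -0.5 * self.n * (math.log(2 * math.pi * sigma2) + 1.0)
            hit = ll - self.w * self.unit * (len(parents) + 2)
            self._cache[key] = hit
        return hit


def _creates_cycle(parent_sets, s: int, t: int) -> bool:
    """Would adding s -> t close a directed cycle? (DFS from s backwards)"""
    stack = [s]
    seen = set()
    while stack:
        node = stack.pop()
        if node == t:
            return True
        if node in seen:
            continue
        seen.add(node)
        stack.extend(parent_sets[node])
    return False


def learn_static(
    data,
    w: float = 1.0,
    conditions=None,
    penalty_unit: str = "half_log_n",
) -> StaticDAG:
    """Hill-climb a static Gaussian BN with add/delete/reverse moves.

    ``data`` is a DataFrame (columns = conditions) or an (n, p) array with
    ``conditions`` names.  The score family matches the dynamic learner;
    acyclicity is enforced on every move and ties are broken by
    (target, source) column position.
    """
    if isinstance(data, pd.DataFrame):
        conditions = tuple(data.columns)
        X = data.to_numpy(dtype=float)
    else:
        X = np.asarray(data, dtype=float)
        if conditions is None:
            raise ParameterError("conditions names required for array input")
        conditions = tuple(conditions)
    scorer = _StaticScorer(X, conditions, w, penalty_unit)
    p = scorer.p
    parent_sets = [set() for _ in range(p)]
    current = [scorer.local_score(t, ()) for t in range(p)]

    while True:
        best_delta = _EPS_IMPROVE
        best_move = None
        for t in range(p):
            ps = parent_sets[t]
            for s in range(p):
                if s == t:
                    continue
                if s in ps:
                    # delete s -> t
                    delta = scorer.local_score(t, tuple(sorted(ps - {s}))) - current[t]
                    if delta > best_delta:
                        best_delta, best_move = delta, ("delete", t, s)
                    # reverse s -> t into t -> s
                    if t not in parent_sets[s]:
                        ps_wo = parent_sets[t] - {s}
                        parent_sets[t] = ps_wo  # temporarily, for the cycle check
                        ok = not _creates_cycle(parent_sets, t, s)
                        parent_sets[t] = ps
                        if ok:
                            delta = (
                                scorer.local_score(t, tuple(sorted(ps_wo)))
                                - current[t]
                                + scorer.local_score(s, tuple(sorted(parent_sets[s] | {t})))
                                - current[s]
                            )
                            if delta > best_delta:
                                best_delta, best_move = delta, ("reverse", t, s)
                else:
                    if _creates_cycle(parent_sets, s, t):
                        continue
                    delta = scorer.local_score(t, tuple(sorted(ps | {s}))) - current[t]
                    if delta > best_delta:
                        best_delta, best_move = delta, ("add", t, s)
        if best_move is None:
            break
        kind, t, s = best_move
        if kind == "add":
            parent_sets[t].add(s)
        elif kind == "delete":
            parent_sets[t].discard(s)
        else:  # reverse
            parent_sets[t].discard(s)
            parent_sets[s].add(t)
            current[s] = scorer.local_score(s, tuple(sorted(parent_sets[s])))
        current[t] = scorer.local_score(t, tuple(sorted(parent_sets[t])))

    arcs = frozenset(
        (conditions[s], conditions[t]) for t in range(p) for s in parent_sets[t]
    )
    return StaticDAG(conditions, arcs)


def fit_static_coefficients(dag: StaticDAG, data) -> dict:
    """OLS coefficient of every arc in a static DAG: {(source, target): beta}."""
    if isinstance(data, pd.DataFrame):
        X = data[list(dag.conditions)].to_numpy(dtype=float)
    else:
        X = np.asarray(data, dtype=float)
    scorer = _StaticScorer(X, dag.conditions, 0.0, "half_log_n")
    idx = {c: i for i, c in enumerate(dag.conditions)}
    out = {}
    for t_name in dag.conditions:
        parent_names = dag.parents(t_name)
        if not parent_names:
            continue
        parents = tuple(idx[s] for s in parent_names)
        beta, _ = scorer.solve(idx[t_name], parents)
        for s_name, b in zip(parent_names, beta[1:]):
            out[(s_name, t_name)] = float(b)
    return out


def remove_spatiotemporal(
    panel: PanelData, baseline: SpatioTemporalBaseline, prewhiten: bool = False
) -> PanelData:
    """Subtract fitted state/county intercepts (and optionally AR(1) structure)."""
    return baseline.residualize(panel, prewhiten=prewhiten)


@dataclass
class CoefficientComparison:
    """Raw-vs-residualized coefficient audit over shared static arcs."""

    inflated_fraction: float  # |beta_raw| >= 2 |beta_resid|
    sign_flip_fraction: float
    n_shared: int
    inflated_fraction_union: float
    sign_flip_fraction_union: float
    n_union: int
    detail: pd.DataFrame


def compare_coefficients(coef_raw: dict, coef_resid: dict) -> CoefficientComparison:
    """Fractions of coefficients inflated >= 2x and with flipped sign.

    The primary figures use the intersection of the two arc sets; union
    figures (missing coefficients treated as 0, excluded from the sign
    comparison) are reported alongside.
    """
    shared = sorted(set(coef_raw) & set(coef_resid))
    union = sorted(set(coef_raw) | set(coef_resid))
    if not union:
        raise ParameterError("no arcs to compare")
    rows = []
    for arc in union:
        b_raw = coef_raw.get(arc, 0.0)
        b_res = coef_resid.get(arc, 0.0)
        rows.append(
            {
                "source": arc[0],
                "target": arc[1],
                "beta_raw": b_raw,
                "beta_resid": b_res,
                "shared": arc in coef_raw and arc in coef_resid,
                "inflated": abs(b_raw) >= 2 * abs(b_res),
                "sign_flip": (np.sign(b_raw) != np.sign(b_res))
                if (b_raw != 0 and b_res != 0)
                else np.nan,
            }
        )
    detail = pd.DataFrame(rows)
    sh = detail[detail["shared"]]
    if len(sh):
        inflated = float(sh["inflated"].mean())
        flips = sh["sign_flip"].dropna()
        sign_flip = float(flips.mean()) if len(flips) else np.nan
    else:
        inflated = sign_flip = np.nan
        logger.warning("raw and residualized fits share no arcs; union figures only")
    flips_u = detail["sign_flip"].dropna()
    return CoefficientComparison(
        inflated_fraction=inflated,
        sign_flip_fraction=sign_flip,
        n_shared=len(sh),
        inflated_fraction_union=float(detail["inflated"].mean()),
        sign_flip_fraction_union=float(flips_u.mean()) if len(flips_u) else np.nan,
        n_union=len(detail),
        detail=detail,
    )


@dataclass
class ArcClassification:
    """Static arcs classified against the folded dynamic network."""

    counts: dict  # class -> count over {correct, feedback_collapsed, reversed, spurious}
    fractions: dict
    n_arcs: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"class": k, "count": self.counts[k], "fraction": self.fractions[k]}
                for k in ("correct", "feedback_collapsed", "reversed", "spurious")
            ]
        )

    def summary(self) -> str:
        parts = [
            f"{k}: {self.counts[k]} ({100 * self.fractions[k]:.0f}%)"
            for k in ("correct", "feedback_collapsed", "reversed", "spurious")
        ]
        return f"{self.n_arcs} static arcs — " + ", ".join(parts)


def classify_arcs(static_dag: StaticDAG, folded: FoldedGraph) -> ArcClassification:
    """Classify each static arc X->Y against the folded dynamic truth.

    correct: folded has unidirectional X->Y; feedback_collapsed: folded has
    X<->Y; reversed: folded has Y->X only; spurious: no cross arc between
    X and Y.  Autoloops never enter the comparison (a static DAG cannot
    contain them).
    """
    if set(static_dag.conditions) != set(folded.nodes):
        raise ParameterError("static DAG and folded graph use different conditions")
    counts = {"correct": 0, "feedback_collapsed": 0, "reversed": 0, "spurious": 0}
    for s, t in static_dag.arcs:
        if tuple(sorted((s, t))) in folded.feedback:
            counts["feedback_collapsed"] += 1
        elif (s, t) in folded.unidirectional:
            counts["correct"] += 1
        elif (t, s) in folded.unidirectional:
            counts["reversed"] += 1
        else:
            counts["spurious"] += 1
    n = static_dag.n_arcs
    fractions = {k: (v / n if n else np.nan) for k, v in counts.items()}
    return ArcClassification(counts=counts, fractions=fractions, n_arcs=n)
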