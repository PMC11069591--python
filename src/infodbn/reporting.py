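"""Variance-share reporting and generative, stratified inference.

A parent's contribution to a t1 node is measured by explained variance in
the node's local regression.  Because the contribution of correlated
parents depends on the order they enter the model, the sequential
explained-variance increments are averaged over all orderings of the
non-self parents (LMG-style attribution); the self-parent (the condition's
own previous week) always enters first and is excluded from the normalized
shares, since autocorrelations are strong enough to dwarf everything else.

The fitted network is also a generative model: sampling the t0 slice and
pushing it through the local models yields joint (t0, t1) draws on which
conditional hypotheses can be tested by stratification, e.g. quartile
strata of a potential confounder.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dbn import FittedDBN, LagPairs
from .errors import ParameterError

_MAX_LMG_PARENTS = 16


@dataclass
class VarianceShareReport:
    """Explained-variance attribution of one target's parents."""

    target: str
    self_parent: str | None
    raw: dict  # non-self parent -> averaged explained-variance increment
    shares: dict  # non-self parent -> normalized share (sums to 1)
    self_variance: float  # explained variance of the self-parent term
    total_explained: float
    note: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"target": self.target, "parent": p, "raw": self.raw[p], "share": self.shares[p]}
            for p in sorted(self.raw)
        ]
        return pd.DataFrame(rows)


def _lmg_attribution(y: np.ndarray, base: np.ndarray | None, cols: dict) -> tuple:
    """Averaged-over-orderings explained-variance increments.

    ``base`` columns (always including the intercept, handled implicitly)
    enter first; ``cols`` maps candidate names to regressor columns.  The
    average increment of a candidate over all orderings equals the average
    over subsets S of the others of EV(S + j) - EV(S), weighted by
    1 / (m * C(m-1, |S|)).  Returns (raw increments dict, EV(base),
    EV(base + all)).
    """
    n = len(y)
    names = list(cols)
    m = len(names)
    if m > _MAX_LMG_PARENTS:
        raise ParameterError(f"LMG attribution limited to {_MAX_LMG_PARENTS} parents")
    yc = y - y.mean()
    tss = float(yc @ yc)

    def explained(subset: tuple) -> float:
        X = [np.ones(n)]
        if base is not None:
            X.extend(base.T)
        X.extend(cols[names[j]] for j in subset)
        X = np.column_stack(X)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return tss - float(resid @ resid)

    ev = {}
    for size in range(m + 1):
        for subset in itertools.combinations(range(m), size):
            ev[subset] = explained(subset)

    raw = {}
    for j in range(m):
        others = [k for k in range(m) if k != j]
        total = 0.0
        for size in range(m):
            weight = 1.0 / (m * math.comb(m - 1, size))
            for subset in itertools.combinations(others, size):
                with_j = tuple(sorted(subset + (j,)))
                total += weight * (ev[with_j] - ev[subset])
        raw[names[j]] = total / n  # per-observation variance units
    return raw, ev[()] / n, ev[tuple(range(m))] / n


def parent_variance_shares(
    fit: FittedDBN, lag_pairs: LagPairs, target: str
) -> VarianceShareReport:
    """Per-parent explained-variance shares of one t1 node.

    The self-parent (if present) enters the model first and its
    contribution is reported separately; the remaining parents' averaged
    sequential increments are normalized to sum to one.
    """
    if target not in fit.conditions:
        raise ParameterError(f"unknown target {target!r}")
    parents = fit.dag.parents(target)
    if not parents:
        raise ParameterError(f"target {target!r} has no parents")
    cond_idx = {c: i for i, c in enumerate(lag_pairs.conditions)}
    y = lag_pairs.t1[:, cond_idx[target]]
    self_parent = target if target in parents else None
    others = [p for p in parents if p != target]

    base = (
        lag_pairs.t0[:, [cond_idx[target]]] if self_parent is not None else None
    )
    if not others:
        raw, ev_base, _ = _lmg_attribution(y, base, {})
        return VarianceShareReport(
            target=target,
            self_parent=self_parent,
            raw={},
            shares={},
            self_variance=ev_base,
            total_explained=ev_base,
            note="only the self-parent is present; no shares to normalize",
        )

    cols = {p: lag_pairs.t0[:, cond_idx[p]] for p in others}
    raw, ev_base, ev_all = _lmg_attribution(y, base, cols)
    total_nonself = sum(raw.values())
    if total_nonself <= 0:
        shares = {p: np.nan for p in others}
        note = "non-self parents explain no variance"
    else:
        shares = {p: raw[p] / total_nonself for p in others}
        note = ""
    return VarianceShareReport(
        target=target,
        self_parent=self_parent,
        raw=raw,
        shares=shares,
        self_variance=ev_base,
        total_explained=ev_all,
        note=note,
    )


@dataclass
class SimulatedSlices:
    """Joint (t0, t1) draws from a fitted network used as a generative model."""

    t0: pd.DataFrame
    t1: pd.DataFrame


def simulate_from_dbn(
    fit: FittedDBN,
    lag_pairs: LagPairs,
    n_samples: int,
    t0_source: str = "empirical",
    seed: int | None = None,
) -> SimulatedSlices:
    """Forward-simulate joint (t0, t1) samples from the fitted local models.

    The t0 slice is drawn by resampling observed t0 rows (default), which
    preserves the joint dependence of the previous week, or from the
    fitted marginal Gaussians (``t0_source="gaussian"``, independent
    across conditions).  The t1 slice is then drawn from the per-node
    linear-Gaussian models.
    """
    if t0_source not in ("empirical", "gaussian"):
        raise ParameterError(f"unknown t0_source {t0_source!r}")
    rng = np.random.default_rng(seed)
    conds = list(lag_pairs.conditions)
    cond_idx = {c: i for i, c in enumerate(conds)}
    if t0_source == "empirical":
        idx = rng.integers(0, lag_pairs.n, size=n_samples)
        t0 = lag_pairs.t0[idx]
    else:
        t0 = np.column_stack(
            [
                rng.normal(fit.t0_marginals[c][0], np.sqrt(fit.t0_marginals[c][1]), n_samples)
                for c in conds
            ]
        )
    t1 = np.empty((n_samples, len(conds)))
    for j, c in enumerate(conds):
        nm = fit.nodes[c]
        mean = np.full(n_samples, nm.intercept)
        for parent, beta in nm.coefficients.items():
            mean += beta * t0[:, cond_idx[parent]]
        t1[:, j] = mean + rng.normal(0.0, np.sqrt(nm.sigma2), n_samples)
    return SimulatedSlices(
        t0=pd.DataFrame(t0, columns=conds), t1=pd.DataFrame(t1, columns=conds)
    )


@dataclass
class StratifiedShareResult:
    """Focal condition's same-week variance share, overall and per stratum."""

    target: str
    focal: str
    stratifier: str
    unstratified: float
    per_stratum: dict  # {"low", "average", "high"} -> share or NaN
    n_sim: int
    notes: dict = field(default_factory=dict)


def _focal_share(
    t0: pd.DataFrame, t1: pd.DataFrame, fit: FittedDBN, target: str, focal: str
) -> float:
    """Focal@t1's normalized share in the augmented regression of target@t1."""
    parents = fit.dag.parents(target)
    self_parent = target if target in parents else None
    y = t1[target].to_numpy()
    base = t0[[target]].to_numpy() if self_parent is not None else None
    cols = {f"{p}@t0": t0[p].to_numpy() for p in parents if p != target}
    focal_key = f"{focal}@t1"
    cols[focal_key] = t1[focal].to_numpy()
    raw, _, _ = _lmg_attribution(y, base, cols)
    total = sum(raw.values())
    if total <= 0:
        return np.nan
    return raw[focal_key] / total


def stratified_share(
    fit: FittedDBN,
    lag_pairs: LagPairs,
    target: str,
    focal: str,
    stratifier: str,
    n_sim: int = 100_000,
    seed: int | None = None,
    quartiles: str = "simulated",
) -> StratifiedShareResult:
    """Same-week association of a focal condition with a target, stratified.

    Joint (t0, t1) samples are simulated from the fitted network; strata
    are the stratifier's t0 quartiles (low = Q1, average = Q2-Q3,
    high = Q4) computed on the simulated draws (or on the observed rows
    with ``quartiles="empirical"``).  Within each stratum — and once
    overall — target@t1 is regressed on the focal condition at t1 plus the
    target's own parents, and the focal's normalized explained-variance
    share is reported.  Degenerate strata are reported as NaN.
    """
    for name in (target, focal, stratifier):
        if name not in fit.conditions:
            raise ParameterError(f"unknown condition {name!r}")
    if len({target, focal, stratifier}) != 3:
        raise ParameterError("target, focal and stratifier must be distinct")
    sim = simulate_from_dbn(fit, lag_pairs, n_sim, seed=seed)
    s0 = sim.t0[stratifier].to_numpy()
    if quartiles == "simulated":
        q1, q3 = np.quantile(s0, [0.25, 0.75])
    elif quartiles == "empirical":
        obs = lag_pairs.t0[:, list(lag_pairs.conditions).index(stratifier)]
        q1, q3 = np.quantile(obs, [0.25, 0.75])
    else:
        raise ParameterError(f"unknown quartiles mode {quartiles!r}")

    strata = {
        "low": s0 <= q1,
        "average": (s0 > q1) & (s0 < q3),
        "high": s0 >= q3,
    }
    unstratified = _focal_share(sim.t0, sim.t1, fit, target, focal)
    per_stratum = {}
    notes = {}
    for name, mask in strata.items():
        t0s, t1s = sim.t0[mask], sim.t1[mask]
        if mask.sum() < 10 or t1s[target].std() == 0:
            per_stratum[name] = np.nan
            notes[name] = "degenerate stratum"
            continue
        per_stratum[name] = _focal_share(t0s, t1s, fit, target, focal)
    return StratifiedShareResult(
        target=target,
        focal=focal,
        stratifier=stratifier,
        unstratified=unstratified,
        per_stratum=per_stratum,
        n_sim=n_sim,
        notes=notes,
    )
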