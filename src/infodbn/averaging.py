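"""Bootstrap model averaging: arc strengths, significance threshold, consensus.

Arc strength is the fraction of bootstrap-learned structures that contain
a given arc.  Resamples are drawn with replacement at a reduced size
(m-out-of-n bootstrap, default 75%), and the condition column order is
randomly permuted per resample so that search-order tie-breaking does not
leave a systematic imprint on the consensus.

The significance threshold is estimated from the strengths themselves:
the observed strength distribution is matched (in L1 distance between
CDFs) against the ideal configuration in which noise arcs have strength 0
and significant arcs strength 1; the estimated noise fraction maps to a
strength quantile that separates the two groups.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dbn import LagPairs, hill_climb
from .errors import InfoDBNError, ParameterError
from .graphs import TwoSliceDAG

logger = logging.getLogger(__name__)


@dataclass
class ArcStrengthTable:
    """Bootstrap inclusion frequency of every candidate t0->t1 arc."""

    conditions: tuple
    table: pd.DataFrame  # source, target, strength; sorted by descending strength
    B: int
    fraction: float
    seed: int | None

    def strength(self, source: str, target: str) -> float:
        t = self.table
        row = t[(t["source"] == source) & (t["target"] == target)]
        return float(row["strength"].iloc[0]) if len(row) else 0.0

    def strengths(self) -> np.ndarray:
        return self.table["strength"].to_numpy()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def bootstrap_strengths(
    lag_pairs: LagPairs,
    w: float = 1.0,
    B: int = 500,
    fraction: float = 0.75,
    seed: int | None = None,
    replace: bool = True,
    penalty_unit: str = "half_log_n",
    whitelist=None,
    blacklist=None,
) -> ArcStrengthTable:
    """Estimate arc strengths from B reduced-size bootstrap resamples.

    Each resample draws ``ceil(fraction * n)`` rows (with replacement by
    default), permutes the condition columns, and learns a structure by
    hill-climbing; an arc's strength is the fraction of resamples whose
    learned structure contains it.  Per-resample seeds are spawned from
    ``seed``, so the result does not depend on execution order and the
    resamples could be learned in parallel.
    """
    if B < 1:
        raise ParameterError("B must be >= 1")
    if not (0 < fraction <= 1):
        raise ParameterError("fraction must lie in (0, 1]")
    n, p = lag_pairs.n, lag_pairs.p
    m = int(np.ceil(fraction * n))
    counts: dict = {}
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(B)
    for b in range(B):
        rng = np.random.default_rng(children[b])
        for _attempt in range(10):
            rows = (
                rng.integers(0, n, size=m)
                if replace
                else rng.permutation(n)[:m]
            )
            order = rng.permutation(p)
            sub = lag_pairs.subset_rows(rows).permute_conditions(order)
            try:
                dag = hill_climb(sub, w, whitelist, blacklist, penalty_unit)
            except InfoDBNError as exc:  # degenerate resample: redraw, never skip
                logger.warning("resample %d failed (%s); redrawing", b, exc)
                continue
            break
        else:
            raise InfoDBNError(f"resample {b} failed repeatedly")
        for arc in dag.arcs:
            counts[arc] = counts.get(arc, 0) + 1

    conds = lag_pairs.conditions
    rows_out = [
        {"source": s, "target": t, "strength": counts.get((s, t), 0) / B}
        for s in conds
        for t in conds
    ]
    table = (
        pd.DataFrame(rows_out)
        .sort_values(["strength", "source", "target"], ascending=[False, True, True])
        .reset_index(drop=True)
    )
    return ArcStrengthTable(conds, table, B, fraction, seed)


def _noise_fraction_to_threshold(unique_vals, cdf_vals, a: float) -> float:
    """Strength quantile at noise fraction ``a``: midpoint of the gap after
    the last strength whose ECDF does not exceed ``a``."""
    j = int(np.searchsorted(cdf_vals, a + 1e-12, side="right")) - 1
    if j < 0:
        lower = 0.0
        upper = unique_vals[0]
    else:
        lower = unique_vals[j]
        upper = unique_vals[j + 1] if j + 1 < len(unique_vals) else 1.0
    return float(0.5 * (lower + upper))


def _l1_distance(unique_vals, cdf_vals, a: float) -> float:
    """L1 distance on [0, 1] between the strength ECDF and the constant a."""
    xs = np.concatenate([[0.0], unique_vals, [1.0]])
    # ECDF value on each segment [xs[i], xs[i+1])
    seg_vals = np.concatenate([[0.0], cdf_vals])
    seg_lens = np.diff(xs)
    return float(np.sum(np.abs(seg_vals - a) * seg_lens))


def estimate_threshold(strengths, fallback: float = 0.5) -> float:
    """Significance threshold separating noise from significant arc strengths.

    Minimizes the L1 distance between the empirical CDF of the strengths
    and the ideal two-point configuration (noise at 0 with mass ``a``,
    significant arcs at 1); the optimal ``a`` is the length-weighted median
    of the ECDF, and the threshold is the strength quantile at that noise
    fraction (the midpoint of the separating gap, so the comparison
    ``strength > threshold`` is robust to ties).
    """
    s = np.sort(np.asarray(list(strengths), dtype=float))
    if len(s) < 2 or np.all(s == s[0]):
        warnings.warn("strengths show no separation; returning fallback threshold")
        return fallback
    if s[0] < 0 or s[-1] > 1:
        raise ParameterError("strengths must lie in [0, 1]")
    unique_vals, counts = np.unique(s, return_counts=True)
    cdf_vals = np.cumsum(counts) / len(s)

    # weighted median of the segment ECDF values, weights = segment lengths
    xs = np.concatenate([[0.0], unique_vals, [1.0]])
    seg_vals = np.concatenate([[0.0], cdf_vals])
    seg_lens = np.diff(xs)
    keep = seg_lens > 0
    order = np.argsort(seg_vals[keep], kind="mergesort")
    v = seg_vals[keep][order]
    wts = seg_lens[keep][order]
    cum = np.cumsum(wts)
    half = cum[-1] / 2.0
    i = int(np.searchsorted(cum, half))
    if np.isclose(cum[i], half) and i + 1 < len(v):
        a_star = 0.5 * (v[i] + v[i + 1])  # tie interval: midpoint representative
    else:
        a_star = v[i]

    return _noise_fraction_to_threshold(unique_vals, cdf_vals, a_star)


def threshold_grid_search(strengths, grid_size: int = 2001) -> tuple:
    """Brute-force L1 minimization over a fine grid of noise fractions.

    Independent check of :func:`estimate_threshold`: returns
    ``(a_star, threshold)`` where ``a_star`` minimizes the L1 distance over
    the grid and ``threshold`` is the corresponding strength quantile.
    """
    s = np.sort(np.asarray(list(strengths), dtype=float))
    unique_vals, counts = np.unique(s, return_counts=True)
    cdf_vals = np.cumsum(counts) / len(s)
    grid = np.linspace(0.0, 1.0, grid_size)
    dists = np.array([_l1_distance(unique_vals, cdf_vals, a) for a in grid])
    a_star = float(grid[int(np.argmin(dists))])
    return a_star, _noise_fraction_to_threshold(unique_vals, cdf_vals, a_star)


def _greedy_acyclic_arcs(candidates: list, acyclic: bool) -> list:
    """Insert arcs in decreasing strength, discarding cycle-forming ones.

    ``candidates`` is a list of (strength, source, target), assumed sorted
    by decreasing strength with lexicographic tie-breaks.  With
    ``acyclic=False`` (the two-slice case) every arc is kept: forward-only
    arcs cannot form cycles.
    """
    import networkx as nx

    kept = []
    g = nx.DiGraph()
    for strength, s, t in candidates:
        if acyclic and s != t:
            if g.has_node(t) and g.has_node(s) and nx.has_path(g, t, s):
                logger.info("discarding cycle-forming arc %s -> %s (%.3f)", s, t, strength)
                continue
        if acyclic and s == t:
            continue  # self-loops are never admissible in a static DAG
        kept.append((s, t))
        g.add_edge(s, t)
    return kept


def consensus_arcs(
    strength_table: pd.DataFrame, threshold: float, acyclic: bool = False
) -> list:
    """Arcs with strength strictly above the threshold, cycle rule applied."""
    if not (0 < threshold < 1):
        raise ParameterError("threshold must lie in (0, 1)")
    t = strength_table
    sel = t[t["strength"] > threshold]
    candidates = [
        (float(r["strength"]), r["source"], r["target"])
        for _, r in sel.sort_values(
            ["strength", "source", "target"], ascending=[False, True, True]
        ).iterrows()
    ]
    return _greedy_acyclic_arcs(candidates, acyclic)


def consensus_dag(strengths: ArcStrengthTable, threshold: float) -> TwoSliceDAG:
    """Consensus two-slice DAG from an arc-strength table.

    Arcs whose strength strictly exceeds the threshold are inserted in
    decreasing strength order.  The cycle-discard rule is applied verbatim
    even though forward-only two-slice arcs cannot create cycles (the rule
    only activates when this routine is reused for static networks).
    """
    arcs = consensus_arcs(strengths.table, threshold, acyclic=False)
    return TwoSliceDAG(strengths.conditions, frozenset(arcs))
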