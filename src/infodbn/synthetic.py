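"""Synthetic spatio-temporal panels with a known two-slice generating network.

The generator emulates the statistical structure the downstream analysis
assumes: a stable VAR(1)-style cross-condition process inside each county,
additive state and county baselines that are constant over time (random
intercepts), and realistic missingness patterns (isolated cells and runs of
four consecutive weeks).  Because the generating two-slice DAG is known,
every downstream stage — imputation, variance decomposition, structure
learning, averaging, folding — can be scored against a recoverable truth.

Default variance calibration targets a panel in which state membership
accounts for about 12% and county membership for about 49% of each
condition's total variance, with the remainder driven by the within-county
autoregressive process.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .errors import InfeasibleGraphError, ParameterError, UnstableModelError
from .graphs import TwoSliceDAG, fold
from .panel import PanelData

_STABILITY_MARGIN = 0.95  # rescale target for the spectral radius


@dataclass
class LocalParams:
    """Linear-Gaussian local model of one condition at t1."""

    intercept: float
    coefficients: dict  # parent condition -> coefficient
    residual_sd: float


@dataclass
class GroundTruth:
    """A generating two-slice DBN plus its spatial variance components."""

    dag: TwoSliceDAG
    params: dict  # condition -> LocalParams
    state_sd: float
    county_sd: float
    n_feedback: int

    @property
    def conditions(self) -> tuple:
        return self.dag.conditions

    def coefficient_matrix(self) -> np.ndarray:
        """Folded p x p matrix B with B[i, j] = coefficient of j@t0 -> i@t1."""
        conds = self.conditions
        p = len(conds)
        B = np.zeros((p, p))
        idx = {c: i for i, c in enumerate(conds)}
        for c, lp in self.params.items():
            for parent, beta in lp.coefficients.items():
                B[idx[c], idx[parent]] = beta
        return B

    def residual_cov(self) -> np.ndarray:
        return np.diag([self.params[c].residual_sd ** 2 for c in self.conditions])

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.coefficient_matrix()))))

    def stationary_cov(self) -> np.ndarray:
        """Stationary covariance of the within-county VAR(1) deviations."""
        B = self.coefficient_matrix()
        if np.max(np.abs(np.linalg.eigvals(B))) >= 1:
            raise UnstableModelError("spectral radius >= 1; no stationary distribution")
        return linalg.solve_discrete_lyapunov(B, self.residual_cov())

    def stationary_mean(self) -> np.ndarray:
        B = self.coefficient_matrix()
        mu = np.array([self.params[c].intercept for c in self.conditions])
        return np.linalg.solve(np.eye(len(mu)) - B, mu)

    def validate(self) -> None:
        for c in self.conditions:
            lp = self.params[c]
            if lp.residual_sd <= 0:
                raise UnstableModelError(f"residual_sd of {c!r} must be > 0")
            if c not in lp.coefficients:
                raise UnstableModelError(f"{c!r} lacks a self-parent coefficient")
            if abs(lp.coefficients[c]) >= 1:
                raise UnstableModelError(f"self-coefficient of {c!r} has magnitude >= 1")
        if self.spectral_radius() >= 1:
            raise UnstableModelError(
                f"folded coefficient matrix has spectral radius "
                f"{self.spectral_radius():.3f} >= 1"
            )

    # -- fixture serialization (plain text) --------------------------------

    def to_text(self) -> str:
        def fmt(x) -> str:
            arr = np.atleast_1d(np.asarray(x, dtype=float))
            return ",".join(repr(float(v)) for v in arr)

        buf = io.StringIO()
        print(f"# ground truth: p={len(self.conditions)} n_feedback={self.n_feedback}", file=buf)
        print(f"state_sd\t{fmt(self.state_sd)}", file=buf)
        print(f"county_sd\t{fmt(self.county_sd)}", file=buf)
        for c in self.conditions:
            lp = self.params[c]
            print(f"node\t{c}\t{lp.intercept!r}\t{lp.residual_sd!r}", file=buf)
            for parent, beta in sorted(lp.coefficients.items()):
                print(f"arc\t{parent}\t{c}\t{beta!r}", file=buf)
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "GroundTruth":
        def parse_sd(s: str):
            vals = [float(v) for v in s.split(",")]
            return vals[0] if len(vals) == 1 else np.array(vals)

        state_sd = county_sd = 0.0
        n_feedback = 0
        params: dict = {}
        order: list = []
        arcs = set()
        for line in text.splitlines():
            if line.startswith("#"):
                if "n_feedback=" in line:
                    n_feedback = int(line.split("n_feedback=")[1])
                continue
            if not line.strip():
                continue
            parts = line.split("\t")
            if parts[0] == "state_sd":
                state_sd = parse_sd(parts[1])
            elif parts[0] == "county_sd":
                county_sd = parse_sd(parts[1])
            elif parts[0] == "node":
                order.append(parts[1])
                params[parts[1]] = LocalParams(float(parts[2]), {}, float(parts[3]))
            elif parts[0] == "arc":
                parent, child, beta = parts[1], parts[2], float(parts[3])
                params[child].coefficients[parent] = beta
                arcs.add((parent, child))
        dag = TwoSliceDAG(tuple(order), frozenset(arcs))
        return cls(dag, params, state_sd, county_sd, n_feedback)


def _condition_names(p: int) -> tuple:
    width = max(2, len(str(p)))
    return tuple(f"C{i + 1:0{width}d}" for i in range(p))


def make_ground_truth(
    p: int,
    n_feedback: int,
    n_unidirectional: int,
    coeff_range: tuple = (0.2, 0.6),
    auto_range: tuple = (0.5, 0.8),
    residual_sd: float = 1.0,
    base_mean: float = 10.0,
    state_frac: float = 0.0,
    county_frac: float = 0.0,
    seed: int | None = None,
) -> GroundTruth:
    """Draw a stable generating network with prescribed arc classes.

    The folded graph has exactly ``n_feedback`` bidirectional pairs,
    ``n_unidirectional`` one-way cross arcs and an autoloop on every
    condition.  Cross coefficients are drawn uniformly from
    ``+-[coeff_range]``, self-coefficients from ``[auto_range]``; if the
    folded coefficient matrix is not comfortably stable the whole matrix is
    rescaled (preserving the sparsity pattern) until its spectral radius is
    below one.

    ``state_frac``/``county_frac`` set the target shares of total variance
    carried by the state and county random intercepts; the corresponding
    standard deviations are derived from the average stationary
    within-county variance.  The default (0, 0) is a purely temporal panel
    — the model class the structure learner assumes; use
    :func:`with_variance_fractions` to add the nested spatial baselines of
    a realistic panel.
    """
    if p < 2:
        raise ParameterError("need at least 2 conditions")
    n_pairs = p * (p - 1) // 2
    if n_feedback < 0 or n_unidirectional < 0:
        raise InfeasibleGraphError("arc counts must be nonnegative")
    if n_feedback > n_pairs:
        raise InfeasibleGraphError(f"n_feedback={n_feedback} exceeds {n_pairs} available pairs")
    if n_feedback + n_unidirectional > n_pairs:
        raise InfeasibleGraphError(
            f"n_feedback + n_unidirectional = {n_feedback + n_unidirectional} "
            f"exceeds the {n_pairs} off-diagonal pairs"
        )
    if not (0 <= state_frac and 0 <= county_frac and state_frac + county_frac < 1):
        raise ParameterError("state_frac + county_frac must lie in [0, 1)")
    lo, hi = coeff_range
    if not (0 < lo <= hi):
        raise ParameterError("coeff_range must satisfy 0 < lo <= hi")

    rng = np.random.default_rng(seed)
    conds = _condition_names(p)

    pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
    chosen = rng.choice(len(pairs), size=n_feedback + n_unidirectional, replace=False)
    feedback_pairs = [pairs[k] for k in chosen[:n_feedback]]
    uni_pairs = [pairs[k] for k in chosen[n_feedback:]]

    arcs = {(conds[i], conds[i]) for i in range(p)}
    for i, j in feedback_pairs:
        arcs.add((conds[i], conds[j]))
        arcs.add((conds[j], conds[i]))
    for i, j in uni_pairs:
        if rng.random() < 0.5:
            i, j = j, i
        arcs.add((conds[i], conds[j]))

    dag = TwoSliceDAG(conds, frozenset(arcs))

    params = {}
    for c in conds:
        coefs = {}
        for parent in dag.parents(c):
            if parent == c:
                coefs[c] = float(rng.uniform(*auto_range))
            else:
                mag = rng.uniform(lo, hi)
                coefs[parent] = float(mag if rng.random() < 0.5 else -mag)
        params[c] = LocalParams(intercept=0.0, coefficients=coefs, residual_sd=residual_sd)

    gt = GroundTruth(dag, params, 0.0, 0.0, n_feedback)
    rho = gt.spectral_radius()
    if rho >= _STABILITY_MARGIN:
        scale = _STABILITY_MARGIN / rho
        for c in conds:
            params[c].coefficients = {k: v * scale for k, v in params[c].coefficients.items()}


    # intercepts chosen so the stationary mean sits well above zero
    B = gt.coefficient_matrix()
    target_mean = base_mean * np.ones(p)
    mu = (np.eye(p) - B) @ target_mean
    for i, c in enumerate(conds):
        params[c].intercept = float(mu[i])

    # calibrate spatial variance components against the within-county variance
    if state_frac > 0 or county_frac > 0:
        gt = with_variance_fractions(gt, state_frac, county_frac)

    gt.validate()
    return gt


def with_variance_fractions(
    gt: GroundTruth, state_frac: float = 0.12, county_frac: float = 0.49
) -> GroundTruth:
    """Set the spatial variance components to target shares of total variance.

    The defaults emulate a panel in which state membership carries about
    12% and county membership about 49% of each condition's variance.
    Standard deviations are derived per condition from its stationary
    within-county variance, so the shares hold condition by condition
    regardless of how heterogeneous the VAR dynamics are.
    """
    if not (0 <= state_frac and 0 <= county_frac and state_frac + county_frac < 1):
        raise ParameterError("state_frac + county_frac must lie in [0, 1)")
    import copy

    out = copy.deepcopy(gt)
    within = np.diag(gt.stationary_cov())
    resid_frac = 1.0 - state_frac - county_frac
    out.state_sd = np.sqrt(state_frac * within / resid_frac)
    out.county_sd = np.sqrt(county_frac * within / resid_frac)
    return out


def simulate_panel(
    gt: GroundTruth,
    n_states: int = 10,
    counties_per_state: int = 20,
    n_weeks: int = 100,
    seed: int | None = None,
    burn_in: int = 50,
) -> PanelData:
    """Simulate a weekly panel from a ground-truth network.

    Within each county the conditions follow the VAR(1) process implied by
    the folded coefficient matrix, on top of state- and county-level random
    intercepts.  A burn-in of ``burn_in`` weeks (started from a draw of the
    stationary distribution) is discarded.  Values are shifted by a
    per-condition constant so that at least 99.9% are nonnegative, then
    clipped at zero; the clipping fraction is kept below 0.1%.
    """
    if n_weeks < 3:
        raise ParameterError("n_weeks must be >= 3")
    if n_states < 1 or counties_per_state < 1:
        raise ParameterError("n_states and counties_per_state must be >= 1")
    gt.validate()

    rng = np.random.default_rng(seed)
    conds = gt.conditions
    p = len(conds)
    B = gt.coefficient_matrix()
    sigma = np.array([gt.params[c].residual_sd for c in conds])
    m = gt.stationary_mean()
    stat_cov = gt.stationary_cov()
    chol = np.linalg.cholesky(stat_cov + 1e-12 * np.eye(p))

    n_counties = n_states * counties_per_state
    state_ids = [f"S{s + 1:02d}" for s in range(n_states)]
    state_sd = np.broadcast_to(np.asarray(gt.state_sd, dtype=float), (p,))
    county_sd = np.broadcast_to(np.asarray(gt.county_sd, dtype=float), (p,))
    a_s = rng.normal(size=(n_states, p)) * state_sd
    b_c = rng.normal(size=(n_counties, p)) * county_sd

    total = burn_in + n_weeks
    # innovations: (county, week, condition)
    eps = rng.normal(size=(n_counties, total, p)) * sigma
    z0 = rng.normal(size=(n_counties, p)) @ chol.T

    z = np.empty((n_counties, total, p))
    prev = z0
    for t in range(total):
        prev = prev @ B.T + eps[:, t, :]
        z[:, t, :] = prev
    z = z[:, burn_in:, :]

    rows = []
    frames = []
    for ci in range(n_counties):
        si = ci // counties_per_state
        county_id = f"{state_ids[si]}C{ci % counties_per_state + 1:03d}"
        x = m + a_s[si] + b_c[ci] + z[ci]
        df = pd.DataFrame(x, columns=list(conds))
        df.insert(0, "week", np.arange(n_weeks))
        df.insert(0, "county", county_id)
        df.insert(0, "state", state_ids[si])
        frames.append(df)
    frame = pd.concat(frames, ignore_index=True)

    # nonnegativity: shift so that >= 99.9% of each condition is nonnegative
    vals = frame[list(conds)].to_numpy()
    q = np.quantile(vals, 0.001, axis=0)
    shift = np.where(q < 0, -q, 0.0)
    vals = vals + shift
    clip_frac = float(np.mean(vals < 0))
    np.clip(vals, 0.0, None, out=vals)
    frame[list(conds)] = vals
    panel = PanelData(frame)
    panel.clip_fraction = clip_frac
    return panel


def inject_missingness(
    panel: PanelData,
    rate: float,
    mode: str = "single",
    seed: int | None = None,
) -> PanelData:
    """Return a copy of a fully observed panel with cells knocked out.

    ``mode='single'`` removes independently sampled (county, condition,
    week) cells; ``mode='batch4'`` removes runs of four consecutive weeks
    (emulating a month without measurements), truncated only at series
    ends and never merged with an existing missing run.  The realized
    missing fraction is within +-0.5 percentage points of ``rate``.
    """
    if not (0 < rate < 1):
        raise ParameterError(f"rate must lie in (0, 1), got {rate}")
    if mode not in ("single", "batch4"):
        raise ParameterError(f"unknown mode {mode!r}")

    rng = np.random.default_rng(seed)
    frame = panel.frame.copy()
    conds = panel.conditions
    vals = frame[conds].to_numpy().copy()
    if np.isnan(vals).any():
        raise ParameterError("panel must be fully observed at the targeted cells")

    counties = frame["county"].to_numpy()
    county_list = [c for c in pd.unique(counties)]
    county_rows = {c: np.flatnonzero(counties == c) for c in county_list}
    n_cells = vals.size
    target = int(round(rate * n_cells))

    if mode == "single":
        flat = rng.choice(n_cells, size=target, replace=False)
        vals.ravel()[flat] = np.nan
    else:
        missing = np.zeros(vals.shape, dtype=bool)
        n_missing = 0
        attempts = 0
        while n_missing < target:
            attempts += 1
            if attempts > 200 * max(target, 1):
                raise ParameterError(
                    "could not place non-adjacent runs of 4 at the requested rate"
                )
            ci = rng.integers(len(county_list))
            rows = county_rows[county_list[ci]]
            j = rng.integers(len(conds))
            start = rng.integers(len(rows))
            run = rows[start : start + 4]
            # keep injected runs maximal: no overlap/adjacency with existing gaps
            lo = max(start - 1, 0)
            hi = min(start + 5, len(rows))
            if missing[rows[lo:hi], j].any():
                continue
            missing[run, j] = True
            n_missing += len(run)
        vals[missing] = np.nan

    frame[conds] = vals
    return PanelData(frame, validate_nonnegative=False)
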