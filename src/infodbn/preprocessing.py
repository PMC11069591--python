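"""Missing-data management: condition filtering, imputation, benchmarking.

Imputation operates on one (county, condition) weekly series at a time.
The default method is a two-sided exponentially weighted moving average:
a missing cell is replaced by the weighted mean of up to ``k`` observed
neighbours on each side, with weight ``2**(-lag)`` for a neighbour ``lag``
weeks away, renormalized over the neighbours actually available.  Linear
interpolation and a Kalman smoother (local level model) are provided as
comparators for the injection benchmark.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyResultError, ParameterError, UnimputableSeriesError
from .panel import PanelData
from .synthetic import inject_missingness

logger = logging.getLogger(__name__)

DEFAULT_MIN_OBSERVED = 5


def filter_conditions(panel: PanelData, max_missing: float = 0.30) -> PanelData:
    """Drop conditions whose overall missing fraction strictly exceeds the cap.

    A condition at exactly ``max_missing`` is retained ("more than" is read
    as a strict inequality).
    """
    frac = panel.missing_fraction()
    keep = [c for c in panel.conditions if frac[c] <= max_missing]
    dropped = [c for c in panel.conditions if c not in keep]
    if dropped:
        logger.info("dropping conditions over %.0f%% missing: %s", 100 * max_missing, dropped)
    if not keep:
        raise EmptyResultError("every condition exceeds the missingness cap")
    return panel.select_conditions(keep)


def impute_ewma(series: np.ndarray, k: int = 4, min_observed: int = DEFAULT_MIN_OBSERVED) -> np.ndarray:
    """Impute one series with a two-sided exponentially weighted moving average.

    Each missing cell is filled with the weighted mean of up to ``k``
    observed neighbours on each side, weight ``2**(-lag)``; observed cells
    are returned untouched.
    """
    x = np.asarray(series, dtype=float).copy()
    obs_idx = np.flatnonzero(~np.isnan(x))
    if len(obs_idx) < min_observed:
        raise UnimputableSeriesError(
            f"{len(obs_idx)} observed values < min_observed={min_observed}"
        )
    for i in np.flatnonzero(np.isnan(x)):
        left = obs_idx[obs_idx < i][-k:]
        right = obs_idx[obs_idx > i][:k]
        neigh = np.concatenate([left, right])
        w = 2.0 ** (-np.abs(neigh - i))
        x[i] = np.sum(w * x[neigh]) / np.sum(w)
    return x


def impute_linear(series: np.ndarray, min_observed: int = DEFAULT_MIN_OBSERVED) -> np.ndarray:
    """Linear interpolation between observed neighbours, flat at the ends."""
    x = np.asarray(series, dtype=float).copy()
    obs_idx = np.flatnonzero(~np.isnan(x))
    if len(obs_idx) < min_observed:
        raise UnimputableSeriesError(
            f"{len(obs_idx)} observed values < min_observed={min_observed}"
        )
    gaps = np.flatnonzero(np.isnan(x))
    x[gaps] = np.interp(gaps, obs_idx, x[obs_idx])
    return x


def impute_kalman(series: np.ndarray, min_observed: int = DEFAULT_MIN_OBSERVED) -> np.ndarray:
    """Optional comparator: local-level state-space smoother.

    Fits a Gaussian local level model by maximum likelihood and fills the
    gaps with the smoothed state.
    """
    import statsmodels.api as sm

    x = np.asarray(series, dtype=float).copy()
    obs_idx = np.flatnonzero(~np.isnan(x))
    if len(obs_idx) < min_observed:
        raise UnimputableSeriesError(
            f"{len(obs_idx)} observed values < min_observed={min_observed}"
        )
    model = sm.tsa.UnobservedComponents(x, level="llevel")
    res = model.fit(disp=False)
    gaps = np.isnan(x)
    x[gaps] = res.smoothed_state[0][gaps]
    return x


IMPUTERS = {"ewma": impute_ewma, "linear": impute_linear, "kalman": impute_kalman}


def impute_panel(
    panel: PanelData,
    method: str = "ewma",
    k: int = 4,
    min_observed: int = DEFAULT_MIN_OBSERVED,
) -> PanelData:
    """Impute every incomplete (county, condition) series of a panel.

    Series with fewer than ``min_observed`` observed values are left
    missing (route them through :func:`drop_unimputable` afterwards).
    """
    if method not in IMPUTERS:
        raise ParameterError(f"unknown imputation method {method!r}")
    fn = IMPUTERS[method]
    kwargs = {"k": k} if method == "ewma" else {}
    frame = panel.frame.copy()
    vals = frame[panel.conditions].to_numpy().copy()
    counties = frame["county"].to_numpy()
    for county in pd.unique(counties):
        rows = np.flatnonzero(counties == county)
        for j, _cond in enumerate(panel.conditions):
            col = vals[rows, j]
            if not np.isnan(col).any():
                continue
            try:
                vals[rows, j] = fn(col, min_observed=min_observed, **kwargs)
            except UnimputableSeriesError:
                continue
    frame[panel.conditions] = vals
    return PanelData(frame, validate_nonnegative=False)


def drop_unimputable(panel: PanelData, min_observed: int = DEFAULT_MIN_OBSERVED) -> PanelData:
    """Blank out (county, condition) series with too few observed values.

    The dropped series become entirely missing; the panel keeps its shape.
    The number of dropped series and the resulting observed-cell count are
    logged (the real-data analogue is a reduction from 287,900 to 287,866
    county-weeks).
    """
    frame = panel.frame.copy()
    vals = frame[panel.conditions].to_numpy().copy()
    counties = frame["county"].to_numpy()
    n_dropped = 0
    for county in pd.unique(counties):
        rows = np.flatnonzero(counties == county)
        for j in range(len(panel.conditions)):
            n_obs = int(np.sum(~np.isnan(vals[rows, j])))
            if 0 < n_obs < min_observed or n_obs == 0:
                if not np.isnan(vals[rows, j]).all():
                    n_dropped += 1
                vals[rows, j] = np.nan
    frame[panel.conditions] = vals
    out = PanelData(frame, validate_nonnegative=False)
    logger.info(
        "dropped %d unimputable series; %d observed cells remain",
        n_dropped,
        int(out.mask().to_numpy().sum()),
    )
    return out


@dataclass
class ImputationReport:
    """Mean relative imputation error per (method, rate, mode) setting."""

    table: pd.DataFrame  # method, rate, mode, mean_relative_error, n_cells, n_zero_true_cells, n_failed_series

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def error(self, method: str, rate: float, mode: str) -> float:
        t = self.table
        row = t[(t["method"] == method) & (t["rate"] == rate) & (t["mode"] == mode)]
        return float(row["mean_relative_error"].iloc[0])


def benchmark_imputation(
    panel: PanelData,
    methods=("ewma", "linear"),
    rates=(0.02, 0.05, 0.10, 0.20),
    modes=("single", "batch4"),
    seed: int | None = None,
    k: int = 4,
    min_observed: int = DEFAULT_MIN_OBSERVED,
) -> ImputationReport:
    """Injection benchmark on a fully observed panel.

    For every (method, rate, mode) combination, missing values are injected
    with :func:`inject_missingness`, re-imputed, and scored by the mean over
    injected cells of ``|imputed - true| / |true|``.  Cells whose true value
    is zero are excluded from the mean and counted separately.  ``"oracle"``
    is accepted as a method name and returns the true values (a zero-error
    control).
    """
    if not panel.is_complete():
        raise ParameterError("benchmark requires a fully observed panel")
    # canonical column order so results do not depend on how columns arrive
    from .panel import INDEX_COLS

    panel = PanelData(
        panel.frame[INDEX_COLS + sorted(panel.conditions)], validate_nonnegative=False
    )
    truth = panel.frame[panel.conditions].to_numpy()
    rows = []
    ss = np.random.SeedSequence(seed)
    for rate in rates:
        for mode in modes:
            child = ss.spawn(1)[0]
            holed = inject_missingness(panel, rate, mode, seed=child)
            injected = holed.frame[panel.conditions].isna().to_numpy()
            for method in methods:
                n_failed = 0
                if method == "oracle":
                    imputed_vals = truth.copy()
                else:
                    fn = IMPUTERS[method]
                    kwargs = {"k": k} if method == "ewma" else {}
                    imputed_vals = holed.frame[panel.conditions].to_numpy().copy()
                    counties = holed.frame["county"].to_numpy()
                    for county in pd.unique(counties):
                        ridx = np.flatnonzero(counties == county)
                        for j in range(len(panel.conditions)):
                            col = imputed_vals[ridx, j]
                            if not np.isnan(col).any():
                                continue
                            try:
                                imputed_vals[ridx, j] = fn(
                                    col, min_observed=min_observed, **kwargs
                                )
                            except UnimputableSeriesError:
                                n_failed += 1
                                continue
                cells = injected & ~np.isnan(imputed_vals)
                true_vals = truth[cells]
                imp_vals = imputed_vals[cells]
                nonzero = true_vals != 0
                rel = np.abs(imp_vals[nonzero] - true_vals[nonzero]) / np.abs(true_vals[nonzero])
                rows.append(
                    {
                        "method": method,
                        "rate": rate,
                        "mode": mode,
                        "mean_relative_error": float(rel.mean()) if len(rel) else np.nan,
                        "n_cells": int(nonzero.sum()),
                        "n_zero_true_cells": int((~nonzero).sum()),
                        "n_failed_series": n_failed,
                    }
                )
    return ImputationReport(pd.DataFrame(rows))
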