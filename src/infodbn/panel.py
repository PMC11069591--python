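"""Spatio-temporal panel container and CSV interchange.

A panel holds weekly, nonnegative search-query frequencies for a set of
health conditions, observed in counties nested within states.  The tidy
layout is one row per (state, county, week) with one column per condition;
missing cells are ``NaN``.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyResultError, PanelFormatError

INDEX_COLS = ["state", "county", "week"]


class PanelData:
    """A (state, county, week) x condition panel of nonnegative frequencies.

    Parameters
    ----------
    frame:
        Tidy data frame with columns ``state``, ``county``, ``week`` and one
        numeric column per condition.  Weeks must form a contiguous integer
        range within each county, and each county must belong to exactly one
        state.  Missing values are ``NaN``.
    validate_nonnegative:
        Check that all observed values are finite and >= 0.  Disabled for
        derived panels (e.g. residualized ones) that legitimately contain
        negative values.
    """

    def __init__(self, frame: pd.DataFrame, validate_nonnegative: bool = True):
        missing_cols = [c for c in INDEX_COLS if c not in frame.columns]
        if missing_cols:
            raise PanelFormatError(f"panel is missing index columns {missing_cols}")
        conditions = [c for c in frame.columns if c not in INDEX_COLS]
        if not conditions:
            raise EmptyResultError("panel has no condition columns")
        frame = frame.copy()
        try:
            frame["week"] = frame["week"].astype(np.int64)
        except (TypeError, ValueError) as exc:
            bad = frame.loc[pd.to_numeric(frame["week"], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise PanelFormatError(f"non-integer week value at row {row}") from exc
        for c in conditions:
            try:
                frame[c] = frame[c].astype(float)
            except (TypeError, ValueError) as exc:
                raise PanelFormatError(f"non-numeric frequency in column {c!r}") from exc
        frame = frame.sort_values(INDEX_COLS, kind="mergesort").reset_index(drop=True)
        self.frame = frame
        self.conditions = conditions
        self._validate(validate_nonnegative)

    # -- validation --------------------------------------------------------

    def _validate(self, nonnegative: bool) -> None:
        f = self.frame
        states_per_county = f.groupby("county")["state"].nunique()
        bad = states_per_county[states_per_county > 1]
        if len(bad):
            raise PanelFormatError(
                f"county {bad.index[0]!r} appears in {bad.iloc[0]} states; "
                "counties must be nested in exactly one state"
            )
        for county, weeks in f.groupby("county")["week"]:
            w = weeks.to_numpy()
            if len(np.unique(w)) != len(w):
                raise PanelFormatError(f"duplicate week in county {county!r}")
            if w.min() != w[0] or not np.array_equal(np.sort(w), np.arange(w.min(), w.min() + len(w))):
                raise PanelFormatError(
                    f"weeks of county {county!r} are not a contiguous integer range"
                )
        if nonnegative:
            vals = f[self.conditions].to_numpy()
            observed = ~np.isnan(vals)
            if not np.all(np.isfinite(vals[observed])):
                raise PanelFormatError("panel contains non-finite observed values")
            if np.any(vals[observed] < 0):
                raise PanelFormatError("panel contains negative frequencies")

    # -- basic accessors ---------------------------------------------------

    @property
    def states(self) -> list:
        return sorted(self.frame["state"].unique().tolist())

    @property
    def counties(self) -> list:
        return sorted(self.frame["county"].unique().tolist())

    @property
    def n_weeks(self) -> int:
        return int(self.frame["week"].nunique())

    @property
    def values(self) -> np.ndarray:
        """(rows x conditions) value matrix in frame order, NaN = missing."""
        return self.frame[self.conditions].to_numpy()

    def mask(self) -> pd.DataFrame:
        """Boolean observed-mask, aligned with ``frame`` rows."""
        return self.frame[self.conditions].notna()

    def missing_fraction(self) -> pd.Series:
        """Per-condition fraction of missing cells."""
        return self.frame[self.conditions].isna().mean()

    def is_complete(self) -> bool:
        return not self.frame[self.conditions].isna().to_numpy().any()

    def copy(self) -> "PanelData":
        return PanelData(self.frame.copy(), validate_nonnegative=False)

    def with_values(self, values: np.ndarray, validate_nonnegative: bool = False) -> "PanelData":
        """Return a panel with the same index but new condition values."""
        frame = self.frame.copy()
        frame[self.conditions] = values
        return PanelData(frame, validate_nonnegative=validate_nonnegative)

    def select_conditions(self, names: Sequence[str]) -> "PanelData":
        keep = [c for c in self.conditions if c in set(names)]
        if not keep:
            raise EmptyResultError("no conditions left after selection")
        return PanelData(self.frame[INDEX_COLS + keep], validate_nonnegative=False)

    def drop_incomplete_counties(self) -> "PanelData":
        """Drop every county that still has a missing cell (any condition)."""
        f = self.frame
        bad = f.loc[f[self.conditions].isna().any(axis=1), "county"].unique()
        out = f[~f["county"].isin(bad)]
        if out.empty:
            raise EmptyResultError("all counties contain missing cells")
        return PanelData(out, validate_nonnegative=False)

    # -- I/O ----------------------------------------------------------------

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, validate_nonnegative: bool = True) -> "PanelData":
        frame = pd.read_csv(path)
        if "week" in frame.columns and frame["week"].dtype == object:
            # accept ISO dates and convert to 0-based contiguous week indices
            try:
                dates = pd.to_datetime(frame["week"], format="%Y-%m-%d")
            except (TypeError, ValueError):
                pass
            else:
                origin = dates.min()
                frame["week"] = ((dates - origin).dt.days // 7).astype(np.int64)
        return cls(frame, validate_nonnegative=validate_nonnegative)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"PanelData({len(self.states)} states, {len(self.counties)} counties, "
            f"{self.n_weeks} weeks, {len(self.conditions)} conditions)"
        )
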