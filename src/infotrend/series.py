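"""Core containers for monthly time series and environmental panels.

A :class:`MonthlySeries` holds one variable observed on a strictly
consecutive monthly grid for one geography — the atom every pipeline stage
consumes.  An :class:`EnvPanel` bundles the environmental parameters of one
geography on a shared grid, together with missing-data bookkeeping and
per-series exclusion flags.

The numeric time axis used throughout the package maps a calendar month to
fractional years, placing each month at its midpoint::

    t = year + (month - 0.5) / 12

so a rate expressed on this axis is "per year" and dividing by 12 converts
it to "per month" literally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["MonthlySeries", "EnvPanel", "month_axis_years"]


def month_axis_years(dates: pd.PeriodIndex) -> np.ndarray:
    """Numeric-year time axis: each month sits at its midpoint in years."""
    return np.asarray(dates.year + (dates.month - 0.5) / 12.0, dtype=float)


@dataclass(frozen=True)
class MonthlySeries:
    """One variable on a consecutive monthly grid.

    Parameters
    ----------
    dates
        Monthly :class:`pandas.PeriodIndex`, strictly increasing with a
        one-month step and no duplicates.
    values
        Float array aligned with ``dates``; ``NaN`` marks a missing month.
    label
        Variable name (e.g. ``"RSV"`` or a pollutant code).
    geography
        Region the series belongs to.
    """

    dates: pd.PeriodIndex
    values: np.ndarray
    label: str = ""
    geography: str = ""

    def __post_init__(self) -> None:
        dates = pd.PeriodIndex(self.dates, freq="M")
        values = np.asarray(self.values, dtype=float)
        if dates.ndim != 1 or len(dates) < 2:
            raise ValueError("a MonthlySeries needs at least 2 months")
        if len(dates) != len(values):
            raise ValueError("dates and values must have equal length")
        step = np.diff(dates.asi8)
        if not np.all(step == 1):
            bad = dates[1:][step != 1]
            raise ValueError(
                "dates must be strictly consecutive months; "
                f"gap or duplicate before {list(bad.astype(str))}"
            )
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "values", values)

    # -- basic views -------------------------------------------------------

    def __len__(self) -> int:
        return len(self.values)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    @property
    def is_complete(self) -> bool:
        return self.n_missing == 0

    @property
    def time_years(self) -> np.ndarray:
        return month_axis_years(self.dates)

    def require_complete(self, context: str = "") -> None:
        if not self.is_complete:
            where = self.dates[self.missing_mask].astype(str).tolist()
            label = self.label or "series"
            msg = f"{label} has missing values at {where}"
            if context:
                msg = f"{context}: {msg}"
            raise ValueError(msg)

    def with_values(self, values: np.ndarray) -> "MonthlySeries":
        return replace(self, values=np.asarray(values, dtype=float))

    def to_pandas(self) -> pd.Series:
        return pd.Series(self.values, index=self.dates, name=self.label)


@dataclass
class EnvPanel:
    """Environmental parameters of one geography on a shared monthly grid.

    ``excluded`` maps a parameter name to a machine-readable reason
    (``"edge-missing"``, ``"excessive-missingness"``, ``"zero-variance"``);
    excluded series are kept for inspection but skipped downstream.
    """

    geography: str
    series: list[MonthlySeries] = field(default_factory=list)
    excluded: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.series:
            grid = self.series[0].dates
            for s in self.series[1:]:
                if not s.dates.equals(grid):
                    raise ValueError(
                        f"panel series {s.label!r} is not on the shared date grid"
                    )

    def __len__(self) -> int:
        return len(self.series)

    @property
    def dates(self) -> pd.PeriodIndex:
        if not self.series:
            raise ValueError("empty panel has no date grid")
        return self.series[0].dates

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.series]

    def active_series(self) -> list[MonthlySeries]:
        """Series not flagged excluded, in panel order."""
        return [s for s in self.series if s.label not in self.excluded]

    def get(self, label: str) -> MonthlySeries:
        for s in self.series:
            if s.label == label:
                return s
        raise KeyError(f"no series {label!r} in panel for {self.geography!r}")

    def exclude(self, label: str, reason: str) -> None:
        self.get(label)  # raises if absent
        self.excluded[label] = reason
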