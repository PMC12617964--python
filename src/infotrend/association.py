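"""Preprocessing and Spearman correlation screen of environmental panels.

Environmental series first undergo linear interpolation of interior missing
runs; a series missing its first or last month, or more than a configurable
fraction of cells, is excluded (with a machine-readable reason) rather than
extrapolated.  Both the search-interest series and each environmental series
are then z-standardized — a no-op for rank correlation, retained because the
pipeline's standardized series also feed the time-warping stage — and each
parameter is screened against search interest with the Spearman rank
correlation.  Two significance tiers are reported (p < .05 and p < .001);
no multiplicity adjustment is applied, but the number of tests performed is
recorded so readers can apply their own.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .series import MonthlySeries, EnvPanel

__all__ = [
    "CorrelationRecord",
    "interpolate_missing",
    "standardize",
    "spearman",
    "preprocess_panel",
    "correlate_panel",
    "EdgeMissingError",
]

#: default maximum tolerated fraction of missing cells before exclusion
MAX_MISSING_FRAC = 0.3

TIER_NONE = "none"
TIER_05 = "p<.05"
TIER_001 = "p<.001"


class EdgeMissingError(ValueError):
    """Raised when a series is missing its first or last observation."""


@dataclass(frozen=True)
class CorrelationRecord:
    parameter: str
    rho: float
    p_value: float
    tier: str
    n_effective: int

    def to_dict(self) -> dict:
        return {"parameter": self.parameter, "rho": self.rho,
                "p_value": self.p_value, "tier": self.tier,
                "n": self.n_effective}


def interpolate_missing(series: MonthlySeries) -> MonthlySeries:
    """Fill interior missing runs linearly between flanking observations.

    Observed values are untouched; a complete series is returned unchanged.
    Leading or trailing missing values cannot be interpolated and raise
    :class:`EdgeMissingError` (callers flag the series excluded).
    """
    mask = series.missing_mask
    if not mask.any():
        return series
    if mask[0] or mask[-1]:
        raise EdgeMissingError(
            f"{series.label or 'series'}: first/last month missing; "
            "cannot interpolate at the edges"
        )
    idx = np.arange(len(series), dtype=float)
    filled = series.values.copy()
    filled[mask] = np.interp(idx[mask], idx[~mask], series.values[~mask])
    return series.with_values(filled)


def standardize(series: MonthlySeries) -> MonthlySeries:
    """Z-score the series (sample SD, n−1 divisor)."""
    series.require_complete("standardize")
    v = series.values
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError(f"{series.label or 'series'} is constant; "
                         "cannot standardize a zero-variance series")
    return series.with_values((v - v.mean()) / sd)


def _tier(p: float, thresholds: tuple[float, float]) -> str:
    loose, strict = thresholds
    if p < strict:
        return TIER_001
    if p < loose:
        return TIER_05
    return TIER_NONE


def spearman(x: MonthlySeries, y: MonthlySeries, *,
             thresholds: tuple[float, float] = (0.05, 0.001),
             n_permutations: int | None = None,
             seed: int = 0) -> CorrelationRecord:
    """Spearman rank correlation between two complete, aligned series.

    rho is the Pearson correlation of average ranks; the p-value uses the
    t approximation ``t = rho * sqrt((n-2)/(1-rho^2))`` with n−2 degrees of
    freedom, two-sided.  For |rho| = 1 the t statistic is unbounded and the
    p-value is reported at the smallest positive float rather than 0.
    ``n_permutations`` switches to a Monte-Carlo permutation p-value.
    """
    x.require_complete("spearman")
    y.require_complete("spearman")
    n = len(x)
    if len(y) != n:
        raise ValueError("series lengths differ")
    if n < 5:
        raise ValueError("need at least 5 paired months for the screen")
    rx, ry = stats.rankdata(x.values), stats.rankdata(y.values)
    # perfect concordance/discordance is exact, not a rounded 0.999...
    if np.array_equal(rx, ry):
        rho = 1.0
    elif np.array_equal(rx + ry, np.full(n, n + 1.0)):
        rho = -1.0
    else:
        rho = float(np.corrcoef(rx, ry)[0, 1])

    if n_permutations:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            r = float(np.corrcoef(rng.permutation(rx), ry)[0, 1])
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        p = (1 + count) / (n_permutations + 1)
    elif abs(rho) >= 1.0:
        p = float(np.finfo(float).tiny)
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return CorrelationRecord(parameter=y.label, rho=rho, p_value=p,
                             tier=_tier(p, thresholds), n_effective=n)


def preprocess_panel(panel: EnvPanel,
                     max_missing_frac: float = MAX_MISSING_FRAC) -> EnvPanel:
    """Interpolate interior gaps and flag non-analyzable series.

    A series is excluded when its first or last month is missing
    (``edge-missing``), when more than ``max_missing_frac`` of its cells
    are missing (``excessive-missingness``), or when it is constant after
    interpolation (``zero-variance``).
    """
    out = EnvPanel(geography=panel.geography, series=[],
                   excluded=dict(panel.excluded))
    for s in panel.series:
        if s.label in out.excluded:
            out.series.append(s)
            continue
        if s.n_missing / len(s) > max_missing_frac:
            out.excluded[s.label] = "excessive-missingness"
            out.series.append(s)
            continue
        try:
            filled = interpolate_missing(s)
        except EdgeMissingError:
            out.excluded[s.label] = "edge-missing"
            out.series.append(s)
            continue
        if np.all(filled.values == filled.values[0]):
            out.excluded[s.label] = "zero-variance"
            out.series.append(filled)
            continue
        out.series.append(filled)
    return out


def correlate_panel(rsv: MonthlySeries, panel: EnvPanel, *,
                    thresholds: tuple[float, float] = (0.05, 0.001),
                    ) -> list[CorrelationRecord]:
    """Screen every non-excluded parameter against search interest.

    The panel must already be preprocessed (interpolated, exclusions
    applied); records come back in panel order, one per active parameter.
    """
    active = panel.active_series()
    if not active:
        raise ValueError(f"panel for {panel.geography!r} has no analyzable series")
    rsv_z = standardize(rsv)
    records = []
    for s in active:
        records.append(spearman(rsv_z, standardize(s), thresholds=thresholds))
    return records
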