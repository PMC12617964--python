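"""Month-of-year seasonality testing with the Kruskal-Wallis test.

Monthly values are grouped by calendar month and compared with the
tie-corrected Kruskal-Wallis H test; the p-value comes from the chi-square
approximation with (number of months present − 1) degrees of freedom, the
standard choice at this panel size.  A Monte-Carlo permutation p-value is
available for small samples or as a check on the approximation.  Per-month
distribution summaries (n, median, quartiles, min, max) are emitted for
box-plot style reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .series import MonthlySeries

__all__ = ["SeasonalityResult", "kruskal_wallis_by_month"]

_MONTH_NAMES = ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
                "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"]


@dataclass
class SeasonalityResult:
    h_statistic: float
    dof: int
    p_value: float
    monthly_summaries: dict[str, dict] = field(default_factory=dict)
    p_permutation: float | None = None
    n_permutations: int | None = None

    def to_dict(self) -> dict:
        d = {
            "h_statistic": self.h_statistic,
            "dof": self.dof,
            "p_value": self.p_value,
            "monthly_summaries": self.monthly_summaries,
        }
        if self.p_permutation is not None:
            d["p_permutation"] = self.p_permutation
            d["n_permutations"] = self.n_permutations
        return d


def _h_from_ranks(ranks: np.ndarray, group_sizes: np.ndarray,
                  tie_correction: float) -> float:
    """Tie-corrected H given pooled ranks ordered by group blocks."""
    n = ranks.size
    sums = np.add.reduceat(ranks, np.r_[0, np.cumsum(group_sizes)[:-1]])
    h = 12.0 / (n * (n + 1)) * np.sum(sums**2 / group_sizes) - 3.0 * (n + 1)
    return h / tie_correction


def kruskal_wallis_by_month(series: MonthlySeries, *,
                            n_permutations: int | None = None,
                            seed: int = 0) -> SeasonalityResult:
    """Test for month-of-year differences in a monthly series.

    Every calendar month present must contribute at least two observations.
    When every value is tied the tie correction degenerates; H is defined
    as 0 with p = 1.  ``n_permutations`` adds a Monte-Carlo permutation
    p-value ``(1 + #{H* >= H}) / (n_permutations + 1)`` alongside the
    chi-square one.
    """
    series.require_complete("seasonality test")
    months = np.asarray(series.dates.month)
    values = series.values
    present = sorted(set(months.tolist()))
    groups = [values[months == m] for m in present]

    for m, g in zip(present, groups):
        if len(g) < 2:
            raise ValueError(
                f"calendar month {_MONTH_NAMES[m - 1]} has {len(g)} observation(s); "
                "need >= 2 per month"
            )

    summaries = {}
    for m, g in zip(present, groups):
        q1, med, q3 = np.percentile(g, [25, 50, 75])
        summaries[_MONTH_NAMES[m - 1]] = {
            "n": int(len(g)), "median": float(med),
            "q1": float(q1), "q3": float(q3),
            "min": float(g.min()), "max": float(g.max()),
        }

    dof = len(present) - 1
    if np.all(values == values[0]):
        # all ties: the correction term 1 - sum(t^3 - t)/(N^3 - N) is 0
        return SeasonalityResult(h_statistic=0.0, dof=dof, p_value=1.0,
                                 monthly_summaries=summaries)

    h, p = stats.kruskal(*groups)
    result = SeasonalityResult(h_statistic=float(h), dof=dof,
                               p_value=float(p), monthly_summaries=summaries)

    if n_permutations:
        # pooled ranks are invariant under permutation; shuffle assignment
        ranks = stats.rankdata(values)
        n = ranks.size
        ties = np.unique(values, return_counts=True)[1]
        correction = 1.0 - np.sum(ties**3 - ties) / (n**3 - n)
        sizes = np.array([len(g) for g in groups])
        rng = np.random.default_rng(seed)
        h_star = np.empty(n_permutations)
        for i in range(n_permutations):
            h_star[i] = _h_from_ranks(rng.permutation(ranks), sizes, correction)
        result.p_permutation = float(
            (1 + np.sum(h_star >= h - 1e-12)) / (n_permutations + 1)
        )
        result.n_permutations = n_permutations
    return result
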