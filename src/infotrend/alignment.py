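"""Dynamic time warping alignment of environmental series to search interest.

DTW finds the minimal-cost monotone alignment between two sequences,
absorbing lags and local tempo differences; the accumulated cost along the
optimal path (the DTW distance) measures dissimilarity.  The recurrence is
the unconstrained symmetric three-way pattern::

    D(i, j) = d(i, j) + min(D(i-1, j), D(i, j-1), D(i-1, j-1))

with local cost ``d(i, j) = |x_i - y_j|`` on standardized series (squared
cost available behind a flag), no window and no slope constraint, and no
path-length normalization by default.  The optimal path is recovered by
backtracking with a fixed tie-break (diagonal, then vertical, then
horizontal) so paths are reproducible; the distance itself is
tie-invariant.

Alignment is computed only for parameters that passed the correlation
screen, and parameters are ranked ascending by distance — the smallest
distance is the strongest temporal alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import MonthlySeries, EnvPanel
from .association import CorrelationRecord, TIER_NONE, standardize

__all__ = ["DtwRecord", "dtw_distance", "rank_alignment"]


@dataclass(frozen=True)
class DtwRecord:
    """DTW result for one parameter (path indices are 0-based)."""

    parameter: str
    dtw_distance: float
    path: tuple[tuple[int, int], ...]
    step_pattern: str = "symmetric"

    @property
    def path_length(self) -> int:
        return len(self.path)

    def to_dict(self) -> dict:
        return {"parameter": self.parameter, "distance": self.dtw_distance,
                "path_length": self.path_length,
                "step_pattern": self.step_pattern}


def dtw_distance(x, y, *, squared: bool = False,
                 normalize: bool = False, parameter: str = "") -> DtwRecord:
    """DTW distance and optimal warping path between two sequences.

    ``normalize`` divides the accumulated cost by the path length for
    cross-length comparability.  Sequences of length 1 are allowed; empty
    input is an error.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("DTW requires nonempty sequences")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("DTW requires complete sequences (no missing values)")
    n, m = x.size, y.size

    cost = np.abs(x[:, None] - y[None, :])
    if squared:
        cost = cost**2

    D = np.full((n, m), np.inf)
    D[0, 0] = cost[0, 0]
    for j in range(1, m):
        D[0, j] = D[0, j - 1] + cost[0, j]
    for i in range(1, n):
        D[i, 0] = D[i - 1, 0] + cost[i, 0]
        row_prev, row = D[i - 1], D[i]
        for j in range(1, m):
            row[j] = cost[i, j] + min(row_prev[j - 1], row_prev[j], row[j - 1])

    # backtrack: diagonal first, then vertical (i-1), then horizontal (j-1)
    path = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while (i, j) != (0, 0):
        if i > 0 and j > 0:
            moves = ((D[i - 1, j - 1], (i - 1, j - 1)),
                     (D[i - 1, j], (i - 1, j)),
                     (D[i, j - 1], (i, j - 1)))
            best = min(mv[0] for mv in moves)
            for val, nxt in moves:
                if val == best:
                    i, j = nxt
                    break
        elif i > 0:
            i -= 1
        else:
            j -= 1
        path.append((i, j))
    path.reverse()

    dist = float(D[n - 1, m - 1])
    if normalize:
        dist /= len(path)
    pattern = "symmetric" + ("-squared" if squared else "") + \
              ("-normalized" if normalize else "")
    return DtwRecord(parameter=parameter, dtw_distance=dist,
                     path=tuple(path), step_pattern=pattern)


def rank_alignment(rsv: MonthlySeries, panel: EnvPanel,
                   screen: list[CorrelationRecord], *,
                   squared: bool = False,
                   normalize: bool = False) -> list[DtwRecord]:
    """Rank screened parameters by DTW distance to standardized search interest.

    Only parameters with a significance tier in the Spearman screen are
    aligned; both series are z-standardized before warping.  Records come
    back sorted ascending by distance (ties broken by parameter name, so
    the ranking does not depend on panel order).  With no significant
    parameter the ranking is empty — an informative outcome, not an error.
    """
    significant = [r.parameter for r in screen if r.tier != TIER_NONE]
    rsv_z = standardize(rsv).values
    records = []
    for name in significant:
        env_z = standardize(panel.get(name)).values
        records.append(dtw_distance(rsv_z, env_z, squared=squared,
                                    normalize=normalize, parameter=name))
    records.sort(key=lambda r: (r.dtw_distance, r.parameter))
    return records
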