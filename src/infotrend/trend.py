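"""Spline trend estimation with the mean-instantaneous-derivative statistic.

The trend model is ordinary least squares of the monthly series on an
intercept plus a cubic B-spline basis of the numeric-year time variable
(default 4 spline columns, one interior knot at the median observation
time — the dominant statistical-computing convention for a "df = 4" spline
basis, in which the df counts spline columns and the intercept is a
separate model term).

The trend statistic is the mean instantaneous derivative (MID): the fitted
spline's analytic first derivative is evaluated at every observed month on
the numeric-year axis (units per year), averaged, and divided by 12 to give
an average change per month.  A positive MID is an overall rising trend.
Uncertainty comes from a residual bootstrap: residuals are resampled with
replacement, added back to the fitted values, and the model refitted; the
95% CI is the 2.5/97.5 percentile interval of the bootstrap MIDs and the
two-sided p-value is ``2 * min(P(MID* <= 0), P(MID* >= 0))`` floored at
``2 / (n_boot + 1)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

from .series import MonthlySeries

__all__ = [
    "SplineBasis",
    "SplineFit",
    "TrendEstimate",
    "build_basis",
    "fit_trend",
    "instantaneous_derivatives",
    "compute_mid",
    "bootstrap_mid",
    "falsification_contrast",
]

logger = logging.getLogger(__name__)

DEFAULT_DF = 4
DEFAULT_DEGREE = 3


@dataclass(frozen=True)
class SplineBasis:
    """B-spline basis specification on the numeric-year axis.

    ``df`` counts the spline columns; the constant function is carried by a
    separate intercept, so the full (intercept-augmented) space has
    ``df + 1`` B-spline columns of which the first is dropped.
    """

    knots: np.ndarray          # full knot vector, boundary knots repeated
    degree: int
    df: int

    @property
    def boundary(self) -> tuple[float, float]:
        return float(self.knots[self.degree]), float(self.knots[-self.degree - 1])

    def _check_domain(self, t: np.ndarray) -> None:
        lo, hi = self.boundary
        t = np.asarray(t, dtype=float)
        if np.any(t < lo) or np.any(t > hi):
            raise ValueError(
                f"evaluation outside boundary knots [{lo:.6g}, {hi:.6g}]"
            )

    def full_design(self, t: np.ndarray) -> np.ndarray:
        """All ``df + 1`` basis columns (rows sum to 1: partition of unity)."""
        self._check_domain(t)
        return BSpline.design_matrix(
            np.asarray(t, dtype=float), self.knots, self.degree
        ).toarray()

    def design(self, t: np.ndarray) -> np.ndarray:
        """The ``df`` model columns (constant column dropped)."""
        return self.full_design(t)[:, 1:]

    def derivative_design(self, t: np.ndarray) -> np.ndarray:
        """First derivative of each model column at ``t`` (per year)."""
        self._check_domain(t)
        t = np.asarray(t, dtype=float)
        n_full = len(self.knots) - self.degree - 1
        cols = []
        for j in range(1, n_full):
            e = np.zeros(n_full)
            e[j] = 1.0
            cols.append(BSpline(self.knots, e, self.degree).derivative()(t))
        return np.column_stack(cols)


def build_basis(dates, df: int = DEFAULT_DF,
                degree: int = DEFAULT_DEGREE) -> SplineBasis:
    """Construct the B-spline basis for a monthly date grid.

    Interior knots (``df - degree`` of them) sit at quantiles of the
    observation times; boundary knots at the first and last month.
    """
    series_like = dates if isinstance(dates, MonthlySeries) else None
    if series_like is not None:
        t = series_like.time_years
    else:
        from .series import month_axis_years
        import pandas as pd

        t = month_axis_years(pd.PeriodIndex(dates, freq="M"))
    if df < degree:
        raise ValueError(f"df={df} must be >= degree={degree}")
    if len(t) <= df + 1:
        raise ValueError(
            f"need more than df + 1 = {df + 1} months to fit a df={df} spline; "
            f"got {len(t)}"
        )
    n_interior = df - degree
    if n_interior:
        probs = np.arange(1, n_interior + 1) / (n_interior + 1)
        interior = np.quantile(t, probs)
    else:
        interior = np.empty(0)
    knots = np.r_[[t[0]] * (degree + 1), interior, [t[-1]] * (degree + 1)]
    return SplineBasis(knots=knots, degree=degree, df=df)


@dataclass
class SplineFit:
    """OLS fit of a series on intercept + spline basis."""

    basis: SplineBasis
    series: MonthlySeries
    coef: np.ndarray               # intercept first, then df spline columns
    fitted: np.ndarray
    residuals: np.ndarray
    r_squared: float               # NaN when undefined
    adj_r_squared: float           # NaN when undefined
    r2_defined: bool

    @property
    def time_years(self) -> np.ndarray:
        return self.series.time_years

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self.coef[0] + self.basis.design(t) @ self.coef[1:]


def fit_trend(series: MonthlySeries, df: int = DEFAULT_DF,
              degree: int = DEFAULT_DEGREE) -> SplineFit:
    """Fit the spline trend model by ordinary least squares.

    The series must be complete (the trend stage runs on complete RSV
    series).  Adjusted R² uses ``1 - (1 - R²)(n - 1)/(n - p - 1)`` with
    ``p`` the number of spline columns; a zero-variance response leaves R²
    flagged undefined instead of propagating NaN silently.
    """
    series.require_complete("trend fit")
    basis = build_basis(series.dates, df=df, degree=degree)
    t = series.time_years
    X = np.column_stack([np.ones(len(t)), basis.design(t)])
    y = series.values
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    resid = y - fitted
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss > 0:
        r2 = 1.0 - float(resid @ resid) / tss
        n, p = len(y), df
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
        defined = True
    else:
        r2 = adj = float("nan")
        defined = False
    return SplineFit(basis=basis, series=series, coef=coef, fitted=fitted,
                     residuals=resid, r_squared=r2, adj_r_squared=adj,
                     r2_defined=defined)


def instantaneous_derivatives(fit: SplineFit) -> np.ndarray:
    """Analytic first derivative of the fitted spline at each month (per year)."""
    D = fit.basis.derivative_design(fit.time_years)
    return D @ fit.coef[1:]


def compute_mid(fit: SplineFit) -> float:
    """Mean instantaneous derivative: mean per-year rate divided by 12."""
    return float(instantaneous_derivatives(fit).mean() / 12.0)


@dataclass
class TrendEstimate:
    """MID with residual-bootstrap CI and p-value."""

    mid: float                     # RSV units per month
    derivatives: np.ndarray        # per-month rates, RSV units per year
    ci_low: float
    ci_high: float
    p_value: float
    n_boot: int
    seed: int
    df: int
    degree: int
    adj_r_squared: float
    r2_defined: bool
    label: str = ""
    geography: str = ""
    boot_mids: np.ndarray | None = field(default=None, repr=False)

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "geography": self.geography,
            "mid": self.mid,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "df": self.df,
            "degree": self.degree,
            "adj_r_squared": None if not self.r2_defined else self.adj_r_squared,
            "derivatives_per_year": [float(v) for v in self.derivatives],
        }


def bootstrap_mid(series: MonthlySeries, df: int = DEFAULT_DF,
                  n_boot: int = 1000, seed: int = 0, *,
                  degree: int = DEFAULT_DEGREE,
                  leverage_adjust: bool = False) -> TrendEstimate:
    """Residual-bootstrap inference for the MID.

    Each iteration resamples residuals with replacement, adds them to the
    fitted values, refits the spline model and recomputes the MID.  With
    ``leverage_adjust`` residuals are first scaled by ``1/sqrt(1 - h_ii)``
    (default off: raw residuals).
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if n_boot < 100:
        logger.warning("n_boot=%d is small; CIs and p-values will be coarse",
                       n_boot)
    fit = fit_trend(series, df=df, degree=degree)
    deriv = instantaneous_derivatives(fit)
    mid = float(deriv.mean() / 12.0)

    t = fit.time_years
    X = np.column_stack([np.ones(len(t)), fit.basis.design(t)])
    pinv = np.linalg.pinv(X)
    # MID is linear in the coefficients: weight vector maps coef -> MID
    D = fit.basis.derivative_design(t)
    w = np.r_[0.0, D.mean(axis=0) / 12.0]

    resid = fit.residuals
    if leverage_adjust:
        h = np.einsum("ij,ji->i", X, pinv)
        resid = resid / np.sqrt(np.clip(1.0 - h, 1e-12, None))

    rng = np.random.default_rng(seed)
    n = len(resid)
    idx = rng.integers(0, n, size=(n_boot, n))
    y_star = fit.fitted + resid[idx]            # (n_boot, n)
    boot_coef = y_star @ pinv.T                 # refit: (n_boot, p+1)
    boot_mids = boot_coef @ w

    ci_low, ci_high = np.percentile(boot_mids, [2.5, 97.5])
    p_lo = float(np.mean(boot_mids <= 0.0))
    p_hi = float(np.mean(boot_mids >= 0.0))
    floor = 2.0 / (n_boot + 1)
    p = min(1.0, max(2.0 * min(p_lo, p_hi), floor))

    return TrendEstimate(
        mid=mid, derivatives=deriv, ci_low=float(ci_low), ci_high=float(ci_high),
        p_value=p, n_boot=n_boot, seed=seed, df=df, degree=degree,
        adj_r_squared=fit.adj_r_squared, r2_defined=fit.r2_defined,
        label=series.label, geography=series.geography, boot_mids=boot_mids,
    )


def falsification_contrast(target: TrendEstimate, control: TrendEstimate,
                           alpha: float = 0.05) -> dict:
    """Juxtapose the target trend with a falsification-control trend.

    The control is a series expected to show no trend; a significant trend
    there signals confounding.  No new statistic is computed — the verdict
    is a structured reading of the two p-values at ``alpha``.
    """
    if (target.df, target.degree) != (control.df, control.degree):
        raise ValueError("contrast invalid: spline settings differ")
    if target.n_boot != control.n_boot:
        raise ValueError("contrast invalid: bootstrap iteration counts differ")
    t_sig, c_sig = target.significant(alpha), control.significant(alpha)
    if t_sig and not c_sig:
        verdict = "trend specific to target"
    elif not t_sig and not c_sig:
        verdict = "no specific trend"
    elif t_sig and c_sig:
        verdict = "nonspecific rise; confounding not excluded"
    else:
        verdict = "control trend only; target shows no trend"
    return {
        "verdict": verdict,
        "alpha": alpha,
        "target": {"label": target.label, "mid": target.mid,
                   "p_value": target.p_value, "significant": t_sig},
        "control": {"label": control.label, "mid": control.mid,
                    "p_value": control.p_value, "significant": c_sig},
    }
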