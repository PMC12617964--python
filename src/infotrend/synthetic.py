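"""Synthetic monthly panels with known ground truth.

Generates search-interest-like series (0–100 "relative search volume",
RSV) and environmental-parameter-like panels whose trend, seasonality,
association strength, lead/lag and missingness are all controlled, so every
downstream stage — spline trend, seasonality test, correlation screen,
time-warping alignment — can be validated against an analytic truth without
any external data.

Model
-----
The noiseless RSV signal is ``trend(t) + seasonal(month)``:

* ``trend_kind="none"``    — constant at ``base_level``.
* ``trend_kind="linear"``  — straight line rising ``trend_total_rise`` units
  over the window, so consecutive months differ by exactly
  ``trend_total_rise / (n_months - 1)``.
* ``trend_kind="smooth_rise"`` — logistic ramp in time (steepness
  ``logistic_steepness``), rescaled to span exactly ``trend_total_rise``;
  its derivative is nonzero and time-varying, which exercises the spline's
  curvature.

Gaussian noise (``noise_sd``) is added and the result clipped to [0, 100],
mirroring the 0–100 normalisation of relative search volume.  The recorded
``true_mid`` — mean instantaneous derivative, in RSV units per month — is
computed analytically from the noiseless *trend* component before clipping
(the seasonal component averages to zero over whole cycles).

Linked environmental series are built from the standardized noiseless RSV
signal shifted so the environmental series *leads* RSV by ``link_lag``
months, mixed with independent noise so that ``link_strength`` is the
fraction of variance carried by the shared signal::

    x = sign * sqrt(link_strength) * z_signal + sqrt(1 - link_strength) * eps

Null series are pure independent noise.  Each series draws from its own RNG
stream keyed by ``(seed, series index)``, so adding a series never perturbs
earlier ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .series import MonthlySeries, EnvPanel

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate_rsv", "generate_env_panel"]

_TREND_KINDS = ("none", "linear", "smooth_rise")

#: affine display transform applied to z-scored environmental series; the
#: rank-based downstream stages are invariant to it, it only makes CSVs look
#: like measured data rather than z-scores.
_ENV_LOC, _ENV_SCALE = 50.0, 10.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults emulate the study window.

    68 months starting 2018-12, a smooth nonlinear rise of ~30 RSV units
    (a mean rate of ~0.45 units/month), month-to-month noise of 8 RSV units
    (signal-to-noise giving an adjusted R² near 0.6 for the spline fit),
    a 21-parameter panel of which 4 are genuinely linked with a one-month
    lead, and sparse interior missingness.
    """

    n_months: int = 68
    start: str = "2018-12"
    trend_kind: str = "smooth_rise"
    base_level: float = 35.0
    trend_total_rise: float = 30.0
    seasonal_amplitude: float = 0.0
    noise_sd: float = 8.0
    n_env_linked: int = 4
    n_env_null: int = 17
    link_strength: float = 0.6
    link_lag: int = 1
    link_sign: int | tuple[int, ...] = 1
    missing_rate: float = 0.02
    logistic_steepness: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_months < 24:
            raise ValueError(
                "n_months must be >= 24 (two of each calendar month "
                "are needed for the seasonality test)"
            )
        if self.trend_kind not in _TREND_KINDS:
            raise ValueError(f"trend_kind must be one of {_TREND_KINDS}")
        if not 0.0 <= self.link_strength <= 1.0:
            raise ValueError("link_strength must be in [0, 1]")
        if not 0.0 <= self.missing_rate <= 0.3:
            raise ValueError("missing_rate must be in [0, 0.3]")
        if self.noise_sd < 0 or self.seasonal_amplitude < 0:
            raise ValueError("noise_sd and seasonal_amplitude must be >= 0")
        if self.n_env_linked < 0 or self.n_env_null < 0:
            raise ValueError("series counts must be >= 0")
        if abs(self.link_lag) >= self.n_months / 2:
            raise ValueError("link_lag must be < n_months / 2")
        for s in self.signs():
            if s not in (-1, 1):
                raise ValueError("link_sign entries must be +1 or -1")
        pd.Period(self.start, freq="M")  # validates the start month

    def signs(self) -> tuple[int, ...]:
        """Per-linked-series signs, broadcasting a scalar."""
        if isinstance(self.link_sign, int):
            return (self.link_sign,) * self.n_env_linked
        if len(self.link_sign) != self.n_env_linked:
            raise ValueError("link_sign tuple length must equal n_env_linked")
        return tuple(self.link_sign)

    @property
    def dates(self) -> pd.PeriodIndex:
        return pd.period_range(self.start, periods=self.n_months, freq="M")


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside a generated dataset."""

    true_mid: float
    trend_kind: str
    linked: dict[str, dict] = field(default_factory=dict)  # label -> {sign, lag}
    null_labels: list[str] = field(default_factory=list)
    masked_cells: list[tuple[str, str]] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


# -- noiseless components ---------------------------------------------------

def _trend_and_derivative(cfg: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless trend values and analytic per-month derivatives (units/month)."""
    n, r = cfg.n_months, cfg.trend_total_rise
    i = np.arange(n, dtype=float)
    if cfg.trend_kind == "none":
        return np.full(n, cfg.base_level), np.zeros(n)
    if cfg.trend_kind == "linear":
        slope = r / (n - 1)  # per month
        return cfg.base_level + slope * i, np.full(n, slope)
    # smooth_rise: logistic ramp in scaled time u = i/(n-1)
    k = cfg.logistic_steepness
    u = i / (n - 1)
    g = 1.0 / (1.0 + np.exp(-k * (u - 0.5)))
    g0, g1 = g[0], g[-1]
    values = cfg.base_level + r * (g - g0) / (g1 - g0)
    dg_du = k * g * (1.0 - g)
    deriv_per_month = r * dg_du / (g1 - g0) / (n - 1)
    return values, deriv_per_month


def _seasonal(cfg: SyntheticConfig) -> np.ndarray:
    months = np.asarray(cfg.dates.month, dtype=float)
    return cfg.seasonal_amplitude * np.sin(2.0 * np.pi * (months - 1.0) / 12.0)


def noiseless_signal(cfg: SyntheticConfig) -> np.ndarray:
    """Trend plus seasonal component, before noise and clipping."""
    return _trend_and_derivative(cfg)[0] + _seasonal(cfg)


def _rng(cfg: SyntheticConfig, stream: int) -> np.random.Generator:
    # one independent stream per series: RSV is stream 0, env series 1, 2, ...
    return np.random.default_rng([cfg.seed, stream])


# -- generators -------------------------------------------------------------

def generate_rsv(cfg: SyntheticConfig, *, label: str = "RSV",
                 geography: str = "synthetic") -> tuple[MonthlySeries, SyntheticTruth]:
    """Generate an RSV-like series and its ground truth.

    The series is clipped to [0, 100] after noise; ``true_mid`` is the
    analytic mean derivative of the pre-clip noiseless trend, in RSV units
    per month.
    """
    trend, deriv = _trend_and_derivative(cfg)
    signal = trend + _seasonal(cfg)
    noise = _rng(cfg, 0).normal(0.0, cfg.noise_sd, cfg.n_months) if cfg.noise_sd else 0.0
    values = np.clip(signal + noise, 0.0, 100.0)
    truth = SyntheticTruth(true_mid=float(deriv.mean()), trend_kind=cfg.trend_kind)
    return MonthlySeries(cfg.dates, values, label=label, geography=geography), truth


def _shift_leading(z: np.ndarray, lag: int) -> np.ndarray:
    """Shift so the output *leads* the input by ``lag`` months, edges repeated."""
    if lag == 0:
        return z
    if lag > 0:
        return np.concatenate([z[lag:], np.repeat(z[-1], lag)])
    return np.concatenate([np.repeat(z[0], -lag), z[:lag]])


def generate_env_panel(cfg: SyntheticConfig, rsv: MonthlySeries,
                       ) -> tuple[EnvPanel, SyntheticTruth]:
    """Generate an environmental panel tied to (a copy of) the RSV signal.

    Linked series are mixtures of the standardized noiseless RSV signal
    (shifted to lead RSV by ``link_lag``) and independent Gaussian noise;
    null series are pure noise.  Interior cells are masked at
    ``missing_rate``; the first and last month of every series are never
    masked, matching the interior-only interpolation downstream.
    """
    if len(rsv) != cfg.n_months:
        raise ValueError("rsv series length must equal config n_months")

    signal = noiseless_signal(cfg)
    sd = signal.std(ddof=1)
    z = (signal - signal.mean()) / sd if sd > 0 else np.zeros_like(signal)

    truth = SyntheticTruth(true_mid=0.0, trend_kind=cfg.trend_kind)
    series: list[MonthlySeries] = []
    signs = cfg.signs()
    a, b = np.sqrt(cfg.link_strength), np.sqrt(1.0 - cfg.link_strength)

    for j in range(cfg.n_env_linked + cfg.n_env_null):
        rng = _rng(cfg, j + 1)
        if j < cfg.n_env_linked:
            label = f"env_linked_{j + 1}"
            eps = rng.normal(0.0, 1.0, cfg.n_months)
            x = signs[j] * a * _shift_leading(z, cfg.link_lag) + b * eps
            truth.linked[label] = {"sign": signs[j], "lag": cfg.link_lag}
        else:
            label = f"env_null_{j - cfg.n_env_linked + 1}"
            x = rng.normal(0.0, 1.0, cfg.n_months)
            truth.null_labels.append(label)
        values = _ENV_LOC + _ENV_SCALE * x
        if cfg.missing_rate > 0:
            interior = rng.random(cfg.n_months) < cfg.missing_rate
            interior[0] = interior[-1] = False
            values = values.copy()
            values[interior] = np.nan
            truth.masked_cells.extend(
                (label, str(d)) for d in cfg.dates[interior]
            )
        series.append(MonthlySeries(cfg.dates, values, label=label,
                                    geography=rsv.geography))

    return EnvPanel(geography=rsv.geography, series=series), truth
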