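"""Synthetic (quasi-)Poisson time series with known design parameters.

The generators here produce the controlled data on which the closed-form
SE approximators are checked.  One series follows the log-linear model

    E(Y_i) = exp(log(baseline_rate) + beta_true * x_i + coupling * s_i)

where ``s_i = cos(2π·day/365.25 + phase)`` is an annual seasonal signal
shared between the exposure and the outcome: the exposure is
``amplitude·s_i`` plus white noise, and ``coupling`` scales the direct
seasonal effect on the outcome.  A seasonal time spline in the fitted
model absorbs ``s_i``, so the exposure variation usable for estimating
``beta`` is (in expectation) just the white-noise SD, with
R²_x|z = (amplitude²/2) / (amplitude²/2 + noise_sd²) under covariate
adjustment.  Defaults give R²_x|z ≈ 0.4, typical of a strongly seasonal
exposure such as summer heat.

Overdispersion: for ``dispersion > 1`` counts are drawn negative
binomial with per-observation size ``mu_i/(phi − 1)``, which has mean
``mu_i`` and variance exactly ``phi·mu_i`` — the first two moments a
quasi-Poisson model describes; ``dispersion == 1`` draws Poisson.

Seed protocol: every generator takes its randomness from
``numpy.random.default_rng([master_seed, *indices])`` where the indices
identify the series and replicate, so scenario grids are reproducible
and distinct series never share a stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exposure import DAYS_PER_YEAR, CovariateSpec, dow_indicators, time_spline_basis
from .meta import SeriesEstimate

__all__ = [
    "ExposureModel",
    "SimulationConfig",
    "SimulatedSeries",
    "MultiCityConfig",
    "FitResult",
    "simulate_exposure",
    "simulate_counts",
    "simulate_series",
    "fit_series",
    "empirical_se",
    "simulate_multicity",
]


@dataclass(frozen=True)
class ExposureModel:
    """Seasonal-plus-noise exposure: amplitude·cos(2π·day/period + phase) + ε.

    With daily data and an annual period, SD(x) ≈ sqrt(amplitude²/2 +
    noise_sd²) and SD(x|z) ≈ noise_sd once a seasonal spline is in the
    design.
    """

    amplitude: float = 1.155  # amplitude²/2 ≈ 0.667 → R²_x|z ≈ 0.4 at noise_sd 1
    period: float = DAYS_PER_YEAR
    noise_sd: float = 1.0
    phase: float = 0.0


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic daily count series."""

    n_days: int = 1460
    baseline_rate: float = 20.0  # expected events/day, exp(alpha) scale
    beta_true: float = 0.02  # log-RR per exposure unit
    dispersion: float = 1.0
    exposure_model: ExposureModel = field(default_factory=ExposureModel)
    confounder_coupling: float = 0.1  # seasonal log-rate amplitude in the outcome
    start_date: str = "2009-01-01"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 30:
            raise ValueError("n_days must be at least 30")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if self.dispersion < 1:
            raise ValueError("dispersion must be at least 1 for simulation")


@dataclass(frozen=True)
class SimulatedSeries:
    """One synthetic series with the parameters that generated it."""

    dates: pd.DatetimeIndex
    exposure: np.ndarray
    counts: np.ndarray
    beta_true: float
    dispersion: float
    baseline_rate: float


@dataclass(frozen=True)
class MultiCityConfig:
    """Ensemble of series with true coefficients drawn around a common mean.

    Per-series true coefficients are beta_j ~ Normal(template.beta_true,
    tau²); ``rate_overrides`` optionally varies baseline rates across
    series (city size).
    """

    n_series: int
    tau: float = 0.0
    template: SimulationConfig = field(default_factory=SimulationConfig)
    rate_overrides: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be nonnegative")
        if self.tau > 0 and self.n_series < 2:
            raise ValueError("heterogeneity (tau > 0) needs at least 2 series")
        if self.n_series < 1:
            raise ValueError("n_series must be at least 1")
        if self.rate_overrides is not None and len(self.rate_overrides) != self.n_series:
            raise ValueError("rate_overrides length must equal n_series")


@dataclass(frozen=True)
class FitResult:
    """First-stage quasi-Poisson fit summary for one series."""

    estimate: SeriesEstimate
    dispersion_hat: float
    n_obs: int
    total_events: int


def _rng(seed: int, *indices: int) -> np.random.Generator:
    return np.random.default_rng([seed, *indices])


def _seasonal(config: SimulationConfig) -> np.ndarray:
    day = np.arange(config.n_days, dtype=float)
    em = config.exposure_model
    return np.cos(2.0 * math.pi * day / em.period + em.phase)


def simulate_exposure(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw the seasonal-plus-noise exposure series for a config."""
    rng = rng if rng is not None else _rng(config.seed, 0)
    em = config.exposure_model
    return em.amplitude * _seasonal(config) + rng.normal(
        0.0, em.noise_sd, size=config.n_days
    )


def simulate_counts(
    exposure: np.ndarray,
    dates: pd.DatetimeIndex,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SimulatedSeries:
    """Draw daily counts from the log-linear model given an exposure path."""
    rng = rng if rng is not None else _rng(config.seed, 1)
    exposure = np.asarray(exposure, dtype=float)
    lp = (
        math.log(config.baseline_rate)
        + config.beta_true * exposure
        + config.confounder_coupling * _seasonal(config)
    )
    if np.max(lp) > 30:
        raise OverflowError(
            "linear predictor exceeds exp(30); reduce baseline_rate or beta_true"
        )
    mu = np.exp(lp)
    phi = config.dispersion
    if phi == 1.0:
        counts = rng.poisson(mu)
    else:
        # NB with size r = mu/(phi-1), p = 1/phi: mean mu, variance phi*mu
        r = mu / (phi - 1.0)
        counts = rng.negative_binomial(r, 1.0 / phi)
    return SimulatedSeries(
        dates=pd.DatetimeIndex(dates),
        exposure=exposure,
        counts=counts.astype(np.int64),
        beta_true=config.beta_true,
        dispersion=phi,
        baseline_rate=config.baseline_rate,
    )


def simulate_series(
    config: SimulationConfig, *indices: int
) -> SimulatedSeries:
    """Exposure + counts for one config; extra indices split the seed stream."""
    dates = pd.date_range(config.start_date, periods=config.n_days, freq="D")
    rng = _rng(config.seed, *indices)
    x = simulate_exposure(config, rng=rng)
    return simulate_counts(x, dates, config, rng=rng)


def fit_series(
    series: SimulatedSeries, spec: CovariateSpec | None = None
) -> FitResult:
    """Fit the first-stage log-link count regression to one series.

    Design is [intercept | exposure | time spline | day-of-week] per the
    covariate spec.  The returned SE is the model-based SE scaled by the
    Pearson dispersion estimate φ̂ = Σ(Pearson residuals²)/(n − p), i.e.
    a quasi-Poisson fit.
    """
    spec = spec or CovariateSpec()
    x = series.exposure
    if np.allclose(x, x[0]):
        raise ValueError("degenerate design: exposure has no variation")
    if not np.any(series.counts > 0):
        raise ValueError("cannot fit: all counts are zero")
    cols = [np.ones_like(x), x]
    if spec.spline_df_per_year > 0:
        spline = time_spline_basis(series.dates, spec.spline_df_per_year)
        if spline.shape[1] > 1 or not np.allclose(spline, 1.0):
            cols.append(spline)
    if spec.include_dow:
        cols.append(dow_indicators(series.dates))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient regression design")
    model = sm.GLM(series.counts, X, family=sm.families.Poisson())
    try:
        res = model.fit(scale="X2")
    except Exception as exc:  # pragma: no cover - statsmodels raises rarely
        raise RuntimeError(f"count regression failed to converge: {exc}") from exc
    if not res.converged:
        raise RuntimeError(
            f"count regression did not converge in {res.fit_history['iteration']} iterations"
        )
    return FitResult(
        estimate=SeriesEstimate(beta_hat=float(res.params[1]), se=float(res.bse[1])),
        dispersion_hat=float(res.scale),
        n_obs=len(series.counts),
        total_events=int(series.counts.sum()),
    )


def empirical_se(
    config: SimulationConfig,
    spec: CovariateSpec | None = None,
    n_reps: int = 200,
) -> float:
    """Monte-Carlo SE of beta_hat: SD across replicate simulate-and-fit runs.

    Replicate r uses the seed stream [config.seed, r]; failed fits are
    excluded (more than 10% failures raises).
    """
    if n_reps < 50:
        raise ValueError("n_reps must be at least 50 for a stable SD")
    betas = []
    failures = 0
    for rep in range(n_reps):
        try:
            fit = fit_series(simulate_series(config, rep), spec)
        except (ValueError, RuntimeError):
            failures += 1
            continue
        betas.append(fit.estimate.beta_hat)
    if failures > 0.1 * n_reps:
        raise RuntimeError(f"{failures}/{n_reps} replicate fits failed")
    return float(np.std(betas, ddof=1))


def simulate_multicity(config: MultiCityConfig) -> list[SimulatedSeries]:
    """Simulate J series with true coefficients beta_j ~ N(beta_mean, tau²)."""
    rng = _rng(config.seed, 10_000)
    betas = rng.normal(config.template.beta_true, config.tau, size=config.n_series)
    out = []
    for j in range(config.n_series):
        cfg = replace(
            config.template,
            beta_true=float(betas[j]),
            seed=config.seed,
            baseline_rate=(
                float(config.rate_overrides[j])
                if config.rate_overrides is not None
                else config.template.baseline_rate
            ),
        )
        out.append(simulate_series(cfg, 20_000 + j))
    return out
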