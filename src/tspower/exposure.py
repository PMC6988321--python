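"""Estimating the usable variation of an exposure series.

The SE approximators need SD(x|z) — the standard deviation of the
residuals of the exposure of interest in a linear regression of x on
the covariates z the final outcome model would adjust for (seasonal
time spline, day-of-week indicators, and any extras such as temperature
splines or co-pollutants).  This module builds those covariate designs
from a dated exposure series and profiles the exposure: raw SD, usable
SD, R²_x|z, and the variance inflation ratio.

It also provides the exposure transforms that recur in temperature
studies: a linear-threshold "heat" transform (excess above a percentile
of the series) and running means over a lag window.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import patsy

logger = logging.getLogger(__name__)

__all__ = [
    "ExposureSeries",
    "CovariateSpec",
    "ExposureVariation",
    "time_spline_basis",
    "dow_indicators",
    "usable_sd",
    "threshold_exposure",
    "lagged_mean",
]

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class ExposureSeries:
    """A dated exposure series; values may contain NaN (missing)."""

    dates: pd.DatetimeIndex
    values: np.ndarray

    def __post_init__(self) -> None:
        dates = pd.DatetimeIndex(self.dates)
        values = np.asarray(self.values, dtype=float)
        if len(dates) != len(values):
            raise ValueError("dates and values must have equal length")
        if len(dates) > 1 and not dates.is_monotonic_increasing:
            raise ValueError("dates must be increasing")
        if dates.has_duplicates:
            raise ValueError("dates must be strictly increasing (duplicates found)")
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "values", values)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, date_col: str = "date", value_col: str = "exposure"
    ) -> "ExposureSeries":
        for col in (date_col, value_col):
            if col not in df.columns:
                raise ValueError(f"column {col!r} not found in input table")
        dates = pd.to_datetime(df[date_col], format="ISO8601")
        return cls(pd.DatetimeIndex(dates), df[value_col].to_numpy(dtype=float))


@dataclass(frozen=True)
class CovariateSpec:
    """Covariate design a final outcome analysis would adjust for.

    ``spline_df_per_year`` controls the seasonal/trend time spline
    (0 disables it); ``include_dow`` adds day-of-week indicators;
    ``extra_covariates`` maps names to series aligned with the exposure
    dates (entered linearly).
    """

    spline_df_per_year: float = 7.0
    include_dow: bool = True
    extra_covariates: Mapping[str, Sequence[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.spline_df_per_year < 0:
            raise ValueError("spline_df_per_year must be nonnegative")


@dataclass(frozen=True)
class ExposureVariation:
    """Profile of exposure variation before and after covariate adjustment."""

    sd_raw: float
    sd_usable: float
    r2: float
    vif: float
    n_used: int


def time_spline_basis(
    dates: pd.DatetimeIndex, df_per_year: float
) -> np.ndarray:
    """Natural cubic spline basis of day number with df scaled to span.

    Total df k = round(df_per_year × span in years); knots sit at
    equally spaced quantiles of the observed dates with boundary knots
    at the first and last date.  Returns an intercept-only design
    (single column of ones) when k < 1, and otherwise k linearly
    independent columns spanning the natural-spline space less the
    constant (the raw natural-spline basis contains the constant in its
    span, so the columns are centred and orthogonalised to combine
    cleanly with an explicit intercept; fitted values and residual SDs
    depend only on the column span).
    """
    dates = pd.DatetimeIndex(dates)
    n = len(dates)
    if df_per_year > 0 and dates.nunique() < 2:
        raise ValueError("need at least 2 distinct dates for a time spline")
    day = (dates - dates[0]).days.to_numpy(dtype=float)
    span_years = (day.max() - day.min()) / DAYS_PER_YEAR if n > 1 else 0.0
    k = int(round(df_per_year * span_years))
    if k < 1:
        return np.ones((n, 1))
    if dates.nunique() < k + 2:
        raise ValueError(
            f"degenerate design: {k} spline df need at least {k + 2} distinct "
            f"dates, got {dates.nunique()}"
        )
    raw = np.asarray(
        patsy.dmatrix("cr(day, df=df) - 1", {"day": day, "df": k + 1})
    )
    centred = raw - raw.mean(axis=0)
    u, s, _ = np.linalg.svd(centred, full_matrices=False)
    return u[:, :k] * s[:k]


def dow_indicators(dates: pd.DatetimeIndex) -> np.ndarray:
    """Day-of-week indicator columns (Tuesday…Sunday; Monday is reference)."""
    dates = pd.DatetimeIndex(dates)
    if len(dates) == 0:
        raise ValueError("dates must be non-empty")
    dow = dates.dayofweek.to_numpy()  # Monday = 0
    return np.column_stack([(dow == d).astype(float) for d in range(1, 7)])


def _build_design(
    dates: pd.DatetimeIndex, spec: CovariateSpec
) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = [np.ones((len(dates), 1))]
    names = ["intercept"]
    if spec.spline_df_per_year > 0:
        spline = time_spline_basis(dates, spec.spline_df_per_year)
        if spline.shape[1] > 1 or not np.allclose(spline, 1.0):
            cols.append(spline)
            names += [f"spline{i + 1}" for i in range(spline.shape[1])]
    if spec.include_dow:
        cols.append(dow_indicators(dates))
        names += ["dow_tue", "dow_wed", "dow_thu", "dow_fri", "dow_sat", "dow_sun"]
    for name, series in spec.extra_covariates.items():
        arr = np.asarray(series, dtype=float)
        if len(arr) != len(dates):
            raise ValueError(
                f"extra covariate {name!r} has length {len(arr)}, expected {len(dates)}"
            )
        cols.append(arr.reshape(-1, 1))
        names.append(name)
    return np.hstack(cols), names


def usable_sd(
    exposure: ExposureSeries,
    spec: CovariateSpec | None = None,
    denominator: str = "resid_df",
) -> ExposureVariation:
    """Profile exposure variation by residualising x on the covariate design.

    Fits OLS of the exposure on [intercept | time spline | day-of-week |
    extras] over complete cases.  The raw and residual SDs share one
    denominator — residual degrees of freedom ``n − p`` by default
    (``denominator="resid_df"``) or ``n − 1`` (``"n_minus_1"``) — so
    that sd_usable = sd_raw·sqrt(1 − R²) holds exactly.
    """
    spec = spec or CovariateSpec(spline_df_per_year=0.0, include_dow=False)
    if denominator not in ("resid_df", "n_minus_1"):
        raise ValueError("denominator must be 'resid_df' or 'n_minus_1'")

    design, names = _build_design(exposure.dates, spec)
    extra_missing = np.zeros(len(exposure.values), dtype=bool)
    for series in spec.extra_covariates.values():
        extra_missing |= np.isnan(np.asarray(series, dtype=float))
    keep = ~np.isnan(exposure.values) & ~extra_missing
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("usable_sd: dropped %d incomplete rows", n_dropped)

    x = exposure.values[keep]
    X = design[keep]
    n, p = X.shape
    if n < p + 2:
        raise ValueError(
            f"insufficient data: {n} complete cases for a {p}-column design"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # locate offending columns by incremental rank
        collinear = []
        r = 0
        for j in range(p):
            rj = np.linalg.matrix_rank(X[:, : j + 1])
            if rj == r:
                collinear.append(names[j])
            r = rj
        raise ValueError(f"rank-deficient covariate design; collinear: {collinear}")

    coef, _, _, _ = np.linalg.lstsq(X, x, rcond=None)
    resid = x - X @ coef
    ddof = p if denominator == "resid_df" else 1
    tss = float(np.sum((x - x.mean()) ** 2))
    rss = float(np.sum(resid**2))
    if tss <= 0:
        raise ValueError("exposure has no variation")
    r2 = 1.0 - rss / tss
    if rss <= 0 or r2 >= 1.0 - 1e-12:
        raise ValueError(
            "degenerate profile: covariates explain the exposure exactly "
            "(R² = 1), usable SD is undefined"
        )
    sd_raw = math.sqrt(tss / (n - ddof))
    sd_use = math.sqrt(rss / (n - ddof))
    return ExposureVariation(
        sd_raw=sd_raw,
        sd_usable=sd_use,
        r2=r2,
        vif=(sd_raw / sd_use) ** 2,
        n_used=n,
    )


def threshold_exposure(
    values: Sequence[float], percentile: float = 75.0
) -> np.ndarray:
    """Linear-threshold transform: excess of each value above a percentile.

    Returns max(value − q_p, 0) elementwise, with q_p the empirical
    percentile of the complete cases under the linear-interpolation
    (type-7) convention.  The standard "heat" exposure is temperature
    above the 75th centile.
    """
    if not 0 < percentile < 100:
        raise ValueError(f"percentile must lie in (0, 100), got {percentile!r}")
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("values must be non-empty")
    q = np.nanpercentile(arr, percentile)
    return np.maximum(arr - q, 0.0)


def lagged_mean(values: Sequence[float], lags: Sequence[int]) -> np.ndarray:
    """Running mean of the values at the stated lags (lag 0 = same day).

    Entry i is mean(values[i − lag] for lag in lags); entries with any
    lag falling before the series start are NaN.
    """
    arr = np.asarray(values, dtype=float)
    lags = sorted(set(int(lag) for lag in lags))
    if not lags or lags[0] < 0 or lags[-1] >= arr.size:
        raise ValueError(f"invalid lag range {lags} for series of length {arr.size}")
    out = np.full(arr.size, np.nan)
    max_lag = lags[-1]
    stacked = np.column_stack([arr[max_lag - lag : arr.size - lag] for lag in lags])
    out[max_lag:] = stacked.mean(axis=1)
    return out
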