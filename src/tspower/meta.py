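"""Precision approximators and pooling machinery for multi-series studies.

A multi-city time-series study is analysed in two stages: a log-linear
count regression per series gives coefficient estimates ``beta_hat_j``
with standard errors, and a meta-analysis pools them.  Under a
fixed-effect (common true coefficient) model the pooled SE is, to the
same approximation as the single-series case, driven by the *total*
event count across all series.  Under a random-effects model with
between-series heterogeneity SD ``tau`` the number of series matters
too; in the extreme-heterogeneity limit the pooled SE is tau/sqrt(J),
as for a simple sample mean.

The pooling implementations (inverse-variance fixed effect,
DerSimonian–Laird random effects) are the second stage the validation
harness runs on simulated ensembles.  Series are assumed independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .approx import _require_positive, _require_unit_interval, se_quasipoisson

__all__ = [
    "MultiSeriesPlan",
    "SeriesEstimate",
    "MetaResult",
    "se_fe",
    "se_re_full",
    "se_re_from_i2",
    "se_extreme_het",
    "meta_fixed",
    "meta_random",
    "read_estimates",
    "write_estimates",
]


@dataclass(frozen=True)
class SeriesEstimate:
    """First-stage coefficient estimate for one series (log-RR scale)."""

    beta_hat: float
    se: float

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"se must be positive, got {self.se!r}")


@dataclass(frozen=True)
class MultiSeriesPlan:
    """Design inputs for a planned J-series study.

    ``tau`` (heterogeneity SD, log-RR units) and ``i_squared`` (fraction
    of total variance between series) may both be stored, but each
    random-effects computation is driven by exactly one of them.
    ``per_series_se`` optionally carries predicted per-series SEs for
    the full random-effects approximation.
    """

    n_series: int
    total_events: float
    sd_usable: float
    dispersion: float = 1.0
    tau: float | None = None
    i_squared: float | None = None
    per_series_se: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if self.n_series < 1:
            raise ValueError("n_series must be at least 1")
        _require_positive(
            total_events=self.total_events,
            sd_usable=self.sd_usable,
            dispersion=self.dispersion,
        )
        if self.tau is not None and self.tau < 0:
            raise ValueError("tau must be nonnegative")
        if self.i_squared is not None and not 0 <= self.i_squared < 1:
            raise ValueError("i_squared must lie in [0, 1)")
        if self.per_series_se is not None and any(
            s <= 0 for s in self.per_series_se
        ):
            raise ValueError("per_series_se entries must be positive")


@dataclass(frozen=True)
class MetaResult:
    """Pooled coefficient with fixed- and random-effects uncertainty."""

    beta_pooled: float
    se_fe: float
    se_re: float
    tau2: float
    i_squared: float
    q_stat: float
    n_series: int


def se_fe(total_events: float, sd_usable: float, dispersion: float = 1.0) -> float:
    """Fixed-effect pooled-SE approximation from the all-series event total.

    Identical in form to the single-series quasi-Poisson approximator:
    the inverse-variance weighted mean over homogeneous series gains
    precision exactly as one long series with the pooled events would.
    """
    return se_quasipoisson(total_events, sd_usable, dispersion)


def se_re_full(tau: float, per_series_se: Iterable[float]) -> float:
    """Random-effects pooled SE from tau and predicted per-series SEs.

    sqrt(1 / Σ_j (τ² + se_j²)⁻¹): the inverse-variance pooled SE with
    each series' sampling variance inflated by the heterogeneity
    variance.  With tau = 0 this is the fixed-effect pooled SE.
    """
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    ses = np.asarray(list(per_series_se), dtype=float)
    if ses.size == 0:
        raise ValueError("per_series_se must be non-empty")
    if np.any(ses <= 0):
        raise ValueError("per_series_se entries must be positive")
    return float(math.sqrt(1.0 / np.sum(1.0 / (tau**2 + ses**2))))


def se_re_from_i2(se_fe: float, i_squared: float) -> float:
    """Heterogeneity-corrected pooled SE: se_fe / sqrt(1 − I²).

    Assumes a common per-series SE; I² is the fraction of total variance
    in the series estimates attributable to between-series heterogeneity.
    """
    _require_positive(se_fe=se_fe)
    if not 0 <= i_squared < 1:
        raise ValueError(f"i_squared must lie in [0, 1), got {i_squared!r}")
    return se_fe / math.sqrt(1.0 - i_squared)


def se_extreme_het(tau: float, n_series: int) -> float:
    """Extreme-heterogeneity limit tau / sqrt(J) (a simple sample mean).

    Valid when tau dominates every per-series SE; otherwise it
    understates the pooled SE.
    """
    _require_positive(tau=tau)
    if n_series < 1:
        raise ValueError("n_series must be at least 1")
    return tau / math.sqrt(n_series)


def _q_and_weights(estimates: Sequence[SeriesEstimate]):
    betas = np.array([e.beta_hat for e in estimates], dtype=float)
    w = np.array([1.0 / e.se**2 for e in estimates], dtype=float)
    beta_fe = float(np.sum(w * betas) / np.sum(w))
    q = float(np.sum(w * (betas - beta_fe) ** 2))
    return betas, w, beta_fe, q


def _i_squared(q: float, df: int) -> float:
    # Higgins–Thompson: fraction of Q in excess of its null expectation
    if q <= 0:
        return 0.0
    return max(0.0, (q - df) / q)


def meta_fixed(estimates: Sequence[SeriesEstimate]) -> MetaResult:
    """Inverse-variance fixed-effect meta-analysis of per-series estimates."""
    if len(estimates) == 0:
        raise ValueError("estimates must be non-empty")
    betas, w, beta_fe, q = _q_and_weights(estimates)
    se = float(1.0 / math.sqrt(np.sum(w)))
    return MetaResult(
        beta_pooled=beta_fe,
        se_fe=se,
        se_re=se,
        tau2=0.0,
        i_squared=_i_squared(q, len(estimates) - 1),
        q_stat=q,
        n_series=len(estimates),
    )


def meta_random(estimates: Sequence[SeriesEstimate]) -> MetaResult:
    """DerSimonian–Laird random-effects meta-analysis.

    Moment estimator τ̂² = max(0, (Q − (J−1)) / (Σw − Σw²/Σw)) with
    fixed-effect weights w_j = se_j⁻²; the pooled mean and its SE use
    random-effects weights (τ̂² + se_j²)⁻¹.
    """
    if len(estimates) < 2:
        raise ValueError("random-effects pooling needs at least 2 estimates")
    betas, w, beta_fe, q = _q_and_weights(estimates)
    df = len(estimates) - 1
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    ses2 = np.array([e.se**2 for e in estimates])
    w_re = 1.0 / (tau2 + ses2)
    beta_re = float(np.sum(w_re * betas) / np.sum(w_re))
    return MetaResult(
        beta_pooled=beta_re,
        se_fe=float(1.0 / math.sqrt(np.sum(w))),
        se_re=float(1.0 / math.sqrt(np.sum(w_re))),
        tau2=tau2,
        i_squared=_i_squared(q, df),
        q_stat=q,
        n_series=len(estimates),
    )


def read_estimates(path: str | Path) -> list[SeriesEstimate]:
    """Read per-series (beta, se) estimates from a two-column delimited file."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower(): c for c in df.columns}
    try:
        beta_col, se_col = cols["beta"], cols["se"]
    except KeyError:
        if df.shape[1] < 2:
            raise ValueError(f"{path}: need columns 'beta' and 'se'") from None
        beta_col, se_col = df.columns[:2]
    return [
        SeriesEstimate(beta_hat=float(b), se=float(s))
        for b, s in zip(df[beta_col], df[se_col])
    ]


def write_estimates(estimates: Sequence[SeriesEstimate], path: str | Path) -> None:
    """Write per-series estimates as a CSV with columns beta, se."""
    pd.DataFrame(
        {"beta": [e.beta_hat for e in estimates], "se": [e.se for e in estimates]}
    ).to_csv(path, index=False)
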