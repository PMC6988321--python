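"""Closed-form precision approximators for single-series count regressions.

In a log-linear (quasi-)Poisson time-series regression

    E(Y_i) = exp(alpha + beta * x_i + gamma' z_i)

the sampling standard error of ``beta_hat`` is, to a good approximation,
determined by just three planning-stage quantities: the total expected
event count over the study, the *usable* standard deviation of the
exposure (the SD of x conditional on the covariates z), and the
overdispersion ``phi``.  The number of days over which events are spread
is irrelevant given their total.  The functions here evaluate those
approximations and the planning quantities derived from a standard
error: confidence-interval width, power, smallest detectable
coefficient, and required number of events.

All coefficients are on the log relative-risk scale per unit of
exposure.  Tests are two-sided at level ``alpha`` throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy import stats

__all__ = [
    "SingleSeriesPlan",
    "PrecisionEstimate",
    "PowerSpec",
    "z_upper",
    "se_poisson_crude",
    "se_poisson",
    "se_quasipoisson",
    "variance_inflation_ratio",
    "ci_width",
    "power",
    "smallest_detectable",
    "required_events",
    "years_required",
]


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be positive, got {value!r}")


def _require_unit_interval(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not 0.0 < value < 1.0:
            raise ValueError(f"{name} must lie strictly in (0, 1), got {value!r}")


def z_upper(p: float, printed: bool = False) -> float:
    """Standard normal deviate with upper-tail probability ``p``.

    With ``printed=True`` the exact quantile is rounded to two decimals,
    reproducing the rounded z-values used in desk arithmetic
    (z_0.025 -> 1.96, z_0.1 -> 1.28, z_0.2 -> 0.84).
    """
    _require_unit_interval(p=p)
    z = float(stats.norm.isf(p))
    return round(z, 2) if printed else z


@dataclass(frozen=True)
class SingleSeriesPlan:
    """Scalar design inputs for a single-series study.

    Parameters
    ----------
    total_events : float
        Expected total event count over the study (sum of Y_i).
    sd_raw : float
        Unconditional SD of the exposure, in exposure units.
    sd_usable : float
        SD of exposure conditional on covariates, SD(x|z); the variation
        actually available to estimate beta after confounder adjustment.
    dispersion : float
        Overdispersion phi; residual count variance is phi times the
        Poisson mean-variance identity.  Values below 1 are permitted
        (with a warning) but are unusual for count outcomes.
    alpha : float
        Two-sided significance level.
    """

    total_events: float
    sd_raw: float
    sd_usable: float
    dispersion: float = 1.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        _require_positive(
            total_events=self.total_events,
            sd_raw=self.sd_raw,
            sd_usable=self.sd_usable,
            dispersion=self.dispersion,
        )
        _require_unit_interval(alpha=self.alpha)
        if self.sd_usable > self.sd_raw:
            raise ValueError(
                "sd_usable must not exceed sd_raw: conditioning on covariates "
                f"cannot increase the SD (got {self.sd_usable} > {self.sd_raw})"
            )
        if self.dispersion < 1.0:
            warnings.warn(
                "dispersion < 1 (underdispersion) is unusual for count data",
                UserWarning,
                stacklevel=3,
            )


@dataclass(frozen=True)
class PrecisionEstimate:
    """A standard-error approximation together with its CI width."""

    se: float
    method: str  # one of {"poisson_crude", "poisson", "quasi_poisson"}
    ci_width: float


@dataclass(frozen=True)
class PowerSpec:
    """Alternative-hypothesis coefficient with test size and target power."""

    beta_h1: float
    alpha: float = 0.05
    power: float = 0.8

    def __post_init__(self) -> None:
        _require_unit_interval(alpha=self.alpha, power=self.power)


def se_poisson_crude(total_events: float, sd_raw: float) -> float:
    """Crudest SE approximation: 1 / (sqrt(total events) * SD(x)).

    Ignores the loss of exposure variation to covariate adjustment, so
    it understates the SE whenever the exposure is partly explained by
    the covariates (e.g. a seasonal exposure against a seasonal spline).
    """
    _require_positive(total_events=total_events, sd_raw=sd_raw)
    return 1.0 / (math.sqrt(total_events) * sd_raw)


def se_poisson(total_events: float, sd_usable: float) -> float:
    """Poisson SE approximation using the usable SD: 1 / (sqrt(ΣY) * SD(x|z))."""
    _require_positive(total_events=total_events, sd_usable=sd_usable)
    return 1.0 / (math.sqrt(total_events) * sd_usable)


def se_quasipoisson(
    total_events: float, sd_usable: float, dispersion: float = 1.0
) -> float:
    """Quasi-Poisson SE approximation: sqrt(phi) / (sqrt(ΣY) * SD(x|z)).

    Reduces to :func:`se_poisson` at ``dispersion == 1``.
    """
    _require_positive(
        total_events=total_events, sd_usable=sd_usable, dispersion=dispersion
    )
    if dispersion < 1.0:
        warnings.warn(
            "dispersion < 1 (underdispersion) is unusual for count data",
            UserWarning,
            stacklevel=2,
        )
    return math.sqrt(dispersion) / (math.sqrt(total_events) * sd_usable)


def variance_inflation_ratio(sd_raw: float, sd_usable: float) -> float:
    """(SD(x) / SD(x|z))²: factor by which adjustment inflates V(beta_hat)."""
    _require_positive(sd_raw=sd_raw, sd_usable=sd_usable)
    if sd_usable > sd_raw:
        raise ValueError(
            f"sd_usable ({sd_usable}) exceeds sd_raw ({sd_raw}); "
            "conditioning cannot increase the SD"
        )
    return (sd_raw / sd_usable) ** 2


def ci_width(se: float, alpha: float = 0.05, printed_z: bool = False) -> float:
    """Width of the two-sided (1 - alpha) confidence interval, 2 z_{α/2} SE."""
    _require_positive(se=se)
    _require_unit_interval(alpha=alpha)
    return 2.0 * z_upper(alpha / 2.0, printed=printed_z) * se


def power(
    beta_h1: float, se: float, alpha: float = 0.05, printed_z: bool = False
) -> float:
    """Power to detect a true coefficient ``beta_h1`` given SE(beta_hat).

    Normal-approximation power Φ(|β_H1|/SE − z_{α/2}) for a two-sided
    test at level ``alpha``; the (negligible) probability of rejection
    in the wrong tail is ignored.
    """
    _require_positive(se=se)
    _require_unit_interval(alpha=alpha)
    z = z_upper(alpha / 2.0, printed=printed_z)
    return float(stats.norm.cdf(abs(beta_h1) / se - z))


def smallest_detectable(
    se: float,
    alpha: float = 0.05,
    target_power: float = 0.8,
    printed_z: bool = False,
) -> float:
    """Smallest true |beta| detectable at given size and power.

    (z_{α/2} + z_{1−power}) × SE; at alpha = 0.05 and power 0.8 the
    multiplier is 2.80 (printed z: 1.96 + 0.84).
    """
    _require_positive(se=se)
    _require_unit_interval(alpha=alpha, target_power=target_power)
    multiplier = z_upper(alpha / 2.0, printed=printed_z) + z_upper(
        1.0 - target_power, printed=printed_z
    )
    return multiplier * se


def required_events(
    beta_h1: float,
    sd_usable: float,
    alpha: float = 0.05,
    target_power: float = 0.8,
    dispersion: float = 1.0,
    printed_z: bool = False,
) -> float:
    """Total event count needed to detect ``beta_h1`` at given size and power.

    phi * [(z_{α/2} + z_{1−power}) / (|β_H1| * SD(x|z))]².  With
    ``dispersion=1`` this inverts the Poisson SE approximation; the phi
    multiplier extends it to the quasi-Poisson SE.
    """
    if beta_h1 == 0:
        raise ValueError("beta_h1 must be nonzero (a null effect needs infinite events)")
    _require_positive(sd_usable=sd_usable, dispersion=dispersion)
    _require_unit_interval(alpha=alpha, target_power=target_power)
    multiplier = z_upper(alpha / 2.0, printed=printed_z) + z_upper(
        1.0 - target_power, printed=printed_z
    )
    return dispersion * (multiplier / (abs(beta_h1) * sd_usable)) ** 2


def years_required(required: float, events_per_year: float) -> float:
    """Series length in years implied by a required event count."""
    _require_positive(required_events=required, events_per_year=events_per_year)
    return required / events_per_year


def precision_estimate(
    plan: SingleSeriesPlan, method: str = "quasi_poisson", printed_z: bool = False
) -> PrecisionEstimate:
    """Evaluate one of the SE approximators for a plan, with its CI width."""
    if method == "poisson_crude":
        se = se_poisson_crude(plan.total_events, plan.sd_raw)
    elif method == "poisson":
        se = se_poisson(plan.total_events, plan.sd_usable)
    elif method == "quasi_poisson":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            se = se_quasipoisson(plan.total_events, plan.sd_usable, plan.dispersion)
    else:
        raise ValueError(f"unknown method {method!r}")
    return PrecisionEstimate(
        se=se, method=method, ci_width=ci_width(se, plan.alpha, printed_z=printed_z)
    )
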