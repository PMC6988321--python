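"""Assemble planning reports from the closed-form approximators.

A report is a plain dict (ready for YAML/JSON serialisation) in which
every number is recomputable from the echoed inputs via the library
functions — the reporting layer never re-derives any math.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__, approx, meta
from .approx import PowerSpec, SingleSeriesPlan
from .meta import MultiSeriesPlan

__all__ = ["plan_single", "plan_multi", "power_curve_table"]

I2_SWEEP_DEFAULT = (0.0, 0.10, 0.25, 0.50, 0.75)


def plan_single(
    plan: SingleSeriesPlan,
    power_spec: PowerSpec | None = None,
    events_per_year: float | None = None,
    printed_z: bool = False,
) -> dict:
    """Single-series planning report: SEs, CI width, and power block.

    The power block (power at the target coefficient, smallest
    detectable coefficient, required events, years of data) is included
    only when a :class:`PowerSpec` is given.
    """
    se_crude = approx.se_poisson_crude(plan.total_events, plan.sd_raw)
    se_poiss = approx.se_poisson(plan.total_events, plan.sd_usable)
    est = approx.precision_estimate(plan, "quasi_poisson", printed_z=printed_z)
    report: dict = {
        "inputs": {
            "total_events": plan.total_events,
            "sd_raw": plan.sd_raw,
            "sd_usable": plan.sd_usable,
            "dispersion": plan.dispersion,
            "alpha": plan.alpha,
            "events_per_year": events_per_year,
            "printed_z": printed_z,
        },
        "version": __version__,
        "se": {
            "poisson_crude": se_crude,
            "poisson": se_poiss,
            "quasi_poisson": est.se,
        },
        "variance_inflation_ratio": approx.variance_inflation_ratio(
            plan.sd_raw, plan.sd_usable
        ),
        "ci_width": est.ci_width,
    }
    if power_spec is not None:
        required = approx.required_events(
            power_spec.beta_h1,
            plan.sd_usable,
            power_spec.alpha,
            power_spec.power,
            plan.dispersion,
            printed_z=printed_z,
        )
        block = {
            "beta_h1": power_spec.beta_h1,
            "target_power": power_spec.power,
            "power_at_beta_h1": approx.power(
                power_spec.beta_h1, est.se, power_spec.alpha, printed_z=printed_z
            ),
            "smallest_detectable": approx.smallest_detectable(
                est.se, power_spec.alpha, power_spec.power, printed_z=printed_z
            ),
            "required_events": required,
        }
        if events_per_year is not None:
            block["years_required"] = approx.years_required(required, events_per_year)
        report["power"] = block
    return report


def plan_multi(
    plan: MultiSeriesPlan,
    power_spec: PowerSpec | None = None,
    extreme_het: bool = False,
    i2_sweep: Sequence[float] = I2_SWEEP_DEFAULT,
    printed_z: bool = False,
) -> dict:
    """Multi-series planning report: pooled FE/RE SEs with an I² sweep.

    The random-effects SE uses the full tau-based approximation when
    both ``plan.tau`` and per-series SEs are available, the I²
    correction when ``plan.i_squared`` is given, and the tau/sqrt(J)
    extreme-heterogeneity limit when ``extreme_het`` is set.
    """
    se_fixed = meta.se_fe(plan.total_events, plan.sd_usable, plan.dispersion)
    report: dict = {
        "inputs": {
            "n_series": plan.n_series,
            "total_events": plan.total_events,
            "sd_usable": plan.sd_usable,
            "dispersion": plan.dispersion,
            "tau": plan.tau,
            "i_squared": plan.i_squared,
            "printed_z": printed_z,
        },
        "version": __version__,
        "se_fe": se_fixed,
        "i2_sweep": {
            f"{i2:g}": meta.se_re_from_i2(se_fixed, i2) for i2 in i2_sweep
        },
    }
    re_block: dict = {}
    if plan.tau is not None and plan.per_series_se is not None:
        re_block["tau_full"] = meta.se_re_full(plan.tau, plan.per_series_se)
    if plan.i_squared is not None:
        re_block["from_i2"] = meta.se_re_from_i2(se_fixed, plan.i_squared)
    if extreme_het:
        if plan.tau is None or plan.tau <= 0:
            raise ValueError("extreme-heterogeneity SE needs a positive tau")
        re_block["extreme_het"] = meta.se_extreme_het(plan.tau, plan.n_series)
    if re_block:
        report["se_re"] = re_block
    se_for_power = re_block.get(
        "tau_full", re_block.get("from_i2", re_block.get("extreme_het", se_fixed))
    )
    if power_spec is not None:
        report["power"] = {
            "beta_h1": power_spec.beta_h1,
            "target_power": power_spec.power,
            "power_at_beta_h1": approx.power(
                power_spec.beta_h1, se_for_power, power_spec.alpha, printed_z=printed_z
            ),
            "smallest_detectable": approx.smallest_detectable(
                se_for_power, power_spec.alpha, power_spec.power, printed_z=printed_z
            ),
            "se_used": se_for_power,
        }
    return report


def power_curve_table(
    coefficients_per_sd: Sequence[float] = (0.05, 0.02, 0.01, 0.005),
    dispersions: Sequence[float] = (1.0, 1.2, 1.5),
    events: Sequence[float] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Power as a function of total events, effect size and dispersion.

    Coefficients are expressed per one unit of usable exposure SD, so
    the SE is sqrt(phi/events); the default grid covers coefficients of
    5, 2, 1 and 0.5% per SD and dispersions 1.0, 1.2 and 1.5 over a
    logarithmic event range.
    """
    if len(coefficients_per_sd) == 0 or len(dispersions) == 0:
        raise ValueError("empty power-curve grid")
    if events is None:
        events = np.geomspace(100, 2e6, 120)
    events = np.asarray(list(events), dtype=float)
    if events.size == 0:
        raise ValueError("empty power-curve grid")
    records = []
    for coef in coefficients_per_sd:
        for phi in dispersions:
            for n in events:
                se = approx.se_quasipoisson(n, 1.0, phi)
                records.append(
                    {
                        "events": n,
                        "coef_per_sd": coef,
                        "dispersion": phi,
                        "power": approx.power(coef, se, alpha),
                    }
                )
    return pd.DataFrame.from_records(records)
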