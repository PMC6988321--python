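"""Validation harness: percent error of SE approximators on synthetic data.

For each scenario a synthetic series (or multi-city ensemble) is
generated with known parameters, the standard first-stage quasi-Poisson
regression (and, for ensembles, second-stage meta-analysis) is fitted,
and each closed-form approximator is compared with the fitted reference
SE via

    % error = 100 · (approximation − reference) / reference.

Single-series rows check the crude-Poisson, Poisson and quasi-Poisson
approximators against the Pearson-scaled model SE from one long
replicate; the approximators are fed the *realised* event total and the
exposure SDs profiled with the same covariate design the fit uses, so
the comparison isolates the approximation itself from input-parameter
uncertainty.  Multi-city rows check the pooled-SE approximators
(fixed-effect, tau-based random effects, I²-corrected, and the
extreme-heterogeneity limit) against fitted fixed- and random-effects
meta-analytic SEs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import approx, meta
from .exposure import CovariateSpec, ExposureSeries, usable_sd
from .simulate import (
    MultiCityConfig,
    SimulationConfig,
    fit_series,
    simulate_multicity,
    simulate_series,
)

__all__ = [
    "Scenario",
    "ValidationRow",
    "default_single_grid",
    "validate_single",
    "validate_multicity",
    "validate_approximations",
    "summarize",
]


@dataclass(frozen=True)
class Scenario:
    """One validation scenario: a generator config plus the fitted design."""

    label: str
    config: SimulationConfig
    spec: CovariateSpec = field(default_factory=CovariateSpec)


@dataclass(frozen=True)
class ValidationRow:
    """Percent error of one approximator in one scenario."""

    label: str
    approximator: str
    se_true: float
    se_approx: float

    @property
    def pct_error(self) -> float:
        return 100.0 * (self.se_approx - self.se_true) / self.se_true


def default_single_grid(seed: int = 0) -> list[Scenario]:
    """Standard 20-scenario Poisson grid for single-series validation.

    Crosses series length {1000, 3650} days with baseline rate
    {5, 20, 50}/day and true coefficient {0, 0.01, 0.02} per exposure
    unit (18 scenarios), plus two decoupled-exposure scenarios in which
    the exposure carries no seasonality, so the crude and
    covariate-adjusted approximators should coincide.
    """
    scenarios = []
    for n_days, rate, beta in itertools.product(
        (1000, 3650), (5.0, 20.0, 50.0), (0.0, 0.01, 0.02)
    ):
        cfg = SimulationConfig(
            n_days=n_days, baseline_rate=rate, beta_true=beta, seed=seed
        )
        scenarios.append(
            Scenario(label=f"n{n_days}_rate{rate:g}_beta{beta:g}", config=cfg)
        )
    for n_days in (1000, 3650):
        cfg = SimulationConfig(
            n_days=n_days,
            baseline_rate=20.0,
            beta_true=0.02,
            seed=seed,
            exposure_model=replace(SimulationConfig().exposure_model, amplitude=0.0),
            confounder_coupling=0.0,
        )
        scenarios.append(Scenario(label=f"n{n_days}_decoupled", config=cfg))
    return scenarios


def _rows_to_frame(rows: list[ValidationRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "label": [r.label for r in rows],
            "approximator": [r.approximator for r in rows],
            "se_true": [r.se_true for r in rows],
            "se_approx": [r.se_approx for r in rows],
            "pct_error": [r.pct_error for r in rows],
        }
    )


def validate_single(scenarios: list[Scenario], index_offset: int = 0) -> pd.DataFrame:
    """Single-replicate percent error of the single-series approximators.

    Returns one row per scenario × approximator with columns label,
    approximator, se_true, se_approx, pct_error.
    """
    rows: list[ValidationRow] = []
    for idx, sc in enumerate(scenarios):
        series = simulate_series(sc.config, index_offset + idx)
        fit = fit_series(series, sc.spec)
        var = usable_sd(
            ExposureSeries(series.dates, series.exposure), sc.spec
        )
        total = fit.total_events
        se_true = fit.estimate.se
        with warnings.catch_warnings():
            # a fitted dispersion slightly below 1 is routine sampling noise
            warnings.simplefilter("ignore", UserWarning)
            approxes = {
                "poisson_crude (1)": approx.se_poisson_crude(total, var.sd_raw),
                "poisson (2)": approx.se_poisson(total, var.sd_usable),
                "quasi_poisson (3)": approx.se_quasipoisson(
                    total, var.sd_usable, fit.dispersion_hat
                ),
            }
        rows.extend(
            ValidationRow(sc.label, name, se_true, se_hat)
            for name, se_hat in approxes.items()
        )
    return _rows_to_frame(rows)


def validate_multicity(
    config: MultiCityConfig, spec: CovariateSpec | None = None
) -> pd.DataFrame:
    """Percent error of pooled-SE approximators on one simulated ensemble.

    Fits every series, pools by fixed-effect and DerSimonian–Laird
    random-effects meta-analysis, and compares the pooled-SE
    approximators — fed the realised total events, mean usable SD, mean
    fitted dispersion, the generator's true tau and the fitted I² —
    against both fitted references.
    """
    spec = spec or CovariateSpec()
    ensemble = simulate_multicity(config)
    fits = [fit_series(s, spec) for s in ensemble]
    variations = [
        usable_sd(ExposureSeries(s.dates, s.exposure), spec) for s in ensemble
    ]
    total = sum(f.total_events for f in fits)
    sd_use = float(np.mean([v.sd_usable for v in variations]))
    phi_bar = float(np.mean([f.dispersion_hat for f in fits]))

    estimates = [f.estimate for f in fits]
    fe = meta.meta_fixed(estimates)
    re = meta.meta_random(estimates)

    se_fe_poiss = meta.se_fe(total, sd_use, 1.0)
    approx_se_j = [
        approx.se_quasipoisson(f.total_events, v.sd_usable, 1.0)
        for f, v in zip(fits, variations)
    ]
    with warnings.catch_warnings():
        # a mean fitted dispersion slightly below 1 is routine sampling noise
        warnings.simplefilter("ignore", UserWarning)
        se_fe_qp = meta.se_fe(total, sd_use, phi_bar)
    rows = [
        ValidationRow("multicity", "fe_poisson (4)", fe.se_fe, se_fe_poiss),
        ValidationRow(
            "multicity",
            "fe_quasi_poisson (5)",
            fe.se_fe,
            se_fe_qp,
        ),
        ValidationRow(
            "multicity",
            "re_tau_known (6)",
            re.se_re,
            meta.se_re_full(config.tau, approx_se_j),
        ),
        ValidationRow(
            "multicity",
            "re_from_i2 (7)",
            re.se_re,
            meta.se_re_from_i2(se_fe_poiss, re.i_squared),
        ),
    ]
    if config.tau > 0:
        rows.append(
            ValidationRow(
                "multicity",
                "extreme_het (8)",
                re.se_re,
                meta.se_extreme_het(config.tau, config.n_series),
            )
        )
    return _rows_to_frame(rows)


def validate_approximations(
    scenarios: list[Scenario] | None = None,
    multicity: MultiCityConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the standard validation: single-series grid plus an ensemble."""
    if scenarios is None:
        scenarios = default_single_grid(seed)
    frames = [validate_single(scenarios)]
    if multicity is not None:
        frames.append(validate_multicity(multicity))
    return pd.concat(frames, ignore_index=True)


def summarize(rows: pd.DataFrame) -> pd.DataFrame:
    """Mean, mean-absolute, min and max percent error per approximator."""
    return (
        rows.groupby("approximator")["pct_error"]
        .agg(
            mean="mean",
            mean_absolute=lambda s: s.abs().mean(),
            lowest="min",
            highest="max",
        )
        .reset_index()
    )
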