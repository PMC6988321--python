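"""Unit and property tests for the single-series precision approximators."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from tspower import approx
from tspower.approx import (
    PowerSpec,
    SingleSeriesPlan,
    ci_width,
    power,
    required_events,
    se_poisson,
    se_poisson_crude,
    se_quasipoisson,
    smallest_detectable,
    variance_inflation_ratio,
    years_required,
    z_upper,
)

positive = st.floats(min_value=1e-3, max_value=1e6, allow_nan=False)


class TestSeApproximators:
    @pytest.mark.parametrize(
        "events, sd, expected",
        [(100, 1.0, 0.1), (3888, 0.97, 0.016534)],
    )
    def test_crude_examples(self, events, sd, expected):
        assert se_poisson_crude(events, sd) == pytest.approx(expected, abs=5e-6)

    @pytest.mark.parametrize(
        "events, sd, expected",
        [(3888, 0.76, 0.02110), (1, 1, 1.0), (20000, 1.0, 0.0070711)],
    )
    def test_poisson_examples(self, events, sd, expected):
        assert se_poisson(events, sd) == pytest.approx(expected, abs=5e-5)

    def test_poisson_worked_example_rounds_to_printed_value(self):
        assert round(se_poisson(3888, 0.76), 3) == 0.021

    @pytest.mark.parametrize(
        "events, sd, phi, expected",
        [(3888, 0.76, 1.0, 0.02110), (3888, 0.76, 1.2, 0.023115)],
    )
    def test_quasipoisson_examples(self, events, sd, phi, expected):
        assert se_quasipoisson(events, sd, phi) == pytest.approx(expected, abs=5e-5)

    @given(events=positive, sd=positive)
    def test_quadrupling_events_halves_crude_se(self, events, sd):
        assert se_poisson_crude(4 * events, sd) == pytest.approx(
            se_poisson_crude(events, sd) / 2, rel=1e-12
        )

    @given(events=positive, sd=positive)
    def test_dispersion_scaling(self, events, sd):
        assert se_quasipoisson(events, sd, 4.0) == pytest.approx(
            2 * se_poisson(events, sd), rel=1e-12
        )
        assert se_quasipoisson(events, sd, 1.0) == pytest.approx(
            se_poisson(events, sd), rel=1e-12
        )

    @given(
        events=positive,
        sd_raw=positive,
        shrink=st.floats(min_value=0.01, max_value=1.0),
        phi=st.floats(min_value=1.0, max_value=10.0),
    )
    def test_se_ordering(self, events, sd_raw, shrink, phi):
        """Crude <= Poisson <= quasi-Poisson when sd_usable <= sd_raw, phi >= 1."""
        sd_usable = sd_raw * shrink
        a = se_poisson_crude(events, sd_raw)
        b = se_poisson(events, sd_usable)
        c = se_quasipoisson(events, sd_usable, phi)
        assert a <= b * (1 + 1e-12) <= c * (1 + 1e-12)

    @given(
        days=st.integers(min_value=100, max_value=20000),
        rate=st.floats(min_value=0.1, max_value=100.0),
        split=st.integers(min_value=2, max_value=50),
        sd=positive,
    )
    def test_day_count_irrelevance(self, days, rate, split, sd):
        """Designs with equal total events give identical SEs no matter how
        the events are spread over days (days × rate enters only as a
        product)."""
        a = se_quasipoisson(days * rate, sd, 1.3)
        b = se_quasipoisson((days * split) * (rate / split), sd, 1.3)
        assert a == pytest.approx(b, rel=1e-12)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_domain_errors_name_input(self, bad):
        with pytest.raises(ValueError, match="total_events"):
            se_poisson(bad, 1.0)
        with pytest.raises(ValueError, match="sd_usable"):
            se_poisson(10.0, bad)

    def test_underdispersion_warns(self):
        with pytest.warns(UserWarning, match="underdispersion"):
            se_quasipoisson(100, 1.0, 0.8)


class TestVarianceInflation:
    @pytest.mark.parametrize(
        "sd_raw, sd_usable, expected",
        [(1.0, 1.0, 1.0), (9.7, 7.6, 1.629), (2.0, 1.0, 4.0)],
    )
    def test_examples(self, sd_raw, sd_usable, expected):
        assert variance_inflation_ratio(sd_raw, sd_usable) == pytest.approx(
            expected, abs=5e-4
        )

    def test_usable_above_raw_rejected(self):
        with pytest.raises(ValueError, match="sd_usable"):
            variance_inflation_ratio(1.0, 2.0)


class TestCiWidth:
    def test_worked_example_printed_z(self):
        assert round(ci_width(0.021, 0.05, printed_z=True), 3) == 0.082

    def test_exact_quantile(self):
        assert ci_width(1.0, 0.05) == pytest.approx(2 * 1.959964, abs=1e-5)

    def test_width_shrinks_with_se(self):
        assert ci_width(1e-9, 0.05) < 1e-8

    def test_alpha_out_of_range(self):
        with pytest.raises(ValueError, match="p"):
            ci_width(0.1, 1.5)


class TestPower:
    def test_worked_example(self):
        # power 82% to detect 0.06 with SE 0.021
        p = power(0.06, 0.021, 0.05, printed_z=True)
        assert round(100 * p) == 82
        assert p == pytest.approx(0.8152, abs=2e-3)

    def test_null_effect_gives_half_alpha(self):
        assert power(0.0, 0.5, 0.05) == pytest.approx(0.025, abs=1e-6)

    def test_effect_28_ses_gives_80_percent(self):
        assert power(2.8 * 0.1, 0.1, 0.05, printed_z=True) == pytest.approx(
            0.8, abs=2e-3
        )

    @given(
        b1=st.floats(min_value=0.01, max_value=5.0),
        scale=st.floats(min_value=1.01, max_value=5.0),
        se=st.floats(min_value=0.01, max_value=2.0),
    )
    def test_monotone_in_effect_and_precision(self, b1, scale, se):
        p0 = power(b1, se, 0.05)
        p_eff = power(b1 * scale, se, 0.05)
        p_prec = power(b1, se / scale, 0.05)
        assert p_eff >= p0 and p_prec >= p0
        if p0 < 1.0 - 1e-12:  # strict until the normal CDF saturates
            assert p_eff > p0 and p_prec > p0

    def test_decreasing_in_dispersion_via_se(self):
        se1 = se_quasipoisson(5000, 1.0, 1.0)
        se2 = se_quasipoisson(5000, 1.0, 1.5)
        assert power(0.05, se2) < power(0.05, se1)


class TestSmallestDetectable:
    def test_worked_example(self):
        assert round(smallest_detectable(0.021, 0.05, 0.8, printed_z=True), 3) == 0.059

    def test_ten_city_extension(self):
        se = se_poisson(9720, 0.76)
        assert round(smallest_detectable(se, 0.05, 0.8), 3) == 0.037

    def test_power_half_multiplier_is_z_alpha(self):
        assert smallest_detectable(1.0, 0.05, 0.5) == pytest.approx(
            z_upper(0.025), rel=1e-12
        )

    def test_multiplier_at_80_power(self):
        exact = smallest_detectable(1.0, 0.05, 0.8)
        assert 2.80 <= exact <= 2.81
        assert smallest_detectable(1.0, 0.05, 0.8, printed_z=True) == pytest.approx(2.8)


class TestRequiredEvents:
    def test_worked_example_printed_z(self):
        n = required_events(0.06, 0.76, 0.05, 0.9, printed_z=True)
        assert round(n) == 5048

    def test_twenty_thousand_deaths_for_2pct_per_sd(self):
        n = required_events(0.02, 1.0, 0.05, 0.8)
        assert n == pytest.approx(19622, abs=5)

    @given(beta=st.floats(min_value=0.001, max_value=1.0), sd=positive)
    def test_doubling_effect_quarters_requirement(self, beta, sd):
        assert required_events(2 * beta, sd) == pytest.approx(
            required_events(beta, sd) / 4, rel=1e-9
        )

    def test_null_effect_rejected(self):
        with pytest.raises(ValueError, match="beta_h1"):
            required_events(0.0, 1.0)

    def test_dispersion_multiplier(self):
        assert required_events(0.05, 1.0, dispersion=1.5) == pytest.approx(
            1.5 * required_events(0.05, 1.0), rel=1e-12
        )


class TestRoundTrips:
    # target power >= 0.3 keeps the detectability multiplier positive, the
    # regime in which the inversion is well defined
    @given(
        se=st.floats(min_value=1e-4, max_value=10.0),
        alpha=st.floats(min_value=0.001, max_value=0.2),
        p=st.floats(min_value=0.3, max_value=0.99),
    )
    def test_power_of_smallest_detectable_recovers_power(self, se, alpha, p):
        beta = smallest_detectable(se, alpha, p)
        assert power(beta, se, alpha) == pytest.approx(p, abs=1e-9)

    @given(
        beta=st.floats(min_value=0.001, max_value=1.0),
        sd=st.floats(min_value=0.01, max_value=100.0),
        p=st.floats(min_value=0.3, max_value=0.99),
    )
    def test_required_events_recovers_power(self, beta, sd, p):
        n = required_events(beta, sd, 0.05, p)
        assert power(beta, se_poisson(n, sd), 0.05) == pytest.approx(p, abs=1e-9)


class TestYearsRequired:
    @pytest.mark.parametrize(
        "events, per_year, expected",
        [(5048, 486, 10.39), (100, 100, 1.0), (9720, 486, 20.0)],
    )
    def test_examples(self, events, per_year, expected):
        assert years_required(events, per_year) == pytest.approx(expected, abs=0.005)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            years_required(0, 486)


class TestDomainTypes:
    def test_plan_validates_sd_ordering(self):
        with pytest.raises(ValueError, match="sd_usable"):
            SingleSeriesPlan(total_events=100, sd_raw=1.0, sd_usable=2.0)

    def test_plan_warns_on_underdispersion(self):
        with pytest.warns(UserWarning, match="underdispersion"):
            SingleSeriesPlan(total_events=100, sd_raw=1.0, sd_usable=0.9, dispersion=0.9)

    def test_power_spec_bounds(self):
        with pytest.raises(ValueError):
            PowerSpec(beta_h1=0.1, alpha=0.0)
        with pytest.raises(ValueError):
            PowerSpec(beta_h1=0.1, power=1.0)

    def test_precision_estimate_ci_consistency(self):
        plan = SingleSeriesPlan(total_events=3888, sd_raw=0.97, sd_usable=0.76)
        est = approx.precision_estimate(plan, "poisson")
        assert est.ci_width == pytest.approx(
            2 * stats.norm.isf(0.025) * est.se, rel=1e-12
        )

    def test_printed_z_values(self):
        assert z_upper(0.025, printed=True) == 1.96
        assert z_upper(0.1, printed=True) == 1.28
        assert z_upper(0.2, printed=True) == 0.84
        assert z_upper(0.025) == pytest.approx(1.9599640, abs=1e-6)
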