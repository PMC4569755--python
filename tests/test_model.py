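"""Closed-form prediction math: design terms, centiles, quantiles, extrema."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vitd_centiles import (
    ModelCoefficients,
    bmi_transform,
    centile,
    day_of_year,
    design_vector,
    extremum_days,
    mean_sqrt,
    quantile_of,
    seasonal_basis,
)
from vitd_centiles.model import day_to_month_day, design_matrix


@pytest.mark.parametrize(
    "bmi,expected",
    [(25.0, -0.2), (16.0, -0.25), (20.0, -0.22360679774997896)],
)
def test_bmi_transform_values(bmi, expected):
    assert bmi_transform(bmi) == pytest.approx(expected, abs=1e-12)


def test_bmi_transform_rejects_nonpositive():
    with pytest.raises(ValueError):
        bmi_transform(0.0)
    with pytest.raises(ValueError):
        bmi_transform(-5.0)


@given(st.floats(min_value=10.0, max_value=60.0))
def test_bmi_transform_monotone_negative(b):
    assert bmi_transform(b) < 0
    assert bmi_transform(b + 1.0) > bmi_transform(b)


@pytest.mark.parametrize(
    "month,dom,expected",
    [(1, 1, 1), (8, 22, 234), (3, 11, 70), (3, 18, 77), (12, 31, 365), (2, 29, 60)],
)
def test_day_of_year(month, dom, expected):
    assert day_of_year(month, dom) == expected


@pytest.mark.parametrize("month,dom", [(2, 30), (13, 1), (4, 31), (0, 5)])
def test_day_of_year_rejects_invalid(month, dom):
    with pytest.raises(ValueError):
        day_of_year(month, dom)


def test_day_roundtrip_all_year():
    for d in range(1, 366):
        m, dom = day_to_month_day(d)
        assert day_of_year(m, dom) == d


def test_seasonal_basis_frozen_values():
    s1, c1, s2, c2 = seasonal_basis(1)
    assert (s1, c1, s2, c2) == (0.0, 1.0, 0.0, 1.0)
    s1, c1, s2, c2 = seasonal_basis(234)
    # direct trig evaluation at 2*pi*233/365
    assert s1 == pytest.approx(-0.7638886127905429, abs=1e-12)
    assert c1 == pytest.approx(-0.64534811322955, abs=1e-12)
    assert s2 == pytest.approx(0.9859481499638303, abs=1e-12)
    assert c2 == pytest.approx(-0.16705162550211988, abs=1e-12)


@given(st.integers(min_value=1, max_value=365))
def test_seasonal_basis_identities(day):
    s1, c1, s2, c2 = seasonal_basis(day)
    assert s1**2 + c1**2 == pytest.approx(1.0, abs=1e-12)
    assert s2**2 + c2**2 == pytest.approx(1.0, abs=1e-12)
    # double-angle consistency between the harmonics
    assert s2 == pytest.approx(2 * s1 * c1, abs=1e-12)


def test_seasonal_basis_rejects_out_of_range():
    with pytest.raises(ValueError):
        seasonal_basis(0)
    with pytest.raises(ValueError):
        seasonal_basis(366)


class TestDesignVector:
    def test_female_has_no_lowbmi_term_and_harmonic_copies(self):
        x = design_vector("F", 20.0, 234)
        assert x[0] == 1.0
        assert x[7] == 0.0
        assert x[8] == pytest.approx(-0.7638886127905429, abs=1e-12)
        assert x[9] == pytest.approx(-0.64534811322955, abs=1e-12)

    def test_male_boundary_bmi25(self):
        x = design_vector("M", 25.0, 1)
        assert x[7] == 0.0
        assert x[8] == x[9] == 0.0

    def test_male_low_bmi_spline_value(self):
        x = design_vector("M", 20.0, 1)
        assert x[7] == pytest.approx(0.0005572809000084114, rel=1e-9)

    def test_spline_continuous_at_25(self):
        # value and slope of the one-sided term vanish as BMI -> 25-
        eps = 1e-6
        just_below = design_vector("M", 25.0 - eps, 1)[7]
        assert just_below < 1e-12
        assert design_vector("M", 25.0, 1)[7] == 0.0

    def test_matrix_matches_vector(self):
        sexes = ["M", "F", "M", "F"]
        bmis = [20.0, 20.0, 30.0, 30.0]
        days = [1, 100, 234, 365]
        X = design_matrix(sexes, bmis, days)
        for i in range(4):
            np.testing.assert_allclose(
                X[i], design_vector(sexes[i], bmis[i], days[i]), atol=1e-14)

    def test_rejects_bad_sex(self):
        with pytest.raises(ValueError):
            design_vector("X", 25.0, 1)


class TestMeanAndCentile:
    def test_mean_sqrt_term_by_term_oracle(self, published):
        # independent re-evaluation summing the 10 printed terms
        for sex, bmi, day in [("F", 20.0, 234), ("M", 25.0, 1), ("M", 19.0, 100),
                              ("F", 38.0, 300)]:
            s1, c1, s2, c2 = seasonal_basis(day)
            tb = -1.0 / math.sqrt(bmi)
            b = published.beta
            female = sex == "F"
            expected = (b[0] + b[1] * s1 + b[2] * c1 + b[3] * s2 + b[4] * c2
                        + b[5] * tb + b[6] * tb * tb
                        + b[7] * ((tb + 0.2) ** 2 if (not female and bmi < 25) else 0)
                        + (b[8] * s1 + b[9] * c1 if female else 0.0))
            assert mean_sqrt(published, sex, bmi, day) == pytest.approx(
                expected, abs=1e-12)

    def test_mean_sqrt_frozen_examples(self, published):
        assert mean_sqrt(published, "F", 20.0, 234) == pytest.approx(8.3154, abs=5e-4)
        assert mean_sqrt(published, "M", 25.0, 1) == pytest.approx(6.107, abs=1e-12)

    def test_zero_model_predicts_zero(self):
        zero = ModelCoefficients(beta=(0.0,) * 10, sigma_eps=1.0)
        assert mean_sqrt(zero, "F", 22.0, 50) == 0.0

    def test_median_is_squared_mean(self, published):
        for sex, bmi, day in [("F", 20.0, 234), ("M", 32.0, 10)]:
            assert centile(published, sex, bmi, day, 0.5) == pytest.approx(
                mean_sqrt(published, sex, bmi, day) ** 2, abs=1e-12)

    def test_centile_monotone_in_alpha(self, published):
        alphas = np.linspace(0.01, 0.99, 99)
        for sex, bmi, day in [("M", 20.0, 1), ("F", 39.0, 180), ("M", 40.0, 70)]:
            vals = [centile(published, sex, bmi, day, a) for a in alphas]
            assert np.all(np.diff(vals) >= 0)

    def test_centile_rejects_bad_alpha(self, published):
        for a in (0.0, 1.0, -0.1, 50.0):
            with pytest.raises(ValueError):
                centile(published, "F", 25.0, 1, a)

    def test_clamped_centile_warns_and_is_zero(self):
        low = ModelCoefficients(beta=(1.0,) + (0.0,) * 9, sigma_eps=2.0)
        with pytest.warns(RuntimeWarning):
            assert centile(low, "M", 25.0, 1, 0.01) == 0.0


class TestQuantileOf:
    def test_published_worked_example(self, published):
        q = quantile_of(published, "M", 25.0, 1, 60.0)
        assert round(q, 3) == 0.886

    def test_value_at_median(self, published):
        med = mean_sqrt(published, "F", 27.0, 120) ** 2
        assert quantile_of(published, "F", 27.0, 120, med) == pytest.approx(0.5)

    def test_rejects_negative_value(self, published):
        with pytest.raises(ValueError):
            quantile_of(published, "M", 25.0, 1, -1.0)

    @given(st.sampled_from(["M", "F"]),
           st.floats(min_value=18.0, max_value=40.0),
           st.integers(min_value=1, max_value=365),
           st.floats(min_value=0.05, max_value=0.95))
    def test_roundtrip_with_centile(self, published, sex, bmi, day, alpha):
        v = centile(published, sex, bmi, day, alpha)
        assert quantile_of(published, sex, bmi, day, v) == pytest.approx(
            alpha, abs=1e-9)

    def test_strictly_increasing_in_value(self, published):
        vals = np.linspace(5, 150, 60)
        qs = [quantile_of(published, "F", 24.0, 200, v) for v in vals]
        assert np.all(np.diff(qs) > 0)


class TestExtrema:
    def test_published_extrema_dates(self, published):
        assert extremum_days(published, "M") == (70, 234)   # Mar 11 / Aug 22
        assert extremum_days(published, "F") == (77, 234)   # Mar 18 / Aug 22

    @pytest.mark.parametrize("bmi", [18.0, 25.0, 40.0])
    def test_bmi_independent(self, published, bmi):
        assert extremum_days(published, "M", bmi) == (70, 234)

    def test_constant_profile_ties_to_day_one(self):
        flat = ModelCoefficients(
            beta=(5.0, 0, 0, 0, 0, -1.0, -2.0, 0, 0, 0), sigma_eps=1.0)
        assert extremum_days(flat, "M") == (1, 1)
        assert extremum_days(flat, "F") == (1, 1)


def test_amplitude_phase_reparametrisation(published):
    """sin/cos pair equals A*sin(theta + phi) with A,phi from beta1, beta2."""
    b = list(published.beta)
    amp = math.hypot(b[1], b[2])
    phase = math.atan2(b[2], b[1])
    for day in range(1, 366, 30):
        theta = 2 * math.pi * (day - 1) / 365
        direct = b[1] * math.sin(theta) + b[2] * math.cos(theta)
        assert amp * math.sin(theta + phase) == pytest.approx(direct, abs=1e-12)


def test_no_jump_at_bmi_25_for_males(published):
    below = mean_sqrt(published, "M", 25.0 - 1e-9, 150)
    at = mean_sqrt(published, "M", 25.0, 150)
    assert below == pytest.approx(at, abs=1e-6)


def test_model_coefficients_validation():
    with pytest.raises(ValueError):
        ModelCoefficients(beta=(0.0,) * 9, sigma_eps=1.0)
    with pytest.raises(ValueError):
        ModelCoefficients(beta=(0.0,) * 10, sigma_eps=0.0)
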