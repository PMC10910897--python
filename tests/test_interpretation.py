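"""Interval slopes, coefficient conversion, predictions and contrasts.

The numeric expectations here are the published worked-example values:
interval slopes obtained by cumulative summation, converted truncated-cubic
coefficients, and one-unit exposure contrasts, each matched after rounding
to the precision at which they were printed (4 decimals for slopes and
contrasts, 7 for the 1e-7-scale cubic coefficients).
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from splinereg import (
    FittedModel,
    KnotSet,
    check_tail_linearity,
    contrast,
    design_for,
    fit,
    lsp_interval_slopes,
    place_knots,
    predict,
    rcs_design,
    rcs_interval_coeffs,
    rcs_truncated_design,
)

from conftest import EXAMPLE_KNOTS


class TestLspIntervalSlopes:
    def test_one_knot_model_published_slopes(self, published_models):
        ic = lsp_interval_slopes(published_models["lsp_1knot"])
        assert [round(v, 4) for v in ic.values] == [-0.0810, -0.0178]
        assert ic.intervals == ((-np.inf, 330.0), (330.0, np.inf))

    def test_three_knot_model_published_slopes(self, published_models):
        ic = lsp_interval_slopes(published_models["lsp_3knot"])
        assert [round(v, 4) for v in ic.values] == [-0.0156, -0.0827, -0.0226, -0.0098]
        assert len(ic.intervals) == len(EXAMPLE_KNOTS) + 1

    def test_zero_spline_coefficients_reduce_to_single_slope(self, example_knots):
        model = FittedModel.from_coefficients(
            "lsp", (5.0, -0.4, 0.0, 0.0, 0.0), knots=example_knots
        )
        assert lsp_interval_slopes(model).values == (-0.4, -0.4, -0.4, -0.4)

    def test_family_mismatch_rejected(self, published_models):
        with pytest.raises(ValueError):
            lsp_interval_slopes(published_models["quadratic"])

    def test_slope_ci_from_fitted_covariance(self, study_dataset):
        x, y = study_dataset.exposure, study_dataset.outcome
        knots = place_knots(x, 3)
        model = fit(design_for("lsp", x, knots=knots), y)
        ic = lsp_interval_slopes(model, level=0.95)
        for (lo, hi), value in zip(ic.ci, ic.values):
            assert lo < value < hi


class TestRcsIntervalCoeffs:
    def test_published_conversion(self, example_knots):
        b2, b3, b4 = rcs_interval_coeffs(0.0740, example_knots)
        assert round(b2, 7) == 0.0000004
        assert round(b3, 7) == -0.0000006
        assert round(b4, 7) == 0.0000002

    def test_zero_coefficient_degenerates_to_linear(self, example_knots):
        assert rcs_interval_coeffs(0.0, example_knots) == (0.0, 0.0, 0.0)

    def test_wrong_knot_count_rejected(self):
        with pytest.raises(ValueError):
            rcs_interval_coeffs(1.0, KnotSet.from_values([1.0, 2.0]))


class TestCheckTailLinearity:
    def test_conversion_output_conforms(self, example_knots):
        coeffs = rcs_interval_coeffs(0.0740, example_knots)
        r1, r2 = check_tail_linearity(coeffs, example_knots)
        assert abs(r1) < 1e-18
        assert abs(r2) < 1e-15

    def test_perturbation_shows_in_first_residual(self, example_knots):
        b2, b3, b4 = rcs_interval_coeffs(0.0740, example_knots)
        delta = 1e-3
        r1, _ = check_tail_linearity((b2 + delta, b3, b4), example_knots)
        assert r1 == pytest.approx(delta)

    def test_published_rounded_values_conform_to_rounding(self, example_knots):
        r1, r2 = check_tail_linearity((4e-7, -6e-7, 2e-7), example_knots)
        assert abs(r1) < 5e-8  # within rounding of the 7-decimal table values
        assert abs(r2) < 5e-8 * 621.4


class TestPredict:
    def test_top_quartile_prediction_published(self, published_models):
        # all exposures above the upper quartile cut share one fitted value:
        # intercept + top-quartile coefficient = 60.1339 - 15.1727
        curve = predict(published_models["categorical"], [500.0, 800.0, 1100.0])
        np.testing.assert_allclose(curve.fit, 44.9612, atol=1e-10)

    def test_lsp_prediction_continuous_at_knots(self, published_models):
        model = published_models["lsp_3knot"]
        eps = 1e-9
        for k in EXAMPLE_KNOTS:
            left, right = predict(model, [k - eps, k + eps]).fit
            assert left == pytest.approx(right, abs=1e-6)

    def test_predictions_match_dot_product_oracle(self, study_dataset):
        x, y = study_dataset.exposure, study_dataset.outcome
        knots = place_knots(x, 3)
        model = fit(design_for("rcs", x, knots=knots), y)
        grid = np.linspace(x.min(), x.max(), 47)
        curve = predict(model, grid)
        rows = design_for("rcs", grid, knots=knots).matrix
        np.testing.assert_allclose(curve.fit, rows @ model.params, rtol=1e-12)
        assert np.all(curve.ci_low <= curve.fit)
        assert np.all(curve.fit <= curve.ci_high)

    def test_extrapolation_flagged_not_rejected(self, published_models):
        curve = predict(published_models["lsp_3knot"], [100.0, 400.0, 1500.0])
        assert curve.extrapolated.tolist() == [True, False, True]


class TestContrast:
    def test_quadratic_published_contrasts(self, published_models):
        model = published_models["quadratic"]
        assert round(contrast(model, 300, 301).difference, 4) == -0.0506
        assert round(contrast(model, 600, 601).difference, 4) == -0.0266

    def test_rcs_published_contrasts_via_rounded_interval_form(self, example_knots):
        # the published arithmetic plugs the 7-decimal-rounded converted
        # coefficients into the truncated-cubic interval form
        b = [round(v, 7) for v in rcs_interval_coeffs(0.0740, example_knots)]
        model = FittedModel.from_coefficients(
            "rcs_truncated", (75.9306, -0.0738, *b), knots=example_knots
        )
        assert round(contrast(model, 300, 301).decrease, 4) == 0.0644
        assert round(contrast(model, 600, 601).decrease, 4) == 0.0244

    def test_antisymmetry_and_zero_at_equal_points(self, published_models):
        for model in published_models.values():
            assert contrast(model, 350.0, 350.0).difference == 0.0
            fwd = contrast(model, 250.0, 480.0).difference
            rev = contrast(model, 480.0, 250.0).difference
            assert fwd == pytest.approx(-rev, rel=1e-12)

    def test_lsp_unit_contrast_equals_interval_slope(self, published_models):
        model = published_models["lsp_3knot"]
        slopes = lsp_interval_slopes(model).values
        # one-unit contrasts confined to each interval
        for (x0, x1), slope in zip(
            [(150, 151), (250, 251), (400, 401), (700, 701)], slopes
        ):
            assert contrast(model, x0, x1).difference == pytest.approx(slope, rel=1e-9)

    def test_contrast_ci_requires_covariance(self, published_models):
        with pytest.raises(ValueError):
            contrast(published_models["quadratic"], 300, 301, level=0.95)


# restricted basis (one normalised spline column) and the converted
# truncated-cubic interval form describe the same function
@settings(deadline=None, max_examples=75, derandomize=True)
@given(
    k1=st.floats(min_value=10.0, max_value=500.0),
    gap1=st.floats(min_value=5.0, max_value=500.0),
    gap2=st.floats(min_value=5.0, max_value=500.0),
    beta0=st.floats(min_value=-100.0, max_value=100.0),
    beta1=st.floats(min_value=-1.0, max_value=1.0),
    beta2=st.floats(min_value=-5.0, max_value=5.0),
)
def test_restricted_and_interval_forms_agree(k1, gap1, gap2, beta0, beta1, beta2):
    knots = KnotSet.from_values([k1, k1 + gap1, k1 + gap1 + gap2])
    grid = np.linspace(k1 - 50.0, k1 + gap1 + gap2 + 50.0, 400)
    restricted = rcs_design(grid, knots).matrix @ np.array([beta0, beta1, beta2])
    b2, b3, b4 = rcs_interval_coeffs(beta2, knots)
    interval = rcs_truncated_design(grid, knots).matrix @ np.array(
        [beta0, beta1, b2, b3, b4]
    )
    scale = np.max(np.abs(restricted)) + 1.0
    np.testing.assert_allclose(interval, restricted, rtol=0, atol=1e-10 * scale)
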