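"""Regression fit, published constants, predictions and intervals."""

import json
import math

import numpy as np
import pytest
from scipy import stats

from vpquant import (
    PUBLISHED_MODEL,
    LinearModelFit,
    fit_model,
    predict_pcr_norm,
    predict_pv_ratio,
    prediction_interval,
)
from vpquant.errors import (
    DegenerateDesignError,
    InsufficientDataError,
    OutOfDomainError,
)

SIGMA = math.sqrt(0.001089)


def _closed_form_ols(x, y):
    """Independent normal-equation solution for the oracle check."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    sxx = np.sum((x - x.mean()) ** 2)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - slope * x - intercept
    sse = np.sum(resid**2)
    sst = np.sum((y - y.mean()) ** 2)
    mse = sse / (n - 2)
    r2 = 1 - sse / sst
    adj_r2 = 1 - (1 - r2) * (n - 1) / (n - 2)
    f = (sst - sse) / mse
    return slope, intercept, mse, adj_r2, f


class TestFit:
    def test_noise_free_points_fit_exactly(self):
        x = np.linspace(1.2, 2.4, 10)
        fit = fit_model(list(zip(x, 0.28 * x - 0.198)))
        assert fit.slope == pytest.approx(0.28, abs=1e-12)
        assert fit.intercept == pytest.approx(-0.198, abs=1e-12)
        assert fit.mse == pytest.approx(0.0, abs=1e-24)

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_normal_equations_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 13)
        x = rng.uniform(0.5, 3.0, n)
        y = 0.3 * x - 0.2 + rng.normal(0, 0.05, n)
        fit = fit_model(list(zip(x, y)))
        slope, intercept, mse, adj_r2, f = _closed_form_ols(x, y)
        assert fit.slope == pytest.approx(slope, rel=1e-10)
        assert fit.intercept == pytest.approx(intercept, rel=1e-10)
        assert fit.mse == pytest.approx(mse, rel=1e-10)
        assert fit.adj_r2 == pytest.approx(adj_r2, rel=1e-8)
        assert fit.f_stat == pytest.approx(f, rel=1e-8)

    def test_line_passes_through_centroid(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(1, 3, 40)
        y = 0.3 * x + rng.normal(0, 0.1, 40)
        fit = fit_model(list(zip(x, y)))
        assert fit.slope * fit.x_mean + fit.intercept == pytest.approx(y.mean(), rel=1e-12)

    def test_parameter_recovery_bias_small(self):
        """Averaged over seeds at the training sample size, the fitted
        slope is unbiased to well under 2% of the true slope."""
        rng = np.random.default_rng(0)
        slopes = []
        for _ in range(50):
            x = rng.normal(1.83, 0.21, 342)
            y = 0.28 * x - 0.198 + rng.normal(0, SIGMA, 342)
            slopes.append(fit_model(np.column_stack([x, y])).slope)
        assert abs(np.mean(slopes) - 0.28) < 0.02 * 0.28

    def test_degenerate_and_insufficient_inputs(self):
        with pytest.raises(DegenerateDesignError):
            fit_model([(1.0, 0.1), (1.0, 0.2), (1.0, 0.3)])
        with pytest.raises(InsufficientDataError):
            fit_model([(1.0, 0.1), (2.0, 0.2)])


class TestPublishedModel:
    def test_constants(self):
        m = PUBLISHED_MODEL
        assert (m.slope, m.intercept, m.n, m.mse) == (0.28, -0.198, 342, 0.001089)
        assert m.x_mean == 1.83
        assert m.ss_x == pytest.approx(341 * 0.21**2)
        assert m.provenance.startswith("published")

    def test_point_prediction_matches_training_mean(self):
        # at the mean predictor the line reproduces the cohort mean
        assert predict_pcr_norm(PUBLISHED_MODEL, 1.83) == pytest.approx(0.3144)
        assert abs(predict_pcr_norm(PUBLISHED_MODEL, 1.83) - 0.313) < 0.005

    def test_point_prediction_validation_scale(self):
        assert predict_pcr_norm(PUBLISHED_MODEL, 1.80) == pytest.approx(0.306)

    def test_non_positive_prediction_rejected(self):
        with pytest.raises(OutOfDomainError):
            predict_pcr_norm(PUBLISHED_MODEL, 0.198 / 0.28)  # root of the line
        with pytest.raises(ValueError):
            predict_pcr_norm(PUBLISHED_MODEL, -1.0)

    def test_json_round_trip(self, tmp_path):
        path = tmp_path / "model.json"
        PUBLISHED_MODEL.to_json(path)
        loaded = LinearModelFit(**json.loads(path.read_text()))
        assert loaded == PUBLISHED_MODEL


class TestPredictionInterval:
    def test_half_width_at_training_mean(self):
        lower, upper = prediction_interval(PUBLISHED_MODEL, 1.83, 0.95)
        t_crit = stats.t.ppf(0.975, 340)
        expected = t_crit * math.sqrt(0.001089 * (1 + 1 / 342))
        assert (upper - lower) / 2 == pytest.approx(expected, rel=1e-12)
        assert (upper - lower) / 2 == pytest.approx(0.0650, abs=5e-4)

    def test_narrowest_at_predictor_mean_and_widens_outward(self):
        widths = []
        for x in (1.83, 1.9, 2.1, 2.5):
            lo, hi = prediction_interval(PUBLISHED_MODEL, x, 0.95)
            widths.append(hi - lo)
        assert widths == sorted(widths)
        assert widths[0] < widths[-1]

    def test_widens_with_smaller_n(self):
        small = LinearModelFit(
            slope=0.28, intercept=-0.198, n=20, mse=0.001089,
            x_mean=1.83, ss_x=19 * 0.21**2,
        )
        lo_s, hi_s = prediction_interval(small, 1.83, 0.95)
        lo_p, hi_p = prediction_interval(PUBLISHED_MODEL, 1.83, 0.95)
        assert hi_s - lo_s > hi_p - lo_p

    def test_coverage_close_to_nominal(self):
        """95% interval contains ~95% of fresh draws from the
        generative model (Monte-Carlo, 10,000 points)."""
        rng = np.random.default_rng(42)
        x = rng.normal(1.83, 0.21, 10_000)
        y = 0.28 * x - 0.198 + rng.normal(0, SIGMA, 10_000)
        lo, hi = prediction_interval(PUBLISHED_MODEL, x, 0.95)
        coverage = np.mean((y >= lo) & (y <= hi))
        assert coverage == pytest.approx(0.95, abs=0.015)

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            prediction_interval(PUBLISHED_MODEL, 1.83, 1.05)


class TestPVPrediction:
    VCR = 120 * 133 * 0.3144 / 3  # makes the worked example land on P/V = 3

    def test_forward_example(self):
        r = predict_pv_ratio(PUBLISHED_MODEL, 1.83, 120, 133, self.VCR, 0)
        assert r.pv_hat == pytest.approx(3.0, rel=1e-12)
        assert not r.extrapolation

    def test_delay_halves_denominator(self):
        from vpquant.count_measures import TC99M_HALF_LIFE_S

        r = predict_pv_ratio(
            PUBLISHED_MODEL, 1.83, 120, 133, self.VCR, TC99M_HALF_LIFE_S
        )
        assert r.pv_hat == pytest.approx(6.0, rel=1e-12)

    def test_bounds_are_monotone_transform_of_pcr_norm_bounds(self):
        r = predict_pv_ratio(PUBLISHED_MODEL, 1.83, 120, 133, self.VCR, 0)
        scale = 120 * 133 / self.VCR
        assert r.pv_lower == pytest.approx(r.lower * scale, rel=1e-12)
        assert r.pv_upper == pytest.approx(r.upper * scale, rel=1e-12)
        assert r.pv_lower < r.pv_hat < r.pv_upper

    def test_linear_in_dose(self):
        r1 = predict_pv_ratio(PUBLISHED_MODEL, 1.9, 100, 133, 2000, 0)
        r2 = predict_pv_ratio(PUBLISHED_MODEL, 1.9, 200, 133, 2000, 0)
        assert r2.pv_hat == pytest.approx(2 * r1.pv_hat, rel=1e-12)

    def test_extrapolation_flagged(self):
        r = predict_pv_ratio(PUBLISHED_MODEL, 2.9, 120, 133, 2000, 0)
        assert r.extrapolation
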