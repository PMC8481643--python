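import math

import numpy as np
import pytest
from scipy import stats as sps

from sorgspec import (
    cv_percent,
    evaluate_model,
    fit_pls,
    loocv_select,
    paired_t,
    r_squared,
    rate_model,
    rpd,
)


class TestRPDAndCV:
    @pytest.mark.parametrize("sd,rmse,expected", [(75.10, 24.94, 3.01), (13.86, 4.68, 2.96)])
    def test_rpd_reported_values(self, sd, rmse, expected):
        assert round(rpd(sd, rmse), 2) == expected

    def test_rpd_identity_and_error(self):
        assert rpd(3.7, 3.7) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            rpd(5.0, 0.0)

    @pytest.mark.parametrize(
        "mean,sd,expected", [(589.24, 98.25, 16.67), (136.50, 13.18, 9.66)]
    )
    def test_cv_percent_reported_values(self, mean, sd, expected):
        assert round(cv_percent(mean, sd), 2) == expected

    def test_cv_percent_edges(self):
        assert cv_percent(10.0, 0.0) == 0.0
        with pytest.raises(ValueError):
            cv_percent(0.0, 1.0)


class TestRating:
    @pytest.mark.parametrize(
        "r2,rpd_value,expected",
        [
            (0.97, 6.18, "efficient"),
            (0.72, 1.94, "preliminary"),
            (0.5, 1.0, "inadequate"),
            (0.92, 3.5, "successful"),
            (0.85, 2.5, "satisfactory"),
            (0.97, 3.5, "successful"),   # conservative: lower of the two tiers
            (0.75, 5.0, "preliminary"),
        ],
    )
    def test_tiers(self, r2, rpd_value, expected):
        assert rate_model(r2, rpd_value) == expected

    def test_input_validation(self):
        with pytest.raises(ValueError):
            rate_model(1.2, 3.0)
        with pytest.raises(ValueError):
            rate_model(0.9, 0.0)


class TestPairedT:
    def test_identical_vectors(self):
        t, df, p = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0 and df == 2

    def test_zero_mean_differences(self):
        m = np.array([1.0, 0.0, 1.0, 0.0])
        t, _, _ = paired_t(m, m - np.array([1.0, -1.0, 1.0, -1.0]))
        assert t == pytest.approx(0.0)

    def test_hand_computed_case(self):
        measured = np.array([1.0, 2.0, 3.0])
        t, df, p = paired_t(measured, measured - measured)  # differences {1,2,3}
        assert t == pytest.approx(2.0 * math.sqrt(3.0))
        assert df == 2
        assert p == pytest.approx(2 * sps.t.sf(2.0 * math.sqrt(3.0), 2))

    def test_constant_nonzero_differences(self):
        t, _, p = paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert math.isinf(t) and p == 0.0


class TestRSquared:
    def test_pearson_vs_explained(self, rng):
        y = rng.standard_normal(50)
        pred = y + 0.3 * rng.standard_normal(50)
        r2p = r_squared(y, pred)
        assert 0 < r2p <= 1
        # Pearson R^2 is invariant to affine miscalibration; explained is not
        assert r_squared(y, 2 * pred + 1) == pytest.approx(r2p)
        assert r_squared(y, 2 * pred + 1, method="explained") < r2p


class TestEvaluateModel:
    def _fitted(self, rng, noise=0.0):
        X = rng.standard_normal((24, 6))
        y = X[:, 0] - 0.5 * X[:, 2] + noise * rng.standard_normal(24)
        X_cal, y_cal, X_val, y_val = X[:18], y[:18], X[18:], y[18:]
        n_lv, _, cv_pred = loocv_select(X_cal, y_cal, 6)
        model = fit_pls(X_cal, y_cal, n_lv)
        return model, X_cal, y_cal, X_val, y_val, cv_pred[:, n_lv - 1]

    def test_perfect_predictions(self, rng):
        model, X_cal, y_cal, X_val, y_val, cv_pred = self._fitted(rng, noise=0.0)
        report = evaluate_model(model, X_cal, y_cal, X_val, y_val, cv_pred)
        assert report.r2_val == pytest.approx(1.0, abs=1e-9)
        assert report.rmse_val == pytest.approx(0.0, abs=1e-9)
        assert report.rating == "efficient"

    def test_internal_consistency(self, rng):
        model, X_cal, y_cal, X_val, y_val, cv_pred = self._fitted(rng, noise=0.4)
        report = evaluate_model(model, X_cal, y_cal, X_val, y_val, cv_pred)
        assert report.rpd_cv * report.rmse_cv == pytest.approx(report.sd_cal, rel=1e-9)
        assert report.rpd_val * report.rmse_val == pytest.approx(report.sd_val, rel=1e-9)
        assert 0 <= report.r2_val <= 1 and report.rmse_val >= 0
        assert report.rating == rate_model(report.r2_val, report.rpd_val)

    def test_small_validation_rejected(self, rng):
        model, X_cal, y_cal, X_val, y_val, cv_pred = self._fitted(rng, noise=0.1)
        with pytest.raises(ValueError):
            evaluate_model(model, X_cal, y_cal, X_val[:2], y_val[:2], cv_pred)
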