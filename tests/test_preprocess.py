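import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sorgspec import (
    MultiplicativeScatterCorrection,
    PreprocessRecipe,
    SavitzkyGolay,
    StandardNormalVariate,
    apply_recipe,
    msc,
    norris_derivative,
    savgol,
    snv,
)
from sorgspec.preprocess import PreprocessError


class TestMSC:
    def test_reference_row_unchanged(self, rng):
        ref = rng.standard_normal(40)
        X = np.vstack([ref, 2 * ref + 1])
        corrected, a, b, _ = msc(X, reference=ref, return_coef=True)
        np.testing.assert_allclose(corrected[0], ref, atol=1e-12)
        assert a[0] == pytest.approx(0.0, abs=1e-12)
        assert b[0] == pytest.approx(1.0, abs=1e-12)

    def test_affine_inversion(self, rng):
        ref = rng.standard_normal(40)
        corrected = msc(np.atleast_2d(2 * ref + 3), reference=ref)
        np.testing.assert_allclose(corrected[0], ref, atol=1e-10)

    def test_idempotent_with_fixed_reference(self, rng):
        X = rng.standard_normal((6, 50))
        ref = X.mean(axis=0)
        once = msc(X, reference=ref)
        twice = msc(once, reference=ref)
        np.testing.assert_allclose(twice, once, atol=1e-10)

    def test_zero_slope_raises_with_sample_named(self, rng):
        ref = np.linspace(0, 1, 30)
        X = np.vstack([ref, np.full(30, 2.0)])  # flat row has slope 0 on ref
        with pytest.raises(PreprocessError, match="sample index 1"):
            msc(X, reference=ref)

    def test_transformer_reuses_calibration_reference(self, rng):
        X_cal = rng.standard_normal((8, 30))
        X_val = rng.standard_normal((3, 30))
        est = MultiplicativeScatterCorrection().fit(X_cal)
        np.testing.assert_allclose(
            est.transform(X_val), msc(X_val, reference=X_cal.mean(axis=0))
        )


class TestSNV:
    def test_simple_row(self):
        np.testing.assert_allclose(snv([[1.0, 2.0, 3.0]]), [[-1.0, 0.0, 1.0]])

    @settings(deadline=None, derandomize=True)
    @given(
        scale=st.floats(0.1, 50), offset=st.floats(-100, 100),
        seed=st.integers(0, 100),
    )
    def test_affine_invariance(self, scale, offset, seed):
        row = np.random.default_rng(seed).standard_normal((1, 25))
        np.testing.assert_allclose(snv(scale * row + offset), snv(row), atol=1e-8)

    def test_normalization_contract(self, rng):
        out = snv(rng.standard_normal((10, 60)))
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1.0, rtol=1e-12)

    def test_constant_row_raises(self):
        with pytest.raises(PreprocessError, match="sample index 0"):
            snv(np.ones((1, 10)))


class TestSavitzkyGolay:
    def test_polynomial_reproduced_by_smoothing(self):
        j = np.arange(100, dtype=float)
        row = 2.0 + 0.5 * j - 0.01 * j**2
        out = savgol(row[None, :], window=11, polyorder=2, derivative_order=0)
        np.testing.assert_allclose(out[0], row, atol=1e-9)

    def test_second_derivative_of_quadratic(self):
        j = np.arange(50, dtype=float)
        out = savgol((j**2)[None, :], window=5, polyorder=2, derivative_order=2)
        np.testing.assert_allclose(out[0], 2.0, atol=1e-9)

    def test_first_derivative_of_ramp(self):
        j = np.arange(50, dtype=float)
        out = savgol((3.0 * j)[None, :], window=7, polyorder=2, derivative_order=1)
        np.testing.assert_allclose(out[0], 3.0, atol=1e-9)

    @pytest.mark.parametrize("deriv", [1, 2])
    def test_derivative_annihilates_lower_degree_polynomials(self, deriv):
        j = np.arange(80, dtype=float)
        row = sum(c * j**k for k, c in enumerate([4.0, -2.0][: deriv]))
        out = savgol(np.atleast_2d(row), window=9, polyorder=3, derivative_order=deriv)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    @pytest.mark.parametrize(
        "window,poly,deriv", [(10, 2, 0), (5, 5, 0), (5, 2, 3)]
    )
    def test_parameter_errors(self, window, poly, deriv):
        with pytest.raises(PreprocessError):
            savgol(np.zeros((1, 50)), window, poly, deriv)

    def test_transformer_matches_function(self, rng):
        X = rng.standard_normal((3, 70))
        est = SavitzkyGolay(window=11, polyorder=3, derivative_order=2).fit(X)
        np.testing.assert_array_equal(est.transform(X), savgol(X, 11, 3, 2))


def test_norris_derivative_of_ramp_interior():
    j = np.arange(60, dtype=float)
    out = norris_derivative((3.0 * j)[None, :], gap=5, segment=5, order=1)
    np.testing.assert_allclose(out[0, 10:-10], 3.0, atol=1e-9)


class TestRecipe:
    def test_parse_and_str_roundtrip(self):
        recipe = PreprocessRecipe.parse("MSC+SG51p2d2")
        assert recipe == PreprocessRecipe("MSC", 51, 2, 2)
        assert str(recipe) == "MSC+SG51p2d2"
        assert PreprocessRecipe.parse("SG51p2d0").scatter_correction == "none"

    @pytest.mark.parametrize("text", ["OSC+SG51p2d2", "MSC+SG50p2d2", "MSC", ""])
    def test_parse_rejects_invalid(self, text):
        with pytest.raises(PreprocessError):
            PreprocessRecipe.parse(text)

    def test_invalid_recipe_parameters(self):
        with pytest.raises(PreprocessError):
            PreprocessRecipe("MSC", 50, 2, 2)  # even window
        with pytest.raises(PreprocessError):
            PreprocessRecipe("MSC", 51, 1, 2)  # derivative > polyorder

    def test_state_reuse_applies_calibration_reference(self, rng):
        X_cal = 0.3 + 0.02 * rng.standard_normal((10, 80))
        X_val = 0.3 + 0.02 * rng.standard_normal((4, 80))
        recipe = PreprocessRecipe("MSC", 11, 2, 2)
        _, state = apply_recipe(X_cal, recipe)
        treated_val, _ = apply_recipe(X_val, recipe, fitted_state=state)
        manual = savgol(msc(X_val, reference=X_cal.mean(axis=0)), 11, 2, 2)
        np.testing.assert_allclose(treated_val, manual)

    def test_composition_equals_manual_chain(self, rng):
        X = 0.3 + 0.02 * rng.standard_normal((6, 80))
        treated, _ = apply_recipe(X, PreprocessRecipe("SNV", 11, 2, 1))
        np.testing.assert_allclose(treated, savgol(snv(X), 11, 2, 1))
        smoothed, _ = apply_recipe(X, PreprocessRecipe("none", 11, 2, 0))
        np.testing.assert_allclose(smoothed, savgol(X, 11, 2, 0))
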