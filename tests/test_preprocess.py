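import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from nirscal.errors import DegenerateInputError, WindowError
from nirscal.preprocess import (
    MSCReference,
    PreprocessSpec,
    apply_pipeline,
    default_spec_grid,
    detrend,
    fit_msc_reference,
    gap_segment_derivative,
    msc,
    snv,
)
from nirscal.spectra_io import WavelengthGrid

from conftest import make_set

finite_vectors = arrays(
    np.float64,
    st.integers(min_value=8, max_value=60),
    elements=st.floats(-5, 5, allow_nan=False, width=64),
)


class TestSNV:
    def test_three_point_example(self):
        np.testing.assert_allclose(snv([1, 2, 3]), [-1, 0, 1])

    @settings(deadline=None, max_examples=50)
    @given(finite_vectors)
    def test_output_standardised(self, x):
        if np.std(x, ddof=1) < 1e-6:
            return
        out = snv(x)
        assert abs(out.mean()) < 1e-10
        assert abs(out.std(ddof=1) - 1) < 1e-10

    @settings(deadline=None, max_examples=30)
    @given(finite_vectors)
    def test_idempotent_and_affine_invariant(self, x):
        if np.std(x, ddof=1) < 1e-6:
            return
        out = snv(x)
        np.testing.assert_allclose(snv(out), out, atol=1e-10)
        np.testing.assert_allclose(snv(5.0 + 3.0 * np.asarray(x)), out, atol=1e-9)

    def test_constant_spectrum_rejected(self):
        with pytest.raises(DegenerateInputError):
            snv(np.full(10, 2.0))


class TestDetrend:
    def test_quadratic_annihilated(self, small_grid):
        wl = small_grid.wavelengths()
        x = 3.0 - 0.002 * wl + 1e-6 * wl**2
        out = detrend(x, small_grid)
        assert np.max(np.abs(out)) < 1e-9

    def test_matches_vandermonde_least_squares(self, small_grid, rng):
        """Oracle: explicit normal-equations fit on the Vandermonde basis."""
        wl = small_grid.wavelengths()
        x = rng.normal(size=wl.size)
        V = np.vander((wl - wl.mean()) / wl.std(), 3, increasing=True)
        beta = np.linalg.solve(V.T @ V, V.T @ x)
        expected = x - V @ beta
        np.testing.assert_allclose(detrend(x, small_grid), expected, atol=1e-8)

    @settings(deadline=None, max_examples=30)
    @given(arrays(np.float64, 50, elements=st.floats(-2, 2, width=64)))
    def test_residuals_orthogonal_to_polynomial_basis(self, x):
        grid = WavelengthGrid(1100, 1198, 2)
        wl = grid.wavelengths()
        out = detrend(x, grid)
        w = (wl - wl.mean()) / wl.std()
        for k in range(3):
            assert abs(out @ w**k) < 1e-6

    def test_excessive_degree_rejected(self):
        grid = WavelengthGrid(1100, 1106, 2)
        with pytest.raises(DegenerateInputError):
            detrend(np.arange(4.0), grid, degree=3)


class TestMSC:
    def test_reference_spectrum_unchanged(self, small_grid, rng):
        ref_vec = rng.uniform(0.2, 0.8, size=small_grid.n_points)
        s = make_set(small_grid, ref_vec[None, :])
        out = msc(s, MSCReference(ref_vec))
        np.testing.assert_allclose(out.spectra[0].absorbance, ref_vec, atol=1e-10)

    def test_exact_affine_model_inverted(self, small_grid, rng):
        ref_vec = rng.uniform(0.2, 0.8, size=small_grid.n_points)
        s = make_set(small_grid, (0.3 + 1.7 * ref_vec)[None, :])
        out = msc(s, MSCReference(ref_vec))
        np.testing.assert_allclose(out.spectra[0].absorbance, ref_vec, atol=1e-10)

    def test_corrected_spectra_have_unit_fit_against_reference(self, small_grid, rng):
        """Oracle: refitting (a, b) on corrected spectra must give (0, 1)."""
        ref_vec = rng.uniform(0.2, 0.8, size=small_grid.n_points)
        X = (
            rng.uniform(0.5, 2.0, size=(6, 1)) * ref_vec
            + rng.uniform(-0.3, 0.3, size=(6, 1))
            + rng.normal(0, 0.01, size=(6, small_grid.n_points))
        )
        out = msc(make_set(small_grid, X), MSCReference(ref_vec))
        ref_c = ref_vec - ref_vec.mean()
        for s in out.spectra:
            x = s.absorbance
            b = float(ref_c @ (x - x.mean())) / float(ref_c @ ref_c)
            a = float(x.mean() - b * ref_vec.mean())
            assert abs(b - 1.0) < 1e-9
            assert abs(a) < 1e-9


class TestGapSegmentDerivative:
    def test_first_derivative_of_ramp_is_slope_times_gap(self):
        m = 0.37
        x = m * np.arange(60.0)
        for gap in (2, 3, 4, 5):
            spec = PreprocessSpec("none", 1, gap, 1, 1)
            out, _ = gap_segment_derivative(x, spec)
            np.testing.assert_allclose(out, m * gap, atol=1e-10)

    def test_order_zero_no_smoothing_is_identity(self, rng):
        x = rng.normal(size=40)
        out, _ = gap_segment_derivative(x, PreprocessSpec("none", 0, 1, 1, 1))
        np.testing.assert_array_equal(out, x)

    def test_matches_bruteforce_loop_oracle(self, rng):
        """Oracle: two explicit boxcar loops and two even-gap differences."""
        x = rng.normal(size=80)
        spec = PreprocessSpec("none", 2, 4, 4, 1)

        def boxcar_loop(v, m):
            return np.array(
                [np.mean(v[i:i + m]) for i in range(len(v) - m + 1)]
            )

        def gap_loop(v, g):  # even g
            h = g // 2
            return np.array(
                [v[i + h] - v[i - h] for i in range(h, len(v) - h)]
            )

        expected = gap_loop(gap_loop(boxcar_loop(boxcar_loop(x, 4), 1), 4), 4)
        out, _ = gap_segment_derivative(x, spec)
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_odd_gap_matches_interpolated_loop_oracle(self, rng):
        x = rng.normal(size=50)
        spec = PreprocessSpec("none", 1, 5, 1, 1)
        h = 2
        expected = np.array(
            [
                0.5 * (x[i + h] + x[i + h + 1]) - 0.5 * (x[i - h - 1] + x[i - h])
                for i in range(h + 1, len(x) - h - 1)
            ]
        )
        out, _ = gap_segment_derivative(x, spec)
        np.testing.assert_allclose(out, expected, atol=1e-10)

    @settings(deadline=None, max_examples=25)
    @given(
        arrays(np.float64, 60, elements=st.floats(-3, 3, width=64)),
        arrays(np.float64, 60, elements=st.floats(-3, 3, width=64)),
    )
    def test_linearity(self, x, y):
        spec = PreprocessSpec("none", 1, 4, 4, 1)
        a, b = 1.7, -0.6
        lhs, _ = gap_segment_derivative(a * x + b * y, spec)
        tx, _ = gap_segment_derivative(x, spec)
        ty, _ = gap_segment_derivative(y, spec)
        np.testing.assert_allclose(lhs, a * tx + b * ty, atol=1e-9)

    def test_trimmed_axis_tracks_convolution_support(self, small_grid, rng):
        x = rng.normal(size=small_grid.n_points)
        spec = PreprocessSpec("none", 1, 4, 4, 1)
        out, wl = gap_segment_derivative(x, spec, small_grid)
        assert out.size == wl.size == small_grid.n_points - 3 - 4
        # gap difference preserves window centres
        assert wl[0] == pytest.approx(small_grid.wavelengths()[:4].mean() + 4)

    def test_short_spectrum_rejected(self):
        with pytest.raises(WindowError):
            gap_segment_derivative(np.arange(5.0), PreprocessSpec("none", 1, 4, 4, 1))


class TestApplyPipeline:
    def test_identity_pipeline(self, small_grid, rng):
        X = rng.uniform(size=(4, small_grid.n_points))
        s = make_set(small_grid, X)
        out, wl, ref = apply_pipeline(s, PreprocessSpec("none", 0, 1, 1, 1))
        np.testing.assert_array_equal(out, X)
        assert ref is None

    def test_default_grid_has_eight_distinct_specs(self):
        specs = default_spec_grid()
        assert len(specs) == 8
        assert len(set(specs)) == 8

    def test_msc_reference_reused_not_refit(self, small_grid, rng):
        """Perturbing validation spectra must leave the stored reference,
        and hence the calibration-set output, unchanged."""
        Xc = rng.uniform(0.2, 0.8, size=(6, small_grid.n_points))
        cal = make_set(small_grid, Xc)
        spec = PreprocessSpec("MSC", 1, 4, 4, 1)
        out_cal, _, ref = apply_pipeline(cal, spec)
        np.testing.assert_array_equal(
            ref.reference_spectrum, fit_msc_reference(cal).reference_spectrum
        )
        Xv = rng.uniform(0.2, 0.8, size=(3, small_grid.n_points))
        val = make_set(small_grid, Xv)
        out_val1, _, ref1 = apply_pipeline(val, spec, msc_reference=ref)
        # mutate validation data; stored reference must not move
        val_perturbed = make_set(small_grid, Xv + 0.5)
        _, _, ref2 = apply_pipeline(val_perturbed, spec, msc_reference=ref)
        np.testing.assert_array_equal(ref1.reference_spectrum,
                                      ref2.reference_spectrum)
        out_cal2, _, _ = apply_pipeline(cal, spec, msc_reference=ref)
        np.testing.assert_array_equal(out_cal, out_cal2)

    def test_snv_dt_applies_snv_then_detrend(self, small_grid, rng):
        x = rng.uniform(0.2, 0.8, size=small_grid.n_points)
        s = make_set(small_grid, x[None, :])
        out, _, _ = apply_pipeline(s, PreprocessSpec("SNV_DT", 0, 1, 1, 1))
        expected = detrend(snv(x), small_grid)
        np.testing.assert_allclose(out[0], expected, atol=1e-10)
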