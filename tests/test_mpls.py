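import numpy as np
import pytest

from nirscal.errors import (
    DegenerateInputError,
    GridMismatchError,
    RankError,
)
from nirscal.mpls import (
    calibrate,
    cross_validate,
    detect_outliers,
    fit_model,
    fit_pls1,
    predict,
)
from nirscal.preprocess import PreprocessSpec, default_spec_grid
from nirscal.spectra_io import WavelengthGrid

from conftest import make_set

IDENTITY = PreprocessSpec("none", 0, 1, 1, 1)


class TestFitPLS1:
    def test_single_informative_wavelength_needs_one_factor(self, rng):
        # uninformative columns are made sample-orthogonal to the signal
        # column so the first weight vector is exactly that column
        X = rng.normal(size=(20, 6))
        Xc = X - X.mean(axis=0)
        sig = Xc[:, 3]
        for j in range(6):
            if j != 3:
                X[:, j] -= (sig @ Xc[:, j]) / (sig @ sig) * sig
        y = 2.0 + 3.0 * X[:, 3]
        fit = fit_pls1(X, y, n_factors=1)
        sec = np.sqrt(np.mean((fit.predict_factors(X)[:, 0] - y) ** 2))
        assert sec < 1e-8

    @pytest.mark.parametrize("modified", [True, False])
    def test_full_rank_equals_least_squares_oracle(self, rng, modified):
        """At n_factors = rank, PLS predictions equal the OLS fit."""
        X = rng.normal(size=(8, 6))
        y = rng.normal(size=8)
        fit = fit_pls1(X, y, n_factors=6, modified=modified)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
        expected = y.mean() + Xc @ beta
        got = fit.predict_factors(X)[:, -1]
        np.testing.assert_allclose(got, expected, atol=1e-8)

    def test_coefficient_vector_matches_recursion(self, rng):
        """Folding the per-factor scalings into one vector must reproduce
        the sequential-deflation predictions."""
        X = rng.normal(size=(30, 15))
        y = rng.normal(size=30)
        fit = fit_pls1(X, y, n_factors=5, modified=True)
        Xnew = rng.normal(size=(7, 15))
        via_recursion = fit.predict_factors(Xnew)
        for k in range(1, 6):
            b = fit.coefficients(k)
            via_coef = y.mean() + (Xnew - fit.x_mean) @ b
            np.testing.assert_allclose(via_coef, via_recursion[:, k - 1],
                                       atol=1e-8)

    def test_modified_close_to_plain_on_homoscedastic_columns(self, rng):
        """With equal column variances the residual standardisation is
        nearly a no-op: coefficient cosine similarity > 0.99."""
        X = rng.normal(size=(60, 10))
        beta = rng.normal(size=10)
        y = X @ beta + rng.normal(0, 0.1, size=60)
        b_mod = fit_pls1(X, y, 4, modified=True).coefficients()
        b_plain = fit_pls1(X, y, 4, modified=False).coefficients()
        cos = b_mod @ b_plain / (np.linalg.norm(b_mod) * np.linalg.norm(b_plain))
        assert cos > 0.99

    def test_plain_pls1_matches_sklearn(self, rng):
        """Independent cross-check of the unmodified path against
        scikit-learn's PLS regression."""
        from sklearn.cross_decomposition import PLSRegression

        X = rng.normal(size=(40, 20))
        y = X @ rng.normal(size=20) + rng.normal(0, 0.5, size=40)
        for k in (1, 3, 5):
            ours = fit_pls1(X, y, k, modified=False)
            ref = PLSRegression(n_components=k, scale=False).fit(X, y)
            np.testing.assert_allclose(
                ours.predict_factors(X)[:, -1],
                ref.predict(X).ravel(),
                atol=1e-8,
            )

    def test_rank_exceeded_raises(self, rng):
        X = np.tile(rng.normal(size=(1, 4)), (6, 1))  # rank 0 after centring
        y = rng.normal(size=6)
        with pytest.raises(RankError):
            fit_pls1(X, y, n_factors=2)

    def test_constant_target_rejected(self, rng):
        with pytest.raises(DegenerateInputError):
            fit_pls1(rng.normal(size=(10, 4)), np.full(10, 2.0), 1)


class TestCrossValidate:
    def test_noise_free_linear_data_chooses_one_factor(self, linear_fn_set):
        cv = cross_validate(linear_fn_set, IDENTITY, max_factors=5,
                            n_groups=4, seed=0)
        assert cv.chosen_factors == 1
        assert cv.secv_by_factors[0] < 1e-6

    def test_same_seed_same_groups_and_secv(self, linear_fn_set):
        a = cross_validate(linear_fn_set, IDENTITY, max_factors=3, seed=11)
        b = cross_validate(linear_fn_set, IDENTITY, max_factors=3, seed=11)
        assert a.groups == b.groups
        np.testing.assert_array_equal(a.secv_by_factors, b.secv_by_factors)

    def test_heldout_bookkeeping_covers_every_sample_once(self, linear_fn_set):
        cv = cross_validate(linear_fn_set, IDENTITY, max_factors=3,
                            n_groups=4, seed=2)
        assert sorted(cv.groups) == sorted(linear_fn_set.sample_ids)
        counts = np.bincount(list(cv.groups.values()), minlength=4)
        assert counts.sum() == len(linear_fn_set)
        assert counts.min() >= 1
        assert set(cv.heldout_predictions) == set(linear_fn_set.sample_ids)

    def test_secv_uses_only_heldout_predictions(self, small_grid, rng):
        """Training-set leakage would give SECV near zero on pure-noise
        targets; held-out SECV must stay at the noise scale."""
        X = rng.normal(size=(30, small_grid.n_points))
        fn = rng.uniform(1, 3, size=30)  # independent of X
        s = make_set(small_grid, X, fn=fn)
        cv = cross_validate(s, IDENTITY, max_factors=4, n_groups=5, seed=0)
        assert cv.secv > 0.5 * np.std(fn)


class TestDetectOutliers:
    def test_clean_data_keeps_everything(self, linear_fn_set):
        rep = detect_outliers(linear_fn_set, IDENTITY, max_factors=3, seed=0)
        assert rep.eliminated_ids == []

    def test_planted_outlier_is_eliminated(self, small_grid, rng):
        wl = small_grid.wavelengths()
        band = np.exp(-((wl - 1150.0) ** 2) / (2 * 12.0**2))
        n = 40
        fn = rng.uniform(1, 3, size=n)
        X = 0.3 + np.outer(0.1 * fn, band) + rng.normal(0, 1e-4, (n, wl.size))
        fn_obs = fn.copy()
        fn_obs[17] += 10 * fn.std()  # reference value shifted far off
        s = make_set(small_grid, X, fn=fn_obs)
        rep = detect_outliers(s, IDENTITY, max_factors=3, seed=1, max_passes=1)
        assert rep.eliminated_ids == ["s17"]

    def test_zero_passes_means_no_eliminations(self, linear_fn_set):
        rep = detect_outliers(linear_fn_set, IDENTITY, max_passes=0, seed=0)
        assert rep.passes == 0
        assert rep.eliminated_ids == []


class TestCalibrate:
    def test_single_candidate_is_best(self, linear_fn_set):
        results = calibrate(linear_fn_set, [IDENTITY], max_factors=3, seed=0)
        assert len(results) == 1
        assert results[0].spec == IDENTITY

    def test_results_ranked_by_secv(self, linear_fn_set):
        specs = [IDENTITY, PreprocessSpec("SNV", 1, 4, 4, 1)]
        results = calibrate(linear_fn_set, specs, max_factors=3, seed=0)
        secvs = [r.cv_report.secv for r in results]
        assert secvs == sorted(secvs)
        assert secvs[0] <= min(secvs)

    def test_eight_spec_grid_returns_eight_reports(self, small_grid, rng):
        wl = small_grid.wavelengths()
        band = np.exp(-((wl - 1150.0) ** 2) / (2 * 10.0**2))
        n = 30
        fn = rng.uniform(1, 3, size=n)
        X = (0.3 + 0.1 * (wl - wl[0]) / 1000.0 + np.outer(0.1 * fn, band)
             + rng.normal(0, 1e-3, (n, wl.size)))
        s = make_set(small_grid, X, fn=fn)
        results = calibrate(s, default_spec_grid(), max_factors=4, seed=0)
        assert len(results) == 8
        assert len({r.spec for r in results}) == 8


class TestPredict:
    def test_training_set_reproduces_fitted_values(self, linear_fn_set):
        model = fit_model(linear_fn_set, IDENTITY, n_factors=1)
        yhat = predict(model, linear_fn_set)
        np.testing.assert_allclose(yhat, linear_fn_set.fn_vector(), atol=1e-8)

    def test_perturbing_one_spectrum_changes_only_that_prediction(
        self, linear_fn_set, small_grid
    ):
        model = fit_model(linear_fn_set, IDENTITY, n_factors=1)
        base = predict(model, linear_fn_set)
        X = linear_fn_set.absorbance_matrix().copy()
        X[3] += 0.05
        perturbed = make_set(small_grid, X, fn=linear_fn_set.fn_vector())
        got = predict(model, perturbed)
        np.testing.assert_allclose(np.delete(got, 3), np.delete(base, 3),
                                   atol=1e-10)
        assert abs(got[3] - base[3]) > 1e-6

    def test_grid_mismatch_rejected(self, linear_fn_set, rng):
        model = fit_model(linear_fn_set, IDENTITY, n_factors=1)
        other_grid = WavelengthGrid(1100, 1148, 2)  # 25 points
        short = make_set(other_grid, rng.uniform(size=(2, 25)))
        with pytest.raises(GridMismatchError):
            predict(model, short)

    def test_duplicating_a_sample_never_increases_sec(self, linear_fn_set,
                                                      small_grid, rng):
        from nirscal.valstats import sep

        X = linear_fn_set.absorbance_matrix()
        fn = linear_fn_set.fn_vector()
        noisy = X + rng.normal(0, 1e-3, X.shape)
        s = make_set(small_grid, noisy, fn=fn)
        model = fit_model(s, IDENTITY, n_factors=2)
        rmse = np.sqrt(np.mean((predict(model, s) - fn) ** 2))

        X_dup = np.vstack([noisy, noisy[0]])
        fn_dup = np.append(fn, fn[0])
        s_dup = make_set(small_grid, X_dup, fn=fn_dup)
        model_dup = fit_model(s_dup, IDENTITY, n_factors=2)
        rmse_dup = np.sqrt(
            np.mean((predict(model_dup, s_dup)[:-1] - fn) ** 2)
        )
        assert rmse_dup <= rmse + 1e-6
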