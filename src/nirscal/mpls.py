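"""Modified partial least squares (MPLS) calibration.

PLS1 via NIPALS, with the Shenk-Westerhaus modification: after each
latent factor is extracted, the columns of the X residual matrix are
standardised (divided by their sample standard deviation) before the next
factor is computed. The per-factor scalings are folded back into a single
regression vector over wavelengths, so a fitted model predicts with one
dot product.

Factor count is chosen by grouped cross-validation on the standard error
of cross-validation (SECV), and calibration outliers are eliminated
iteratively from the held-out residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateInputError,
    GridMismatchError,
    OutlierRunawayError,
    RankError,
    SplitError,
)
from .preprocess import MSCReference, PreprocessSpec, apply_pipeline
from .spectra_io import SpectraSet

_EPS = 1e-12


@dataclass
class PLSFit:
    """Raw NIPALS state: per-factor weights/loadings plus centring."""

    x_mean: np.ndarray
    y_mean: float
    weights: list[np.ndarray]          # w_k, unit norm
    x_loadings: list[np.ndarray]       # p_k
    y_loadings: list[float]            # q_k
    residual_scales: list[np.ndarray]  # s_k (all ones when not modified)
    modified: bool

    @property
    def n_factors(self) -> int:
        return len(self.weights)

    def coefficients(self, n_factors: int | None = None) -> np.ndarray:
        """Regression vector b with ŷ = y_mean + (x - x_mean) · b.

        Folds the per-factor residual scalings into the vector by
        propagating the deflation operators.
        """
        k_max = self.n_factors if n_factors is None else n_factors
        p = self.x_mean.size
        b = np.zeros(p)
        chain = np.eye(p)
        for k in range(k_max):
            v = chain.T @ self.weights[k]
            b += self.y_loadings[k] * v
            if k + 1 < k_max:
                chain = (chain - np.outer(self.x_loadings[k],
                                          self.weights[k] @ chain))
                chain /= self.residual_scales[k][:, None]
        return b

    def predict_factors(self, X: np.ndarray) -> np.ndarray:
        """Predictions at every cumulative factor count.

        Returns an (n_samples, n_factors) matrix whose column f-1 is the
        prediction using the first f factors, computed by running the
        deflation recursion on the new spectra.
        """
        Xc = np.asarray(X, float) - self.x_mean
        n = Xc.shape[0]
        preds = np.empty((n, self.n_factors))
        yhat = np.full(n, self.y_mean)
        for k in range(self.n_factors):
            t = Xc @ self.weights[k]
            yhat = yhat + self.y_loadings[k] * t
            preds[:, k] = yhat
            Xc = (Xc - np.outer(t, self.x_loadings[k])) / self.residual_scales[k]
        return preds


def fit_pls1(
    X: np.ndarray,
    y: np.ndarray,
    n_factors: int,
    modified: bool = True,
    allow_early_stop: bool = False,
) -> PLSFit:
    """Fit a PLS1 model with NIPALS.

    Parameters
    ----------
    X, y : training spectra matrix and reference values; centring is
        handled internally.
    n_factors : latent factors to extract.
    modified : apply the per-factor residual standardisation.
    allow_early_stop : stop quietly when the residuals are exhausted
        (rank reached) instead of raising a rank error.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
        raise ValueError("X must be (n, p) and y length n")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("missing or non-finite values in X or y")
    if n_factors < 1:
        raise ValueError("n_factors must be >= 1")
    if y.std() < _EPS:
        raise DegenerateInputError("reference values have zero variance")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xr = X - x_mean
    yr = y - y_mean

    fit = PLSFit(x_mean=x_mean, y_mean=y_mean, weights=[], x_loadings=[],
                 y_loadings=[], residual_scales=[], modified=modified)
    for _ in range(n_factors):
        w = Xr.T @ yr
        wn = np.linalg.norm(w)
        if wn < 1e-10:
            if allow_early_stop:
                break
            raise RankError(
                f"requested {n_factors} factors but residuals are exhausted "
                f"after {fit.n_factors}"
            )
        w = w / wn
        t = Xr @ w
        tt = float(t @ t)
        if tt < _EPS:
            if allow_early_stop:
                break
            raise RankError("degenerate score vector; rank exceeded")
        p_load = (Xr.T @ t) / tt
        q = float(t @ yr) / tt
        Xr = Xr - np.outer(t, p_load)
        yr = yr - q * t
        if modified:
            s = Xr.std(axis=0, ddof=1) if Xr.shape[0] > 1 else np.ones(Xr.shape[1])
            s = np.where(s < _EPS, 1.0, s)
            Xr = Xr / s
        else:
            s = np.ones(Xr.shape[1])
        fit.weights.append(w)
        fit.x_loadings.append(p_load)
        fit.y_loadings.append(q)
        fit.residual_scales.append(s)
    return fit


@dataclass
class MPLSModel:
    """A fitted calibration: preprocessing + centred linear predictor."""

    preprocess: PreprocessSpec
    msc_reference: MSCReference | None
    wavelengths: np.ndarray          # trimmed axis the coefficients live on
    x_center: np.ndarray
    x_scale: np.ndarray
    y_center: float
    n_factors: int
    coefficients: np.ndarray
    pls_fit: PLSFit
    training_ids: list[str]
    modified: bool = True

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, float) - self.x_center) / self.x_scale
        return Xs @ self.coefficients + self.y_center


@dataclass
class CrossValReport:
    """SECV per candidate factor count and the chosen model size."""

    secv_by_factors: np.ndarray
    chosen_factors: int
    r2_cv: float
    groups: dict[str, int]
    heldout_predictions: dict[str, float] = field(default_factory=dict)

    @property
    def secv(self) -> float:
        return float(self.secv_by_factors[self.chosen_factors - 1])


@dataclass
class OutlierReport:
    eliminated_ids: list[str]
    t_statistics: dict[str, float]
    passes: int


def _default_max_factors(n_samples: int) -> int:
    return max(1, min(16, n_samples // 3))


def _fit_preprocessed(cal: SpectraSet, spec: PreprocessSpec, max_factors: int,
                      modified: bool = True):
    """Preprocess a calibration set and fit PLS on it."""
    X, wl, ref = apply_pipeline(cal, spec)
    y = cal.fn_vector()
    k = min(max_factors, X.shape[0] - 1, X.shape[1])
    fit = fit_pls1(X, y, k, modified=modified, allow_early_stop=True)
    return X, wl, ref, fit


def cross_validate(
    cal: SpectraSet,
    spec: PreprocessSpec,
    max_factors: int | None = None,
    n_groups: int = 5,
    seed: int = 0,
    selection: str = "parsimonious",
    modified: bool = True,
) -> CrossValReport:
    """Grouped ("leave-n-out") cross-validation of an MPLS calibration.

    Samples are partitioned into ``n_groups`` random groups (seeded). Each
    group is predicted by a model fitted on the remaining groups — the MSC
    reference, centring and factors are all refitted without the held-out
    group. SECV(f) pools held-out squared errors at every factor count f;
    the chosen count is the smallest f whose SECV is within 2% of the
    minimum (``selection="argmin"`` disables the parsimony guard).
    """
    if n_groups < 2:
        raise SplitError("cross-validation needs at least 2 groups")
    ids = cal.sample_ids
    n = len(ids)
    if n < n_groups:
        raise SplitError(f"{n} samples cannot form {n_groups} groups")
    y_all = cal.fn_vector()
    if np.any(np.isnan(y_all)):
        raise SplitError("all calibration samples need a reference FN value")
    if max_factors is None:
        max_factors = _default_max_factors(n)

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    group_of = np.empty(n, dtype=int)
    for rank, idx in enumerate(perm):
        group_of[idx] = rank % n_groups

    preds = np.full((n, max_factors), np.nan)
    for g in range(n_groups):
        test_mask = group_of == g
        train = cal.subset([ids[i] for i in np.flatnonzero(~test_mask)])
        test = cal.subset([ids[i] for i in np.flatnonzero(test_mask)])
        X_tr, wl, ref, fit = _fit_preprocessed(train, spec, max_factors, modified)
        X_te, _, _ = apply_pipeline(test, spec, msc_reference=ref)
        p = fit.predict_factors(X_te)
        # factor counts beyond the attainable rank keep the last prediction
        if p.shape[1] < max_factors:
            p = np.hstack([p, np.repeat(p[:, -1:], max_factors - p.shape[1], axis=1)])
        preds[test_mask] = p

    errs = preds - y_all[:, None]
    secv = np.sqrt(np.mean(errs**2, axis=0))
    f_min = int(np.argmin(secv))
    if selection == "argmin":
        chosen = f_min + 1
    else:
        threshold = 1.02 * secv[f_min]
        chosen = int(np.flatnonzero(secv <= threshold)[0]) + 1

    yhat = preds[:, chosen - 1]
    r = np.corrcoef(yhat, y_all)[0, 1]
    return CrossValReport(
        secv_by_factors=secv,
        chosen_factors=chosen,
        r2_cv=float(r**2),
        groups={ids[i]: int(group_of[i]) for i in range(n)},
        heldout_predictions={ids[i]: float(yhat[i]) for i in range(n)},
    )


def detect_outliers(
    cal: SpectraSet,
    spec: PreprocessSpec,
    t_crit: float = 2.5,
    max_passes: int = 2,
    max_factors: int | None = None,
    n_groups: int = 5,
    seed: int = 0,
    modified: bool = True,
) -> OutlierReport:
    """Iterative elimination of calibration samples with large CV residuals.

    Each pass cross-validates, standardises the held-out residuals by the
    SECV (T statistic), and removes samples with T above ``t_crit``. Stops
    after ``max_passes`` passes or when nothing is removed. Aborts if more
    than 25% of the original samples would be discarded.
    """
    if t_crit <= 0:
        raise ValueError("t_crit must be positive")
    n_original = len(cal)
    working = cal
    eliminated: list[str] = []
    t_stats: dict[str, float] = {}
    passes = 0
    for _ in range(max_passes):
        cv = cross_validate(working, spec, max_factors=max_factors,
                            n_groups=n_groups, seed=seed, modified=modified)
        y = working.fn_vector()
        ids = working.sample_ids
        secv = cv.secv
        if secv < _EPS:
            break
        t_now = {
            sid: abs(cv.heldout_predictions[sid] - y[i]) / secv
            for i, sid in enumerate(ids)
        }
        t_stats.update(t_now)
        drop = [sid for sid, t in t_now.items() if t > t_crit]
        passes += 1
        if not drop:
            break
        if len(eliminated) + len(drop) > 0.25 * n_original:
            raise OutlierRunawayError(
                f"eliminating {len(eliminated) + len(drop)} of {n_original} "
                "samples exceeds the 25% guard"
            )
        eliminated.extend(drop)
        working = working.subset([sid for sid in ids if sid not in set(drop)])
    return OutlierReport(eliminated_ids=eliminated, t_statistics=t_stats,
                         passes=passes)


@dataclass
class CalibrationResult:
    spec: PreprocessSpec
    model: MPLSModel
    cv_report: CrossValReport
    outlier_report: OutlierReport


def fit_model(
    cal: SpectraSet,
    spec: PreprocessSpec,
    n_factors: int,
    modified: bool = True,
) -> MPLSModel:
    """Fit a final MPLS calibration at a fixed factor count."""
    X, wl, ref, fit = _fit_preprocessed(cal, spec, n_factors, modified)
    k = fit.n_factors
    return MPLSModel(
        preprocess=spec,
        msc_reference=ref,
        wavelengths=wl,
        x_center=fit.x_mean,
        x_scale=np.ones_like(fit.x_mean),
        y_center=fit.y_mean,
        n_factors=k,
        coefficients=fit.coefficients(k),
        pls_fit=fit,
        training_ids=list(cal.sample_ids),
        modified=modified,
    )


def calibrate(
    cal: SpectraSet,
    candidate_specs: list[PreprocessSpec],
    max_factors: int | None = None,
    n_groups: int = 5,
    seed: int = 0,
    t_crit: float = 2.5,
    max_passes: int = 2,
    modified: bool = True,
) -> list[CalibrationResult]:
    """Run the full calibration loop for every candidate treatment.

    For each preprocessing spec: outlier elimination (CV-driven), a final
    cross-validation on the cleaned samples, and a final model fit at the
    chosen factor count. Results are ranked by SECV, best first.
    """
    if not candidate_specs:
        raise ValueError("need at least one candidate preprocessing spec")
    results = []
    for spec in candidate_specs:
        outliers = detect_outliers(cal, spec, t_crit=t_crit,
                                   max_passes=max_passes,
                                   max_factors=max_factors,
                                   n_groups=n_groups, seed=seed,
                                   modified=modified)
        cleaned = cal.subset(
            [sid for sid in cal.sample_ids
             if sid not in set(outliers.eliminated_ids)]
        )
        cv = cross_validate(cleaned, spec, max_factors=max_factors,
                            n_groups=n_groups, seed=seed, modified=modified)
        model = fit_model(cleaned, spec, cv.chosen_factors, modified=modified)
        results.append(CalibrationResult(spec, model, cv, outliers))
    results.sort(key=lambda r: r.cv_report.secv)
    return results


def predict(model: MPLSModel, spectra_set: SpectraSet) -> np.ndarray:
    """Predict FN (% DM) for every sample, reusing all stored fit state.

    Applies the model's preprocessing with its stored MSC reference,
    centring and coefficients; nothing is refitted from the new data.
    """
    if spectra_set.grid.n_points < model.wavelengths.size:
        raise GridMismatchError("prediction grid shorter than the model grid")
    X, wl, _ = apply_pipeline(spectra_set, model.preprocess,
                              msc_reference=model.msc_reference)
    if wl.size != model.wavelengths.size or not np.allclose(wl, model.wavelengths):
        raise GridMismatchError("prediction wavelengths do not match the model")
    return model.predict_matrix(X)
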