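"""Linear-model comparison of laboratory FN against NIRS predictions.

Three nested candidate structures are compared with AICc: a single
regression (laboratory FN explained by the NIRS prediction alone), an
additive model with species-specific intercepts and a common slope, and
an interaction model with species-specific slopes. The parameter count K
includes the intercept, all coefficients, and the residual variance, so
with S species K = 3, S + 2 and 2S + 1 respectively.

If the additive model wins, one pooled calibration with per-species
offsets describes all species — the rationale for a multispecies
equation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import CollinearityError, SampleSizeError

FORMULAS = ("fn_nirs_only", "fn_nirs_plus_species", "fn_nirs_times_species")


@dataclass(frozen=True)
class ModelSpec:
    formula: str

    def __post_init__(self) -> None:
        if self.formula not in FORMULAS:
            raise ValueError(f"formula must be one of {FORMULAS}")

    def k_parameters(self, n_species: int) -> int:
        """Parameter count including intercept, coefficients and residual
        variance: 3, S+2, 2S+1 for the three formulas."""
        if self.formula == "fn_nirs_only":
            return 3
        if self.formula == "fn_nirs_plus_species":
            return n_species + 2
        return 2 * n_species + 1


def _design(nirs_fn: np.ndarray, species: np.ndarray, formula: str) -> np.ndarray:
    levels = pd.unique(species)
    cols = [np.ones_like(nirs_fn), nirs_fn]
    if formula != "fn_nirs_only" and len(levels) > 1:
        for lev in levels[1:]:  # treatment coding, first level is reference
            ind = (species == lev).astype(float)
            cols.append(ind)
            if formula == "fn_nirs_times_species":
                cols.append(ind * nirs_fn)
    return np.column_stack(cols)


def fit_linear_model(lab_fn, nirs_fn, species, spec: ModelSpec):
    """OLS fit of one candidate model; returns (loglik, coefficients).

    Species enter with treatment coding. The log-likelihood is the
    Gaussian likelihood at the MLE (residual variance = SSE/n).
    """
    lab_fn = np.asarray(lab_fn, float)
    nirs_fn = np.asarray(nirs_fn, float)
    species = np.asarray(species)
    if not (lab_fn.size == nirs_fn.size == species.size):
        raise ValueError("lab_fn, nirs_fn and species must have equal length")
    if spec.formula == "fn_nirs_times_species":
        _, counts = np.unique(species, return_counts=True)
        if np.any(counts < 2):
            raise SampleSizeError(
                "interaction model needs >= 2 samples per species"
            )
    X = _design(nirs_fn, species, spec.formula)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError(f"rank-deficient design for {spec.formula}")
    res = sm.OLS(lab_fn, X).fit()
    return float(res.llf), np.asarray(res.params)


def aicc(loglik: float, K: int, n: int) -> float:
    """AIC corrected for small samples: -2 logL + 2K + 2K(K+1)/(n-K-1)."""
    if n <= K + 1:
        raise SampleSizeError(f"AICc undefined for n={n}, K={K}")
    return -2.0 * loglik + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


def akaike_weights(aicc_values) -> tuple[np.ndarray, np.ndarray]:
    """Δi = AICc_i - min AICc and Wi = exp(-Δi/2) normalised to sum 1."""
    a = np.asarray(aicc_values, float)
    if a.size < 1 or not np.all(np.isfinite(a)):
        raise ValueError("need at least one finite AICc value")
    deltas = a - a.min()
    rel = np.exp(-deltas / 2.0)
    return deltas, rel / rel.sum()


@dataclass
class ModelTable:
    """Candidate models sorted by AICc with Δi and Akaike weights."""

    rows: pd.DataFrame  # columns: formula, K, loglik, aicc, delta, weight

    def best(self) -> ModelSpec:
        return select_best(self)


def compare_models(lab_fn, nirs_fn, species, n_aicc: int | None = None) -> ModelTable:
    """Fit all three candidate structures and rank them by AICc.

    ``n_aicc`` is the sample size entering the small-sample correction;
    by default the number of paired observations.
    """
    lab_fn = np.asarray(lab_fn, float)
    species = np.asarray(species)
    n = lab_fn.size if n_aicc is None else n_aicc
    n_species = len(pd.unique(species))
    records = []
    for formula in FORMULAS:
        spec = ModelSpec(formula)
        K = spec.k_parameters(n_species)
        ll, _ = fit_linear_model(lab_fn, nirs_fn, species, spec)
        records.append({"formula": formula, "K": K, "loglik": ll,
                        "aicc": aicc(ll, K, n)})
    df = pd.DataFrame(records)
    deltas, weights = akaike_weights(df["aicc"].to_numpy())
    df["delta"] = deltas
    df["weight"] = weights
    df = df.sort_values(["aicc", "K"], kind="stable").reset_index(drop=True)
    return ModelTable(rows=df)


def select_best(table: ModelTable) -> ModelSpec:
    """Row with Δi = 0; exact AICc ties broken by the smaller K."""
    df = table.rows
    if df.empty:
        raise ValueError("empty model table")
    best_aicc = df["aicc"].min()
    tied = df[df["aicc"] == best_aicc].sort_values("K", kind="stable")
    return ModelSpec(tied.iloc[0]["formula"])


def residual_diagnostics(lab_fn, nirs_fn, species, spec: ModelSpec) -> dict:
    """Advisory homoscedasticity/normality checks on the chosen model.

    Returns Shapiro-Wilk and Breusch-Pagan p-values for the residuals;
    these inform the analyst and gate nothing.
    """
    lab_fn = np.asarray(lab_fn, float)
    nirs_fn = np.asarray(nirs_fn, float)
    species = np.asarray(species)
    X = _design(nirs_fn, species, spec.formula)
    res = sm.OLS(lab_fn, X).fit()
    shapiro_p = float(stats.shapiro(res.resid).pvalue)
    bp = sm.stats.diagnostic.het_breuschpagan(res.resid, X)
    return {"shapiro_p": shapiro_p, "breusch_pagan_p": float(bp[1])}
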