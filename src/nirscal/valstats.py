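"""Calibration/validation summary statistics and adequacy criteria.

Implements the standard NIRS performance vocabulary: SEC/SECV/SEP, bias,
slope of the reference-on-predicted regression, R², and the two adequacy
ratios RPD = SD(reference)/SEP and RER = range(reference)/SEP. A
calibration is conventionally judged usable for quantitative work when
RPD >= 3.0 and/or RER > 10.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegeneracyError, SampleSizeError
from .mpls import MPLSModel, predict
from .spectra_io import SpectraSet

RPD_GOOD = 3.0
RER_GOOD = 10.0

ROLES = ("calibration", "cross_validation", "external_validation", "prediction")


@dataclass
class ValidationReport:
    """All per-set statistics of a calibration or validation run."""

    n: int
    r2: float
    se: float
    bias: float
    slope: float
    sd_ref: float
    range_ref: float
    rpd: float
    rer: float
    role: str
    adequate_rpd: bool = False
    adequate_rer: bool = False

    @property
    def adequate(self) -> bool:
        """RPD >= 3.0 and/or RER > 10: usable for quantitative analysis."""
        return self.adequate_rpd or self.adequate_rer


def sep(predicted, reference, bias_corrected: bool = True) -> float:
    """Standard error of prediction.

    Bias-corrected (default): ``sqrt(sum((e - mean(e))^2) / (n - 1))`` with
    e = predicted - reference. Without the correction this is the RMSEP,
    ``sqrt(sum(e^2) / n)``.
    """
    predicted = np.asarray(predicted, float)
    reference = np.asarray(reference, float)
    if predicted.shape != reference.shape:
        raise ValueError("predicted and reference must have equal length")
    n = predicted.size
    if n < 2:
        raise SampleSizeError("SEP needs at least 2 samples")
    e = predicted - reference
    if bias_corrected:
        return float(np.sqrt(np.sum((e - e.mean()) ** 2) / (n - 1)))
    return float(np.sqrt(np.sum(e**2) / n))


def sec(predicted, reference, n_factors: int) -> float:
    """Standard error of calibration with n - f - 1 degrees of freedom."""
    predicted = np.asarray(predicted, float)
    reference = np.asarray(reference, float)
    n = predicted.size
    dof = n - n_factors - 1
    if dof < 1:
        raise SampleSizeError(f"SEC undefined for n={n} with {n_factors} factors")
    e = predicted - reference
    return float(np.sqrt(np.sum(e**2) / dof))


def rpd(sd_ref: float, se: float) -> float:
    """Ratio of performance to deviation: SD of the reference over SEP."""
    if se <= 0:
        raise DegeneracyError("RPD undefined for a zero standard error")
    return float(sd_ref) / float(se)


def rer(range_ref: float, se: float) -> float:
    """Range error ratio: reference range over SEP."""
    if se <= 0:
        raise DegeneracyError("RER undefined for a zero standard error")
    return float(range_ref) / float(se)


def bias(predicted, reference) -> float:
    """Mean prediction error, mean(predicted - reference)."""
    return float(np.mean(np.asarray(predicted, float) - np.asarray(reference, float)))


def slope_and_r2(predicted, reference) -> tuple[float, float]:
    """Slope of reference regressed on predicted, and squared correlation.

    The regression direction follows the reporting convention that the
    laboratory value is the response explained by the NIRS prediction:
    slope = cov(reference, predicted) / var(predicted).
    """
    predicted = np.asarray(predicted, float)
    reference = np.asarray(reference, float)
    if predicted.size < 3:
        raise SampleSizeError("slope/r2 need at least 3 samples")
    vp = predicted.var(ddof=1)
    vr = reference.var(ddof=1)
    if vp < 1e-300 or vr < 1e-300:
        raise DegeneracyError("zero variance in predicted or reference values")
    cov = np.cov(reference, predicted, ddof=1)[0, 1]
    slope = float(cov / vp)
    r = float(cov / np.sqrt(vp * vr))
    return slope, r * r


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero, the convention used in reported tables."""
    factor = 10.0**decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def evaluate(
    model: MPLSModel,
    spectra_set: SpectraSet,
    role: str = "external_validation",
    bias_corrected_sep: bool = True,
) -> ValidationReport:
    """Predict a set with a fitted model and assemble the full report.

    For ``role="calibration"`` the standard error is the SEC (n - f - 1
    degrees of freedom); otherwise the (bias-corrected by default) SEP.
    """
    if role not in ROLES:
        raise ValueError(f"role must be one of {ROLES}")
    y = spectra_set.fn_vector()
    if np.any(np.isnan(y)):
        raise ValueError("every sample needs a reference FN value to evaluate")
    yhat = predict(model, spectra_set)
    return report_from_pairs(yhat, y, role=role, n_factors=model.n_factors,
                             bias_corrected_sep=bias_corrected_sep)


def report_from_pairs(
    predicted,
    reference,
    role: str = "external_validation",
    n_factors: int | None = None,
    bias_corrected_sep: bool = True,
) -> ValidationReport:
    """Build a ValidationReport from paired predicted/reference values."""
    predicted = np.asarray(predicted, float)
    reference = np.asarray(reference, float)
    n = reference.size
    if n < 2:
        raise SampleSizeError("reports need at least 2 samples")
    if role == "calibration":
        if n_factors is None:
            raise ValueError("calibration reports need the factor count")
        se = sec(predicted, reference, n_factors)
    else:
        se = sep(predicted, reference, bias_corrected=bias_corrected_sep)
    sd_ref = float(reference.std(ddof=1))
    range_ref = float(reference.max() - reference.min())
    slope, r2 = slope_and_r2(predicted, reference)
    rpd_val = rpd(sd_ref, se) if se > 0 else float("inf")
    rer_val = rer(range_ref, se) if se > 0 else float("inf")
    return ValidationReport(
        n=n,
        r2=r2,
        se=se,
        bias=bias(predicted, reference),
        slope=slope,
        sd_ref=sd_ref,
        range_ref=range_ref,
        rpd=rpd_val,
        rer=rer_val,
        role=role,
        adequate_rpd=rpd_val >= RPD_GOOD,
        adequate_rer=rer_val > RER_GOOD,
    )
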