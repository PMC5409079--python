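"""Scatter corrections and derivative math treatments.

The preprocessing vocabulary follows WinISI conventions: a scatter
correction (none, SNV, detrend, SNV+detrend, or MSC) followed by a
"math treatment" written ``(d, g, s1, s2)`` — derivative order,
subtraction gap, first and second smoothing segment, all in data points.
``(1,4,4,1)`` therefore means: boxcar-smooth over 4 points, no second
smoothing, then a first derivative with a 4-point gap.

Edges are truncated rather than padded, so the derivative output lives on
a trimmed wavelength axis which is carried alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateInputError,
    ScatterCorrectionError,
    WindowError,
)
from .spectra_io import SpectraSet, Spectrum, WavelengthGrid

SCATTER_CHOICES = ("none", "SNV", "DT", "SNV_DT", "MSC")


@dataclass(frozen=True)
class PreprocessSpec:
    """Scatter correction plus math treatment ``(deriv_order, gap, smooth1, smooth2)``."""

    scatter: str = "none"
    deriv_order: int = 0
    gap: int = 1
    smooth1: int = 1
    smooth2: int = 1

    def __post_init__(self) -> None:
        if self.scatter not in SCATTER_CHOICES:
            raise ValueError(f"scatter must be one of {SCATTER_CHOICES}")
        if self.deriv_order not in (0, 1, 2):
            raise ValueError("deriv_order must be 0, 1 or 2")
        for name in ("gap", "smooth1", "smooth2"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1 point")

    @property
    def math(self) -> tuple[int, int, int, int]:
        return (self.deriv_order, self.gap, self.smooth1, self.smooth2)

    def label(self) -> str:
        d, g, s1, s2 = self.math
        return f"{self.scatter}+({d},{g},{s1},{s2})"


@dataclass
class MSCReference:
    """Reference spectrum for multiplicative scatter correction.

    By convention this is the mean calibration-set spectrum; it is fitted
    once on calibration data and reused unchanged for validation and
    prediction sets.
    """

    reference_spectrum: np.ndarray

    def __post_init__(self) -> None:
        self.reference_spectrum = np.asarray(self.reference_spectrum, dtype=float)


def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate: centre and scale one spectrum to (0, 1).

    Uses the sample standard deviation (n-1 denominator). Invariant under
    affine transforms of the input and idempotent.
    """
    x = np.asarray(spectrum, dtype=float)
    if x.size < 2:
        raise DegenerateInputError("SNV needs at least 2 points")
    sd = x.std(ddof=1)
    if sd < 1e-12:
        raise DegenerateInputError("SNV undefined for a constant spectrum")
    return (x - x.mean()) / sd


def detrend(spectrum: np.ndarray, grid, degree: int = 2) -> np.ndarray:
    """Residuals of a least-squares polynomial baseline in wavelength.

    ``grid`` may be a :class:`WavelengthGrid` or an explicit wavelength
    vector. Degree 2 is the standard SNV-detrend formulation.
    """
    x = np.asarray(spectrum, dtype=float)
    wl = grid.wavelengths() if isinstance(grid, WavelengthGrid) else np.asarray(grid, float)
    if x.size != wl.size:
        raise WindowError(f"spectrum has {x.size} points, grid has {wl.size}")
    if degree >= x.size - 1:
        raise DegenerateInputError(
            f"detrend degree {degree} needs more than {degree + 1} points"
        )
    # centre/scale the axis for conditioning; residuals are unaffected
    w = (wl - wl.mean()) / (wl.std() if wl.std() > 0 else 1.0)
    coef = np.polynomial.polynomial.polyfit(w, x, degree)
    return x - np.polynomial.polynomial.polyval(w, coef)


def msc(spectra_set: SpectraSet, reference: MSCReference) -> SpectraSet:
    """Multiplicative scatter correction against a fixed reference.

    Each spectrum x is regressed ``x = a + b * reference`` over wavelengths
    and replaced by ``(x - a) / b``. Slopes below 1e-8 in magnitude are a
    scatter-correction failure for that sample.
    """
    ref = reference.reference_spectrum
    if ref.size != spectra_set.grid.n_points:
        raise WindowError("MSC reference length does not match the grid")
    ref_c = ref - ref.mean()
    denom = float(ref_c @ ref_c)
    if denom < 1e-12:
        raise DegenerateInputError("MSC reference spectrum is constant")
    corrected = []
    for s in spectra_set.spectra:
        x = s.absorbance
        b = float(ref_c @ (x - x.mean())) / denom
        a = float(x.mean() - b * ref.mean())
        if abs(b) < 1e-8:
            raise ScatterCorrectionError(
                f"MSC slope {b:.2e} too small for sample {s.sample_id}"
            )
        corrected.append(
            Spectrum(s.sample_id, s.species, s.replicate, (x - a) / b)
        )
    return spectra_set.with_spectra(corrected)


def fit_msc_reference(spectra_set: SpectraSet) -> MSCReference:
    """Mean spectrum of a (calibration) set, the conventional MSC reference."""
    return MSCReference(spectra_set.absorbance_matrix().mean(axis=0))


# -- gap-segment derivative ------------------------------------------------


def _boxcar(x: np.ndarray, wl: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Moving average over m points, truncated at the edges."""
    if m == 1:
        return x, wl
    if x.size < m:
        raise WindowError(f"spectrum of {x.size} points shorter than segment {m}")
    kernel = np.full(m, 1.0 / m)
    sm = np.convolve(x, kernel, mode="valid")
    # window centres: mean wavelength of each m-point window
    wl_out = np.convolve(wl, kernel, mode="valid")
    return sm, wl_out


def _gap_difference(x: np.ndarray, wl: np.ndarray, gap: int) -> tuple[np.ndarray, np.ndarray]:
    """D[i] = s[i + gap/2] - s[i - gap/2]; odd gaps use half-point interpolation."""
    if gap % 2 == 0:
        h = gap // 2
        if x.size < gap + 1:
            raise WindowError(f"spectrum too short for gap {gap}")
        out = x[2 * h:] - x[:-2 * h]
        wl_out = wl[h:-h]
    else:
        # interpolate s at i +/- gap/2 as the mean of the flanking points
        h = gap // 2
        if x.size < gap + 2:
            raise WindowError(f"spectrum too short for gap {gap}")
        upper = 0.5 * (x[2 * h + 1:-1] + x[2 * h + 2:])
        lower = 0.5 * (x[: -2 * h - 2] + x[1: -2 * h - 1])
        out = upper - lower
        wl_out = wl[h + 1: -h - 1]
    return out, wl_out


def gap_segment_derivative(
    spectrum: np.ndarray, spec: PreprocessSpec, grid=None
) -> tuple[np.ndarray, np.ndarray | None]:
    """Smoothed gap derivative of one spectrum.

    Applies a boxcar of ``smooth1`` points, then one of ``smooth2`` points,
    then the gap difference once per derivative order. Returns the
    transformed vector and, when a grid (or wavelength vector) is supplied,
    the trimmed wavelength axis; otherwise None.
    """
    x = np.asarray(spectrum, dtype=float)
    if grid is None:
        wl = np.arange(x.size, dtype=float)
        return_wl = False
    else:
        wl = grid.wavelengths() if isinstance(grid, WavelengthGrid) else np.asarray(grid, float)
        return_wl = True
    if x.size < spec.gap + 2 * spec.smooth1:
        raise WindowError(
            f"spectrum of {x.size} points shorter than derivative support"
        )
    x, wl = _boxcar(x, wl, spec.smooth1)
    x, wl = _boxcar(x, wl, spec.smooth2)
    for _ in range(spec.deriv_order):
        x, wl = _gap_difference(x, wl, spec.gap)
    return (x, wl) if return_wl else (x, None)


def apply_pipeline(
    spectra_set: SpectraSet,
    spec: PreprocessSpec,
    msc_reference: MSCReference | None = None,
) -> tuple[np.ndarray, np.ndarray, MSCReference | None]:
    """Run scatter correction then derivative over a whole set.

    Returns ``(X, wavelengths, fitted_reference)`` where X is the
    (n_samples, n_trimmed) matrix of preprocessed spectra. For MSC the
    reference is fitted as the set mean when none is supplied (the set is
    then by construction the calibration set) and returned so validation
    and prediction sets reuse it; scatter parameters are never refitted
    from non-calibration data.
    """
    working = spectra_set
    fitted_ref = msc_reference

    if spec.scatter == "SNV":
        working = working.with_spectra(
            [Spectrum(s.sample_id, s.species, s.replicate, snv(s.absorbance))
             for s in working.spectra]
        )
    elif spec.scatter == "DT":
        working = working.with_spectra(
            [Spectrum(s.sample_id, s.species, s.replicate,
                      detrend(s.absorbance, working.grid))
             for s in working.spectra]
        )
    elif spec.scatter == "SNV_DT":
        working = working.with_spectra(
            [Spectrum(s.sample_id, s.species, s.replicate,
                      detrend(snv(s.absorbance), working.grid))
             for s in working.spectra]
        )
    elif spec.scatter == "MSC":
        if fitted_ref is None:
            fitted_ref = fit_msc_reference(working)
        working = msc(working, fitted_ref)

    rows = []
    wl_out = None
    for s in working.spectra:
        vec, wl_out = gap_segment_derivative(s.absorbance, spec, working.grid)
        rows.append(vec)
    X = np.vstack(rows) if rows else np.empty((0, 0))
    return X, wl_out, fitted_ref


def default_spec_grid() -> list[PreprocessSpec]:
    """The 4 x 2 grid of candidate treatments: {SNV, DT, SNV+DT, MSC} x
    {(1,4,4,1), (2,4,4,1)} — eight pipelines in total."""
    specs = []
    for scatter in ("SNV", "DT", "SNV_DT", "MSC"):
        for math in ((1, 4, 4, 1), (2, 4, 4, 1)):
            specs.append(PreprocessSpec(scatter, *math))
    return specs
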