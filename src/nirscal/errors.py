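"""Exception hierarchy shared across the package."""


class NirscalError(Exception):
    """Base class for all package-specific errors."""


class SpectraFormatError(NirscalError):
    """Malformed spectra file: bad header, non-monotone or uneven wavelengths."""


class SpectraParseError(NirscalError):
    """Non-numeric or missing values where numbers are required."""


class ConsistencyError(NirscalError):
    """Contradictory metadata, e.g. replicates of one sample with two species."""


class SplitError(NirscalError):
    """Invalid calibration/validation split request."""


class DegenerateInputError(NirscalError):
    """Input without enough variation for the requested transform."""


class WindowError(NirscalError):
    """Spectrum shorter than the derivative/smoothing support."""


class ScatterCorrectionError(NirscalError):
    """MSC regression slope too close to zero for a sample."""


class RankError(NirscalError):
    """More latent factors requested than the data can support."""


class GridMismatchError(NirscalError):
    """Spectra grid incompatible with a fitted model's grid."""


class OutlierRunawayError(NirscalError):
    """Outlier elimination would discard too large a share of the samples."""


class SampleSizeError(NirscalError):
    """Too few samples for the requested statistic."""


class DegeneracyError(NirscalError):
    """Zero-variance input where a correlation or slope is required."""


class CollinearityError(NirscalError):
    """Rank-deficient design matrix in a linear model."""
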