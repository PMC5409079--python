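"""Synthetic faecal NIR spectra with known nitrogen content.

The generator emulates the statistical structure the calibration analysis
assumes: each species has its own faecal-nitrogen (FN) distribution
(truncated normal, % dry matter), spectra are sums of Gaussian absorption
bands on a sloping baseline, and the nitrogen signal enters the
protein-associated combination bands in the 2100-2350 nm region as an
affine (Beer-Lambert, low-concentration) function of FN — with reduced
absorption at 2312 and 2350 nm for higher FN. Replicate scans add
multiplicative/additive scatter (particle-size effects) and white
instrument noise.

Five species parameterise the calibration pool (European rabbit, horse,
Pyrenean chamois, red deer, sheep) and five more act as hold-out species
predicted by the pooled equation (Alpine ibex, cattle, European mouflon,
goat, roe deer).

A per-sample "spectral FN" perturbation (``spectral_fn_noise_sd``)
decouples the spectrum from the reference value by a small amount; it is
the irreducible error floor of any calibration built on these data and
plays the role of the combined laboratory/matrix error of real samples.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .spectra_io import SpectraSet, Spectrum, WavelengthGrid


@dataclass(frozen=True)
class Band:
    """One Gaussian absorption band.

    ``fn_coefficient`` is the absorbance change per % FN (zero for
    FN-independent bands such as the water and fat bands).
    """

    center_nm: float
    width_nm: float
    base_amplitude: float
    fn_coefficient: float = 0.0

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise ValueError("band width must be positive")


@dataclass(frozen=True)
class SpeciesProfile:
    """FN distribution and spectral idiosyncrasies of one species."""

    name: str
    fn_mean: float
    fn_sd: float
    fn_min: float
    fn_max: float
    n_cal: int = 0
    n_val: int = 0
    n_pred: int = 0
    baseline_offset: float = 0.30
    baseline_tilt: float = 0.10      # absorbance per 1000 nm
    amplitude_scale: float = 1.0     # multiplies FN-independent band amplitudes

    def __post_init__(self) -> None:
        if not self.fn_min < self.fn_max:
            raise ValueError("fn_min must be below fn_max")
        if min(self.n_cal, self.n_val, self.n_pred) < 0:
            raise ValueError("sample counts must be non-negative")


@dataclass
class SyntheticConfig:
    grid: WavelengthGrid
    species: list[SpeciesProfile]
    bands: list[Band]
    scatter_slope_sd: float = 0.05   # sigma of LogNormal multiplicative scatter
    scatter_offset_sd: float = 0.02  # SD of additive scatter offset
    noise_sd: float = 0.0005         # white instrument noise per point
    spectral_fn_noise_sd: float = 0.03  # % FN; irreducible calibration error
    amplitude_jitter_rel_sd: float = 0.08  # relative jitter of FN-free bands
    replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("need at least one replicate scan")
        for name in ("scatter_slope_sd", "scatter_offset_sd", "noise_sd",
                     "spectral_fn_noise_sd", "amplitude_jitter_rel_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not any(s.n_cal + s.n_val + s.n_pred > 0 for s in self.species):
            raise ValueError("no samples requested")


# Table-style defaults: the five calibration species' FN moments/ranges and
# counts, and the five hold-out species used as an independent prediction set.
_CAL_SPECIES = [
    # name, mean, sd, min, max, n_cal, n_val, offset, tilt, amp_scale
    ("European rabbit", 1.288, 0.569, 0.75, 2.74, 60, 14, 0.26, 0.12, 0.92),
    ("Horse", 1.606, 0.309, 1.03, 2.30, 60, 10, 0.34, 0.08, 1.06),
    ("Pyrenean chamois", 2.233, 0.469, 1.53, 3.58, 68, 17, 0.30, 0.11, 1.00),
    ("Red deer", 2.432, 0.492, 1.52, 3.39, 77, 19, 0.37, 0.09, 1.10),
    ("Sheep", 1.977, 0.332, 1.47, 3.07, 80, 20, 0.28, 0.13, 0.96),
]

_HOLDOUT_SPECIES = [
    # name, mean, sd, min, max, n_pred, offset, tilt, amp_scale
    ("Alpine ibex", 2.737, 0.479, 1.99, 3.65, 12, 0.31, 0.10, 1.02),
    ("Cattle", 2.870, 0.267, 2.32, 3.31, 12, 0.39, 0.07, 1.12),
    ("European mouflon", 3.190, 0.708, 1.92, 4.09, 15, 0.29, 0.12, 0.98),
    ("Goat", 2.267, 0.234, 1.87, 2.60, 12, 0.27, 0.11, 0.94),
    ("Roe deer", 2.144, 0.536, 1.59, 3.51, 20, 0.33, 0.10, 1.04),
]

# Characteristic bands of faecal NIR spectra: water (1450, 1930), fat
# (1730), and the starch/protein combination region (2106, 2312, 2350)
# where the nitrogen signal lives — positive at 2106, reduced absorption
# at 2312/2350 with increasing FN.
_DEFAULT_BANDS = [
    Band(1450.0, 35.0, 0.18, 0.0),
    Band(1730.0, 30.0, 0.08, 0.0),
    Band(1930.0, 40.0, 0.35, 0.0),
    Band(2106.0, 30.0, 0.15, 0.035),
    Band(2312.0, 25.0, 0.12, -0.020),
    Band(2350.0, 25.0, 0.10, -0.020),
]


def default_config(seed: int = 0) -> SyntheticConfig:
    """Default study conditions: 345 calibration + 80 validation samples
    across five species, 71 hold-out samples across five more, two scans
    per sample on the 1100-2500 nm grid at 2 nm steps."""
    species = [
        SpeciesProfile(name, mean, sd, lo, hi, n_cal=nc, n_val=nv,
                       baseline_offset=off, baseline_tilt=tilt,
                       amplitude_scale=amp)
        for name, mean, sd, lo, hi, nc, nv, off, tilt, amp in _CAL_SPECIES
    ] + [
        SpeciesProfile(name, mean, sd, lo, hi, n_pred=np_,
                       baseline_offset=off, baseline_tilt=tilt,
                       amplitude_scale=amp)
        for name, mean, sd, lo, hi, np_, off, tilt, amp in _HOLDOUT_SPECIES
    ]
    return SyntheticConfig(
        grid=WavelengthGrid(1100.0, 2500.0, 2.0),
        species=species,
        bands=list(_DEFAULT_BANDS),
        seed=seed,
    )


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Rejection sampling; adequate for bounds within a few SD of the mean."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled) + 8)
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(keep.size, size - filled)
        out[filled:filled + take] = keep[:take]
        filled += take
    return out


def generate(config: SyntheticConfig) -> SpectraSet:
    """Draw a complete spectra set (with reference FN) from the config.

    Per sample: FN ~ truncated Normal; clean spectrum = baseline + sum of
    bands with amplitudes ``amplitude_scale * base_amplitude * (1 + jitter)``
    for FN-free bands and ``base_amplitude + fn_coefficient * (FN + eta)``
    for nitrogen-linked bands, eta ~ N(0, spectral_fn_noise_sd). Each
    replicate scan is ``b * clean + a + noise`` with b ~ LogNormal(0,
    scatter_slope_sd) and a ~ N(0, scatter_offset_sd). Fully reproducible
    from the seed.
    """
    rng = np.random.default_rng(config.seed)
    wl = config.grid.wavelengths()
    gaussians = np.vstack([
        np.exp(-((wl - b.center_nm) ** 2) / (2.0 * b.width_nm**2))
        for b in config.bands
    ])
    base_amps = np.array([b.base_amplitude for b in config.bands])
    fn_coefs = np.array([b.fn_coefficient for b in config.bands])
    fn_free = fn_coefs == 0.0

    spectra: list[Spectrum] = []
    fn_ref: dict[str, float] = {}
    set_label: dict[str, str] = {}
    counter = 0
    for profile in config.species:
        counts = (("calibration", profile.n_cal), ("validation", profile.n_val),
                  ("prediction", profile.n_pred))
        n_total = profile.n_cal + profile.n_val + profile.n_pred
        if n_total == 0:
            continue
        fn_values = _truncated_normal(rng, profile.fn_mean, profile.fn_sd,
                                      profile.fn_min, profile.fn_max, n_total)
        baseline = (profile.baseline_offset
                    + profile.baseline_tilt * (wl - wl[0]) / 1000.0)
        idx = 0
        for label, count in counts:
            for _ in range(count):
                fn = float(fn_values[idx])
                idx += 1
                counter += 1
                sid = f"S{counter:04d}"
                fn_spectral = fn + rng.normal(0.0, config.spectral_fn_noise_sd)
                amps = base_amps.copy()
                amps[fn_free] *= profile.amplitude_scale * (
                    1.0 + rng.normal(0.0, config.amplitude_jitter_rel_sd,
                                     size=int(fn_free.sum()))
                )
                amps = amps + fn_coefs * fn_spectral
                clean = baseline + amps @ gaussians
                for rep in range(1, config.replicates + 1):
                    b = float(np.exp(rng.normal(0.0, config.scatter_slope_sd)))
                    a = float(rng.normal(0.0, config.scatter_offset_sd))
                    noise = rng.normal(0.0, config.noise_sd, size=wl.size)
                    spectra.append(
                        Spectrum(sample_id=sid, species=profile.name,
                                 replicate=rep, absorbance=b * clean + a + noise)
                    )
                fn_ref[sid] = fn
                set_label[sid] = label
    return SpectraSet(grid=config.grid, spectra=spectra, fn_ref=fn_ref,
                      set_label=set_label)


def noise_free_config(config: SyntheticConfig | None = None) -> SyntheticConfig:
    """Copy of a config with every stochastic nuisance switched off."""
    cfg = config if config is not None else default_config()
    return replace(cfg, scatter_slope_sd=0.0, scatter_offset_sd=0.0,
                   noise_sd=0.0, spectral_fn_noise_sd=0.0,
                   amplitude_jitter_rel_sd=0.0)


def simulate_lab_nirs_pairs(
    n: int = 80,
    n_species: int = 5,
    intercept_sd: float = 0.15,
    slope: float = 1.0,
    residual_sd: float = 0.10,
    seed: int = 0,
):
    """Paired (laboratory FN, NIRS FN, species) data with species-specific
    intercepts and a common slope — the structure under which the additive
    linear model should win the AICc comparison.

    Returns ``(lab_fn, nirs_fn, species)`` arrays of length n.
    """
    rng = np.random.default_rng(seed)
    per = n // n_species
    sizes = [per + (1 if i < n % n_species else 0) for i in range(n_species)]
    intercepts = rng.normal(0.0, intercept_sd, size=n_species)
    means = np.linspace(1.3, 3.2, n_species)
    nirs, lab, spp = [], [], []
    for i, size in enumerate(sizes):
        x = rng.normal(means[i], 0.45, size=size)
        y = intercepts[i] + slope * x + rng.normal(0.0, residual_sd, size=size)
        nirs.append(x)
        lab.append(y)
        spp.extend([f"species_{i + 1}"] * size)
    return np.concatenate(lab), np.concatenate(nirs), np.array(spp)
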