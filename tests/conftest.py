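import numpy as np
import pytest

from nirscal.spectra_io import SpectraSet, Spectrum, WavelengthGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    return WavelengthGrid(1100.0, 1198.0, 2.0)  # 50 points


def make_set(grid, X, species=None, fn=None, replicate=None, set_label=None):
    """Build a SpectraSet from a matrix of absorbance rows."""
    n = X.shape[0]
    species = species or ["sp"] * n
    spectra = [
        Spectrum(
            sample_id=f"s{i}",
            species=species[i],
            replicate=1 if replicate is None else replicate[i],
            absorbance=X[i],
        )
        for i in range(n)
    ]
    fn_ref = {} if fn is None else {f"s{i}": float(fn[i]) for i in range(n)}
    labels = {} if set_label is None else {f"s{i}": set_label[i] for i in range(n)}
    return SpectraSet(grid=grid, spectra=spectra, fn_ref=fn_ref, set_label=labels)


@pytest.fixture(scope="session")
def default_run():
    """One full workflow run on the default synthetic study, shared by the
    workflow and end-to-end tests."""
    from nirscal.workflow import RunConfig, run_pipeline

    return run_pipeline(RunConfig(seed=1, write_figures=False))


@pytest.fixture
def linear_fn_set(small_grid, rng):
    """Spectra whose absorbance at one band is an exact affine function of
    FN plus tiny structure elsewhere — one latent factor suffices."""
    wl = small_grid.wavelengths()
    n = 24
    fn = rng.uniform(1.0, 3.0, size=n)
    band = np.exp(-((wl - 1150.0) ** 2) / (2 * 12.0**2))
    base = 0.3 + 0.05 * (wl - wl[0]) / 1000.0
    X = base + np.outer(0.1 * fn, band)
    return make_set(small_grid, X, fn=fn)
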