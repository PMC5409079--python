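"""Data model and file I/O for NIR spectra sets.

A :class:`SpectraSet` bundles log(1/R) absorbance spectra on a common
wavelength grid with per-sample metadata (species, replicate, set
membership) and optional reference faecal-nitrogen values (% dry matter).
The on-disk interchange format is a wide CSV with columns
``sample_id, species, replicate, set, fn_ref, <nm>, <nm>, ...`` where the
wavelength columns are bare integers in nanometres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConsistencyError, SpectraFormatError, SpectraParseError, SplitError

META_COLUMNS = ["sample_id", "species", "replicate", "set", "fn_ref"]

SET_LABELS = ("calibration", "validation", "prediction")


@dataclass(frozen=True)
class WavelengthGrid:
    """Evenly spaced wavelength axis in nanometres."""

    start_nm: float
    end_nm: float
    step_nm: float

    def __post_init__(self) -> None:
        if not self.start_nm < self.end_nm:
            raise SpectraFormatError(
                f"grid start {self.start_nm} must be below end {self.end_nm}"
            )
        if self.step_nm <= 0:
            raise SpectraFormatError(f"grid step must be positive, got {self.step_nm}")
        span = (self.end_nm - self.start_nm) / self.step_nm
        if abs(span - round(span)) > 1e-9:
            raise SpectraFormatError(
                f"grid ({self.start_nm}, {self.end_nm}, {self.step_nm}) does not "
                "contain a whole number of steps"
            )

    @property
    def n_points(self) -> int:
        return int(round((self.end_nm - self.start_nm) / self.step_nm)) + 1

    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.n_points)


@dataclass
class Spectrum:
    """One scan: absorbance = log(1/R) at each grid point."""

    sample_id: str
    species: str
    replicate: int
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if not np.all(np.isfinite(self.absorbance)):
            raise SpectraParseError(f"non-finite absorbance in sample {self.sample_id}")


@dataclass
class SpectraSet:
    """Spectra on a shared grid plus reference chemistry and set labels."""

    grid: WavelengthGrid
    spectra: list[Spectrum]
    fn_ref: dict[str, float] = field(default_factory=dict)
    set_label: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.grid.n_points
        for s in self.spectra:
            if s.absorbance.shape != (n,):
                raise SpectraFormatError(
                    f"sample {s.sample_id} has {s.absorbance.size} points, "
                    f"grid has {n}"
                )
        for sid, v in self.fn_ref.items():
            if not (0.0 < v < 100.0):
                raise SpectraParseError(f"fn_ref for {sid} out of (0, 100): {v}")
        for sid, lab in self.set_label.items():
            if lab not in SET_LABELS:
                raise SpectraParseError(f"unknown set label {lab!r} for {sid}")

    # -- convenience accessors -------------------------------------------

    def __len__(self) -> int:
        return len(self.spectra)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.spectra]

    @property
    def species(self) -> list[str]:
        return [s.species for s in self.spectra]

    def absorbance_matrix(self) -> np.ndarray:
        """Stack spectra into an (n_samples, n_wavelengths) matrix."""
        return np.vstack([s.absorbance for s in self.spectra])

    def fn_vector(self) -> np.ndarray:
        """Reference FN aligned with the spectra order (NaN where absent)."""
        return np.array([self.fn_ref.get(s.sample_id, np.nan) for s in self.spectra])

    def subset(self, sample_ids) -> "SpectraSet":
        wanted = set(sample_ids)
        spectra = [s for s in self.spectra if s.sample_id in wanted]
        return SpectraSet(
            grid=self.grid,
            spectra=spectra,
            fn_ref={k: v for k, v in self.fn_ref.items() if k in wanted},
            set_label={k: v for k, v in self.set_label.items() if k in wanted},
        )

    def by_set(self, label: str) -> "SpectraSet":
        ids = [sid for sid, lab in self.set_label.items() if lab == label]
        return self.subset(ids)

    def by_species(self, name: str) -> "SpectraSet":
        return self.subset([s.sample_id for s in self.spectra if s.species == name])

    def with_spectra(self, spectra: list[Spectrum], grid=None) -> "SpectraSet":
        return SpectraSet(
            grid=grid if grid is not None else self.grid,
            spectra=spectra,
            fn_ref=dict(self.fn_ref),
            set_label=dict(self.set_label),
        )


# -- CSV round trip --------------------------------------------------------


def _infer_grid(wavelengths: list[float]) -> WavelengthGrid:
    if len(wavelengths) < 2:
        raise SpectraFormatError("need at least two wavelength columns")
    diffs = np.diff(wavelengths)
    if np.any(diffs <= 0):
        raise SpectraFormatError(
            "wavelength columns must be strictly increasing; got "
            f"{wavelengths[:5]}..."
        )
    step = diffs[0]
    if not np.allclose(diffs, step, rtol=0, atol=1e-9):
        raise SpectraFormatError("wavelength columns are not evenly spaced")
    return WavelengthGrid(wavelengths[0], wavelengths[-1], float(step))


def read_spectra_csv(path, grid_policy="infer") -> SpectraSet:
    """Read a wide-format spectra CSV.

    Parameters
    ----------
    path : str or Path
        CSV with columns ``sample_id, species, replicate, set, fn_ref``
        followed by numeric wavelength columns in strictly increasing order.
    grid_policy : "infer" or WavelengthGrid
        With ``"infer"`` the grid is derived from the header; an explicit
        grid is validated against the header instead.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "species": str})
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise SpectraFormatError(f"missing metadata columns: {missing}")
    wl_cols = [c for c in df.columns if c not in META_COLUMNS]
    try:
        wavelengths = [float(c) for c in wl_cols]
    except ValueError as exc:
        raise SpectraFormatError(f"non-numeric wavelength column: {exc}") from None
    grid = _infer_grid(wavelengths)
    if grid_policy != "infer":
        if not isinstance(grid_policy, WavelengthGrid):
            raise SpectraFormatError("grid_policy must be 'infer' or a WavelengthGrid")
        if (grid_policy.start_nm, grid_policy.end_nm, grid_policy.step_nm) != (
            grid.start_nm,
            grid.end_nm,
            grid.step_nm,
        ):
            raise SpectraFormatError(
                f"header grid {grid} does not match requested {grid_policy}"
            )
        grid = grid_policy

    spectra: list[Spectrum] = []
    fn_ref: dict[str, float] = {}
    set_label: dict[str, str] = {}
    values = df[wl_cols].to_numpy()
    for i, row in enumerate(df.itertuples(index=False)):
        vec = values[i]
        if not np.all(np.isfinite(vec)):
            bad = wl_cols[int(np.flatnonzero(~np.isfinite(vec))[0])]
            raise SpectraParseError(
                f"non-numeric absorbance at row {i + 2}, column {bad}"
            )
        spectra.append(
            Spectrum(
                sample_id=str(row.sample_id),
                species=str(row.species),
                replicate=int(row.replicate),
                absorbance=vec,
            )
        )
        sid = str(row.sample_id)
        if pd.notna(row.fn_ref):
            fn_ref[sid] = float(row.fn_ref)
        if isinstance(row.set, str) and row.set:
            set_label[sid] = row.set
    return SpectraSet(grid=grid, spectra=spectra, fn_ref=fn_ref, set_label=set_label)


def write_spectra_csv(spectra_set: SpectraSet, path) -> None:
    """Write the wide CSV layout; absorbance at 6 significant digits."""
    wl = spectra_set.grid.wavelengths()
    wl_cols = [
        str(int(w)) if float(w).is_integer() else repr(float(w)) for w in wl
    ]
    rows = []
    for s in spectra_set.spectra:
        row = {
            "sample_id": s.sample_id,
            "species": s.species,
            "replicate": s.replicate,
            "set": spectra_set.set_label.get(s.sample_id, ""),
            "fn_ref": spectra_set.fn_ref.get(s.sample_id, ""),
        }
        row.update({c: float(f"{v:.6g}") for c, v in zip(wl_cols, s.absorbance)})
        rows.append(row)
    pd.DataFrame(rows, columns=META_COLUMNS + wl_cols).to_csv(path, index=False)


# -- replicate averaging and set splitting ---------------------------------


def average_replicates(spectra_set: SpectraSet) -> SpectraSet:
    """Average repeated scans of each sample point-wise.

    Replicate scans of one ``sample_id`` must agree on species. The result
    has one spectrum per sample with ``replicate = 1``. Idempotent.
    """
    order: list[str] = []
    groups: dict[str, list[Spectrum]] = {}
    for s in spectra_set.spectra:
        if s.sample_id not in groups:
            order.append(s.sample_id)
            groups[s.sample_id] = []
        groups[s.sample_id].append(s)
    averaged = []
    for sid in order:
        members = groups[sid]
        species = {m.species for m in members}
        if len(species) > 1:
            raise ConsistencyError(
                f"sample {sid} has conflicting species labels: {sorted(species)}"
            )
        mean = np.mean([m.absorbance for m in members], axis=0)
        averaged.append(
            Spectrum(sample_id=sid, species=members[0].species, replicate=1,
                     absorbance=mean)
        )
    return spectra_set.with_spectra(averaged)


def split_cal_val(
    spectra_set: SpectraSet,
    val_fraction: float,
    seed: int,
    stratify_by_species: bool = True,
) -> tuple[SpectraSet, SpectraSet]:
    """Partition samples into calibration and external-validation sets.

    With stratification each species contributes
    ``round(n_species * val_fraction)`` validation samples. The partition is
    disjoint, exhaustive, and deterministic for a given seed. Every sample
    must carry a reference FN value.
    """
    if not 0.0 < val_fraction < 1.0:
        raise SplitError(f"val_fraction must be in (0, 1), got {val_fraction}")
    ids = spectra_set.sample_ids
    if len(set(ids)) != len(ids):
        raise SplitError("split requires replicate-averaged data (unique sample_ids)")
    missing = [sid for sid in ids if sid not in spectra_set.fn_ref]
    if missing:
        raise SplitError(f"samples without reference FN cannot be split: {missing[:5]}")

    rng = np.random.default_rng(seed)
    val_ids: list[str] = []
    if stratify_by_species:
        by_species: dict[str, list[str]] = {}
        for s in spectra_set.spectra:
            by_species.setdefault(s.species, []).append(s.sample_id)
        for species in sorted(by_species):
            members = sorted(by_species[species])
            if len(members) < 2:
                raise SplitError(
                    f"species {species!r} has {len(members)} sample(s); "
                    "stratified split needs at least 2"
                )
            n_val = int(math.floor(len(members) * val_fraction + 0.5))
            n_val = min(max(n_val, 0), len(members) - 1)
            chosen = rng.choice(len(members), size=n_val, replace=False)
            val_ids.extend(members[i] for i in sorted(chosen))
    else:
        members = sorted(ids)
        n_val = int(math.floor(len(members) * val_fraction + 0.5))
        n_val = min(max(n_val, 0), len(members) - 1)
        chosen = rng.choice(len(members), size=n_val, replace=False)
        val_ids.extend(members[i] for i in sorted(chosen))

    val_set = set(val_ids)
    cal = spectra_set.subset([sid for sid in ids if sid not in val_set])
    val = spectra_set.subset([sid for sid in ids if sid in val_set])
    for sid in cal.sample_ids:
        cal.set_label[sid] = "calibration"
    for sid in val.sample_ids:
        val.set_label[sid] = "validation"
    return cal, val
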