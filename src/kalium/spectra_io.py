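"""Reading, writing and validation of wide-format leaf spectra tables.

The interchange format is a plain CSV with one row per sample::

    sample_id,potassium,400,401,...,2500
    S0001,0.53,0.041,0.042,...

``potassium`` is the leaf potassium content in units of 10 g/kg; the
remaining columns are reflectance values at integer-nanometre wavelengths.
All downstream math (fractional differentiation in particular) assumes a
strictly uniform 1-nm wavelength grid, which this module enforces: input on
a coarser or irregular grid is linearly resampled on ingestion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, RangeError, ValidationError

#: Default working spectral range, nm. Shorter wavelengths recorded by field
#: spectroradiometers (350-399 nm) are noisy and discarded on ingestion.
DEFAULT_RANGE_NM = (400, 2500)


@dataclass
class Dialect:
    """Column-naming convention of a spectra CSV."""

    id_col: str = "sample_id"
    potassium_col: str = "potassium"
    #: what to do when wavelength spacing is not exactly 1 nm:
    #: ``"resample"`` (linear interpolation) or ``"error"``.
    on_nonuniform: str = "resample"


@dataclass
class SpectraSet:
    """A samples x bands reflectance matrix with aligned potassium values.

    Parameters
    ----------
    sample_ids
        Opaque per-sample identifiers, length ``n_samples``.
    wavelengths
        Strictly increasing wavelength axis in nm with uniform 1-nm spacing.
    reflectance
        ``(n_samples, n_bands)`` matrix. Unitless; at ``order == 0`` every
        value must lie in [0, 1].
    potassium
        Leaf potassium content per sample, units of 10 g/kg, strictly
        positive.
    order
        Fractional-differentiation order of the stored matrix; 0.0 for raw
        reflectance.
    """

    sample_ids: list
    wavelengths: np.ndarray
    reflectance: np.ndarray
    potassium: np.ndarray
    order: float = 0.0

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.potassium = np.asarray(self.potassium, dtype=float)
        self.sample_ids = list(self.sample_ids)
        n, k = self.reflectance.shape
        if len(self.sample_ids) != n or len(self.potassium) != n:
            raise ValidationError(
                f"row mismatch: {n} reflectance rows, {len(self.sample_ids)} ids, "
                f"{len(self.potassium)} potassium values"
            )
        if len(self.wavelengths) != k:
            raise ValidationError(
                f"column mismatch: {k} reflectance columns, "
                f"{len(self.wavelengths)} wavelengths"
            )
        if k >= 2:
            steps = np.diff(self.wavelengths)
            if np.any(steps <= 0):
                raise ValidationError("wavelengths must be strictly increasing")
            if not np.allclose(steps, 1.0, atol=1e-9):
                raise ValidationError(
                    "wavelength spacing must be exactly 1 nm "
                    "(resample with resample_to_grid first)"
                )
        if not np.all(np.isfinite(self.reflectance)):
            bad = [self.sample_ids[i] for i in
                   np.unique(np.nonzero(~np.isfinite(self.reflectance))[0])]
            raise ValidationError(f"non-finite reflectance in samples: {bad}")
        if not np.all(np.isfinite(self.potassium)):
            raise ValidationError("non-finite potassium values")
        if np.any(self.potassium <= 0):
            bad = [self.sample_ids[i] for i in np.nonzero(self.potassium <= 0)[0]]
            raise ValidationError(f"non-positive potassium for samples: {bad}")
        if self.order == 0.0 and (
            self.reflectance.min() < 0.0 or self.reflectance.max() > 1.0
        ):
            raise ValidationError("raw (order 0) reflectance must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[1]

    def subset(self, indices: Sequence[int]) -> "SpectraSet":
        """Row-subset by integer indices, preserving order field."""
        idx = np.asarray(indices, dtype=int)
        return replace(
            self,
            sample_ids=[self.sample_ids[i] for i in idx],
            reflectance=self.reflectance[idx],
            potassium=self.potassium[idx],
        )

    def same_grid(self, other: "SpectraSet") -> bool:
        return (
            self.wavelengths.shape == other.wavelengths.shape
            and np.array_equal(self.wavelengths, other.wavelengths)
        )


def read_spectra_table(path: str | Path, dialect: Dialect | None = None) -> SpectraSet:
    """Read a wide-format spectra CSV into a validated :class:`SpectraSet`.

    Wavelength columns are recognised as any header parseable as a number,
    sorted ascending regardless of file order. Rows with missing reflectance
    are rejected with an error naming the offending sample ids. The result
    is always at differentiation order 0.0.
    """
    dialect = dialect or Dialect()
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in (dialect.id_col, dialect.potassium_col):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    wl_cols: list[tuple[float, str]] = []
    for c in df.columns:
        if c in (dialect.id_col, dialect.potassium_col):
            continue
        try:
            wl_cols.append((float(c), c))
        except ValueError as exc:
            raise FormatError(
                f"column {c!r} is neither {dialect.id_col!r}, "
                f"{dialect.potassium_col!r} nor a wavelength in nm"
            ) from exc
    if len(wl_cols) < 2:
        raise FormatError("need at least two numeric wavelength columns")
    wl_cols.sort(key=lambda t: t[0])
    wavelengths = np.array([w for w, _ in wl_cols])
    refl = df[[c for _, c in wl_cols]].to_numpy(dtype=float)

    ids = df[dialect.id_col].astype(str).tolist()
    missing_rows = np.unique(np.nonzero(~np.isfinite(refl))[0])
    if missing_rows.size:
        bad = [ids[i] for i in missing_rows]
        raise ValidationError(f"missing/non-numeric reflectance in samples: {bad}")
    potassium = pd.to_numeric(df[dialect.potassium_col], errors="coerce").to_numpy()
    if np.any(~np.isfinite(potassium)) or np.any(potassium <= 0):
        bad = [ids[i] for i in np.nonzero(~(potassium > 0))[0]]
        raise ValidationError(f"non-positive or missing potassium for samples: {bad}")

    steps = np.diff(wavelengths)
    uniform = np.allclose(steps, 1.0, atol=1e-9)
    s = SpectraSet.__new__(SpectraSet)  # defer validation until after resampling
    s.sample_ids, s.wavelengths, s.reflectance, s.potassium, s.order = (
        ids, wavelengths, refl, potassium, 0.0,
    )
    if not uniform:
        if dialect.on_nonuniform == "error":
            raise ValidationError("wavelength grid is not uniform 1 nm")
        lo = math.ceil(wavelengths[0])
        hi = math.floor(wavelengths[-1])
        return resample_to_grid(s, lo, hi)
    return SpectraSet(ids, wavelengths, refl, potassium, 0.0)


def resample_to_grid(s: SpectraSet, start_nm: float, end_nm: float) -> SpectraSet:
    """Linearly resample a spectra set onto the 1-nm grid [start_nm, end_nm].

    Values at wavelengths shared between the input and output grids are
    preserved exactly; the operation is the identity when the input is
    already on the requested grid.
    """
    wl = np.asarray(s.wavelengths, dtype=float)
    if start_nm < wl[0] or end_nm > wl[-1]:
        raise RangeError(
            f"requested range [{start_nm}, {end_nm}] nm exceeds data range "
            f"[{wl[0]}, {wl[-1]}] nm"
        )
    grid = np.arange(float(start_nm), float(end_nm) + 0.5, 1.0)
    if wl.shape == grid.shape and np.array_equal(wl, grid):
        return SpectraSet(s.sample_ids, wl, s.reflectance, s.potassium, s.order)
    out = np.empty((s.n_samples, grid.size))
    for i in range(s.n_samples):
        out[i] = np.interp(grid, wl, s.reflectance[i])
    # exact preservation at shared grid points (np.interp is exact there up
    # to fp lookup; enforce bitwise equality for robustness)
    shared = np.isin(grid, wl)
    if shared.any():
        src_idx = np.searchsorted(wl, grid[shared])
        out[:, shared] = s.reflectance[:, src_idx]
    return SpectraSet(s.sample_ids, grid, out, s.potassium, s.order)


#: column order of the tidy comparison-table CSV
COMPARISON_COLUMNS = [
    "model", "order", "split", "r2", "mse", "mae",
    "n_components", "hyperparams", "seed", "error",
]


def write_comparison_frame(df: pd.DataFrame, path: str | Path) -> None:
    """Write a model-comparison table as tidy CSV at full float precision."""
    if df.empty:
        raise ValidationError("refusing to write an empty comparison table")
    missing = [c for c in COMPARISON_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"comparison table missing columns: {missing}")
    df[COMPARISON_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def read_comparison_frame(path: str | Path) -> pd.DataFrame:
    """Read back a comparison CSV written by :func:`write_comparison_frame`."""
    df = pd.read_csv(
        path, dtype={"hyperparams": str, "error": str},
        float_precision="round_trip",
    )
    missing = [c for c in COMPARISON_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"comparison table missing columns: {missing}")
    return df[COMPARISON_COLUMNS]


def write_spectra_table(s: SpectraSet, path: str | Path,
                        dialect: Dialect | None = None) -> None:
    """Write a :class:`SpectraSet` in the wide CSV interchange format."""
    dialect = dialect or Dialect()
    cols = {dialect.id_col: s.sample_ids, dialect.potassium_col: s.potassium}
    wl_names = [f"{w:g}" for w in s.wavelengths]
    df = pd.DataFrame(cols)
    df = pd.concat([df, pd.DataFrame(s.reflectance, columns=wl_names)], axis=1)
    df.to_csv(path, index=False, float_format="%.17g")
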