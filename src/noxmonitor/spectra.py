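"""Absorbance-spectrum data model, validation, arithmetic and file I/O.

A :class:`Spectrum` is one UV-Vis absorbance fingerprint on a uniform
wavelength grid, with the optical pathlength and an optional acquisition
timestamp attached.  The analysis convention throughout the package is net
absorbance (blank-corrected against ultrapure water) in absorbance units
(AU), recorded at 0.5 nm resolution; the analysis window is 200-300 nm
because the spectra of the species of interest are flat above 300 nm.

Two text dialects are supported, mirroring bench spectrophotometer exports:

* long CSV  -- header ``wavelength_nm,absorbance``, one spectrum per file,
  optional ``# key: value`` metadata header lines (``label``, ``timestamp``,
  ``pathlength_cm``);
* wide CSV  -- header ``wavelength_nm,<label_1>,<label_2>,...`` holding a
  whole time series; labels that parse as ISO-8601 timestamps become the
  spectra's timestamps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    SpectrumFormatError,
    SpectrumValidationError,
    WavelengthRangeError,
)

#: absolute tolerance for comparing wavelengths (nm)
WAVELENGTH_TOL = 1e-6

#: float format used when writing spectra; wide enough for exact round-trips
_FLOAT_FMT = "%.17g"


@dataclass(frozen=True)
class WavelengthGrid:
    """A uniform wavelength grid ``start_nm .. stop_nm`` in steps of ``step_nm``."""

    start_nm: float
    stop_nm: float
    step_nm: float = 0.5

    def __post_init__(self) -> None:
        if not (self.start_nm < self.stop_nm):
            raise SpectrumValidationError(
                f"start_nm ({self.start_nm}) must be < stop_nm ({self.stop_nm})"
            )
        if not (self.step_nm > 0):
            raise SpectrumValidationError(f"step_nm must be > 0, got {self.step_nm}")
        n_steps = (self.stop_nm - self.start_nm) / self.step_nm
        if abs(n_steps - round(n_steps)) > 1e-6:
            raise SpectrumValidationError(
                f"grid span {self.start_nm}-{self.stop_nm} is not an integer "
                f"number of {self.step_nm} nm steps"
            )

    def __len__(self) -> int:
        return int(round((self.stop_nm - self.start_nm) / self.step_nm)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        n = len(self)
        return self.start_nm + self.step_nm * np.arange(n)

    def index_of(self, wavelength_nm: float) -> int:
        """Index of an exact grid point; raises if not on the grid."""
        pos = (wavelength_nm - self.start_nm) / self.step_nm
        idx = int(round(pos))
        if idx < 0 or idx >= len(self) or abs(pos - idx) * self.step_nm > WAVELENGTH_TOL:
            raise WavelengthRangeError(
                f"{wavelength_nm} nm is not a point of grid "
                f"[{self.start_nm}, {self.stop_nm}] step {self.step_nm}"
            )
        return idx

    def contains(self, wavelength_nm: float) -> bool:
        return (
            self.start_nm - WAVELENGTH_TOL
            <= wavelength_nm
            <= self.stop_nm + WAVELENGTH_TOL
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return (
            abs(self.start_nm - other.start_nm) <= WAVELENGTH_TOL
            and abs(self.stop_nm - other.stop_nm) <= WAVELENGTH_TOL
            and abs(self.step_nm - other.step_nm) <= WAVELENGTH_TOL
        )

    def __hash__(self) -> int:  # consistent with the tolerant __eq__
        return hash((round(self.start_nm, 5), round(self.stop_nm, 5), round(self.step_nm, 5)))


#: full analysis grid (instrument records to 800 nm; >300 nm is flat)
DEFAULT_GRID = WavelengthGrid(200.0, 300.0, 0.5)
#: wavelengths modelled by the chloramine-decay compensation (below the anchor)
MODELLED_GRID = WavelengthGrid(200.0, 244.5, 0.5)
#: anchor wavelength: the monochloramine absorbance maximum
ANCHOR_NM = 245.0
#: default optical pathlength of the quartz cell (cm)
DEFAULT_PATHLENGTH_CM = 10.0


def _validate_vector(grid: WavelengthGrid, values: np.ndarray, what: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.shape[0] != len(grid):
        raise SpectrumValidationError(
            f"{what} length {values.shape} does not match grid length {len(grid)}"
        )
    if not np.all(np.isfinite(values)):
        raise SpectrumValidationError(f"{what} contains non-finite values")
    return values


@dataclass(frozen=True)
class Spectrum:
    """One absorbance fingerprint.

    Negative absorbances are permitted: instrument noise on blank-corrected
    spectra can legitimately dip below zero.
    """

    grid: WavelengthGrid
    absorbance: np.ndarray
    pathlength_cm: float = DEFAULT_PATHLENGTH_CM
    timestamp: datetime | None = None
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "absorbance", _validate_vector(self.grid, self.absorbance, "absorbance")
        )
        if not (self.pathlength_cm > 0):
            raise SpectrumValidationError(
                f"pathlength_cm must be > 0, got {self.pathlength_cm}"
            )

    def value_at(self, wavelength_nm: float) -> float:
        """Absorbance at a wavelength, linearly interpolated within the span."""
        if not self.grid.contains(wavelength_nm):
            raise WavelengthRangeError(
                f"{wavelength_nm} nm outside span "
                f"[{self.grid.start_nm}, {self.grid.stop_nm}]"
            )
        return float(np.interp(wavelength_nm, self.grid.wavelengths, self.absorbance))

    def with_label(self, label: str) -> "Spectrum":
        return replace(self, label=label)


@dataclass(frozen=True)
class DifferenceSpectrum:
    """Pointwise difference between two spectra on a common grid."""

    grid: WavelengthGrid
    delta: np.ndarray
    minuend_label: str = ""
    subtrahend_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "delta", _validate_vector(self.grid, self.delta, "delta"))

    def delta_at(self, wavelength_nm: float) -> float:
        if not self.grid.contains(wavelength_nm):
            raise WavelengthRangeError(
                f"{wavelength_nm} nm outside span "
                f"[{self.grid.start_nm}, {self.grid.stop_nm}]"
            )
        return float(np.interp(wavelength_nm, self.grid.wavelengths, self.delta))


def subtract(a: Spectrum, b: Spectrum) -> DifferenceSpectrum:
    """``a - b`` pointwise; both spectra must share grid and pathlength."""
    if a.grid != b.grid:
        raise SpectrumValidationError(
            "grid mismatch: align spectra to a common grid before subtracting"
        )
    if abs(a.pathlength_cm - b.pathlength_cm) > 1e-9:
        raise SpectrumValidationError(
            f"pathlength mismatch: {a.pathlength_cm} vs {b.pathlength_cm} cm "
            "(operations do not rescale pathlengths)"
        )
    return DifferenceSpectrum(
        grid=a.grid,
        delta=a.absorbance - b.absorbance,
        minuend_label=a.label,
        subtrahend_label=b.label,
    )


def delta_at(d: DifferenceSpectrum, wavelength_nm: float) -> float:
    """Offset of a difference spectrum at one wavelength (canonical anchor: 245 nm)."""
    return d.delta_at(wavelength_nm)


def align_to_grid(s: Spectrum, grid: WavelengthGrid) -> Spectrum:
    """Resample a spectrum onto a target grid by linear interpolation.

    Exact pass-through when the grids already coincide.  The target grid must
    lie within the source span (no extrapolation).
    """
    if s.grid == grid:
        return replace(s, grid=grid)
    if (
        grid.start_nm < s.grid.start_nm - WAVELENGTH_TOL
        or grid.stop_nm > s.grid.stop_nm + WAVELENGTH_TOL
    ):
        raise WavelengthRangeError(
            f"target grid [{grid.start_nm}, {grid.stop_nm}] outside source span "
            f"[{s.grid.start_nm}, {s.grid.stop_nm}]"
        )
    values = np.interp(grid.wavelengths, s.grid.wavelengths, s.absorbance)
    return Spectrum(
        grid=grid,
        absorbance=values,
        pathlength_cm=s.pathlength_cm,
        timestamp=s.timestamp,
        label=s.label,
    )


# ---------------------------------------------------------------------------
# file I/O


def _grid_from_wavelengths(wl: np.ndarray) -> WavelengthGrid:
    if wl.size < 2:
        raise SpectrumFormatError("a spectrum needs at least two wavelength points")
    diffs = np.diff(wl)
    if np.any(diffs <= 0):
        raise SpectrumValidationError("wavelengths must be strictly increasing")
    step = float(diffs[0])
    if np.max(np.abs(diffs - step)) > WAVELENGTH_TOL:
        raise SpectrumFormatError("non-uniform wavelength spacing is not supported")
    return WavelengthGrid(float(wl[0]), float(wl[-1]), step)


def _parse_timestamp(text: str) -> datetime | None:
    try:
        return datetime.fromisoformat(text.strip())
    except (ValueError, TypeError):
        return None


def read_spectrum(path: str | Path, dialect: str = "long") -> Spectrum:
    """Read a single spectrum from a long-dialect CSV file.

    Metadata is taken from ``# key: value`` header lines when present; the
    label defaults to the file stem.
    """
    if dialect != "long":
        raise SpectrumFormatError(f"unknown single-spectrum dialect {dialect!r}")
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            if ":" in line:
                key, _, val = line.lstrip("#").partition(":")
                meta[key.strip()] = val.strip()
            body_start = i + 1
        else:
            break
    try:
        df = pd.read_csv(
            Path(path).open("r", encoding="utf-8"), skiprows=body_start
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise SpectrumFormatError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise SpectrumFormatError(f"{path}: expected two columns, got {df.shape[1]}")
    wl = pd.to_numeric(df.iloc[:, 0], errors="coerce").to_numpy()
    ab = pd.to_numeric(df.iloc[:, 1], errors="coerce").to_numpy()
    if np.any(~np.isfinite(wl)) or np.any(~np.isfinite(ab)):
        raise SpectrumFormatError(f"{path}: non-numeric values in data columns")
    grid = _grid_from_wavelengths(wl)
    return Spectrum(
        grid=grid,
        absorbance=ab,
        pathlength_cm=float(meta.get("pathlength_cm", DEFAULT_PATHLENGTH_CM)),
        timestamp=_parse_timestamp(meta["timestamp"]) if "timestamp" in meta else None,
        label=meta.get("label", path.stem),
    )


def write_spectrum(s: Spectrum, path: str | Path) -> None:
    """Write one spectrum in the long CSV dialect with metadata header lines."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if s.label:
            fh.write(f"# label: {s.label}\n")
        if s.timestamp is not None:
            fh.write(f"# timestamp: {s.timestamp.isoformat()}\n")
        fh.write(f"# pathlength_cm: {_FLOAT_FMT % s.pathlength_cm}\n")
        fh.write("wavelength_nm,absorbance\n")
        for wl, ab in zip(s.grid.wavelengths, s.absorbance):
            fh.write(f"{_FLOAT_FMT % wl},{_FLOAT_FMT % ab}\n")


def read_series(path: str | Path, pathlength_cm: float = DEFAULT_PATHLENGTH_CM) -> list[Spectrum]:
    """Read a wide-dialect CSV as a list of spectra, one per value column.

    Column labels that parse as ISO-8601 timestamps become spectrum
    timestamps, and the list is returned in increasing timestamp order.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pragma: no cover
        raise SpectrumFormatError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise SpectrumFormatError(f"{path}: expected wavelength + >=1 spectrum column")
    wl = pd.to_numeric(df.iloc[:, 0], errors="coerce").to_numpy()
    if np.any(~np.isfinite(wl)):
        raise SpectrumFormatError(f"{path}: non-numeric wavelength column")
    grid = _grid_from_wavelengths(wl)
    spectra: list[Spectrum] = []
    for col in df.columns[1:]:
        ab = pd.to_numeric(df[col], errors="coerce").to_numpy()
        if np.any(~np.isfinite(ab)):
            raise SpectrumFormatError(f"{path}: non-numeric values in column {col!r}")
        spectra.append(
            Spectrum(
                grid=grid,
                absorbance=ab,
                pathlength_cm=pathlength_cm,
                timestamp=_parse_timestamp(str(col)),
                label=str(col),
            )
        )
    if all(s.timestamp is not None for s in spectra):
        spectra.sort(key=lambda s: s.timestamp)  # type: ignore[arg-type]
    return spectra


def write_series(spectra: list[Spectrum], path: str | Path) -> None:
    """Write spectra sharing one grid as a wide CSV (one column per spectrum)."""
    if not spectra:
        raise SpectrumValidationError("cannot write an empty series")
    grid = spectra[0].grid
    for s in spectra[1:]:
        if s.grid != grid:
            raise SpectrumValidationError("all series spectra must share one grid")
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        labels = []
        for i, s in enumerate(spectra):
            if s.label:
                labels.append(s.label)
            elif s.timestamp is not None:
                labels.append(s.timestamp.isoformat())
            else:
                labels.append(f"spectrum_{i}")
        fh.write("wavelength_nm," + ",".join(labels) + "\n")
        cols = [s.absorbance for s in spectra]
        for j, wl in enumerate(grid.wavelengths):
            row = ",".join(_FLOAT_FMT % c[j] for c in cols)
            fh.write(f"{_FLOAT_FMT % wl},{row}\n")
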