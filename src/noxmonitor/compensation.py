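"""Monochloramine-decay spectral compensation anchored at 245 nm.

Monochloramine absorbs maximally at 245 nm, where nitrate and nitrite are
essentially transparent, so the absorbance drop at 245 nm between a
baseline spectrum and a later spectrum measures the decay alone.  Pure
monochloramine dilution series show that the absorbance difference between
two concentrations at any wavelength i in 200-244.5 nm is a linear function
of the difference at 245 nm.  Fitting those per-wavelength lines once on
ultrapure-water standards lets the decay contribution at every wavelength
be predicted from the single observed anchor offset of a drinking-water
sample; subtracting the predicted decay spectrum from the recorded sample
spectrum isolates the combined nitrate + nitrite (NOx) difference spectrum.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from .errors import (
    InsufficientCalibrationError,
    NotFittedError,
    NumericalError,
    SpectrumValidationError,
)
from .metrics import r_squared, rmse
from .spectra import (
    ANCHOR_NM,
    MODELLED_GRID,
    Spectrum,
    WavelengthGrid,
    align_to_grid,
)

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class DeltaDataset:
    """Pairwise absorbance differences from a monochloramine dilution series.

    Each record is one unordered pair of calibration spectra, oriented
    higher concentration minus lower (by absorbance at the anchor), so
    anchor deltas are nonnegative.
    """

    anchor_nm: float
    modelled_wavelengths: np.ndarray  # (m,)
    anchor_deltas: np.ndarray  # (n_records,)
    delta_matrix: np.ndarray  # (n_records, m)

    def __post_init__(self) -> None:
        if self.delta_matrix.shape != (
            self.anchor_deltas.shape[0],
            self.modelled_wavelengths.shape[0],
        ):
            raise SpectrumValidationError("delta_matrix shape mismatch")


@dataclass(frozen=True)
class NOxSpectrum:
    """Isolated combined nitrate + nitrite difference spectrum.

    Absorbance is relative to the series baseline; small negative values
    from noise are kept (prediction consumes unclipped values), with
    :meth:`clipped` available for display.
    """

    grid: WavelengthGrid
    absorbance: np.ndarray
    anchor_delta: float = 0.0
    baseline_timestamp: datetime | None = None
    sample_timestamp: datetime | None = None
    label: str = ""

    def clipped(self) -> np.ndarray:
        """Display variant with negatives clipped at zero."""
        return np.maximum(self.absorbance, 0.0)

    def features(self, window: tuple[float, float] = (200.0, ANCHOR_NM)) -> np.ndarray:
        """Absorbance vector on the grid points within a wavelength window."""
        wl = self.grid.wavelengths
        mask = (wl >= window[0] - 1e-9) & (wl <= window[1] + 1e-9)
        if not mask.any():
            raise SpectrumValidationError("window not covered by the spectrum grid")
        return self.absorbance[mask]


def _common_calibration_grid(spectra: list[Spectrum], anchor_nm: float) -> WavelengthGrid:
    if len(spectra) < 3:
        raise InsufficientCalibrationError(
            f"need >= 3 calibration spectra, got {len(spectra)}"
        )
    grid = spectra[0].grid
    for s in spectra[1:]:
        if s.grid != grid:
            raise SpectrumValidationError(
                "calibration spectra must share one grid (align first)"
            )
    if not (grid.contains(MODELLED_GRID.start_nm) and grid.contains(anchor_nm)):
        raise SpectrumValidationError(
            f"calibration grid must cover {MODELLED_GRID.start_nm}-{anchor_nm} nm"
        )
    return grid


def compute_pairwise_deltas(
    calibration: list[Spectrum],
    anchor_nm: float = ANCHOR_NM,
    pair_mode: str = "all",
) -> DeltaDataset:
    """Differences for concentration pairs of a monochloramine series.

    ``pair_mode='all'`` uses every unordered pair, C(n, 2) records;
    ``'baseline'`` uses only pairs against the most concentrated spectrum.
    Pairs are oriented by absorbance at the anchor so anchor deltas are >= 0.
    """
    grid = _common_calibration_grid(calibration, anchor_nm)
    if pair_mode not in ("all", "baseline"):
        raise ValueError(f"pair_mode must be 'all' or 'baseline', got {pair_mode!r}")
    wl = grid.wavelengths
    mwl = MODELLED_GRID.wavelengths
    mask = np.isin(np.round(wl * 2).astype(int), np.round(mwl * 2).astype(int))
    if mask.sum() != len(mwl):
        raise SpectrumValidationError(
            "calibration grid must contain every modelled wavelength "
            f"({MODELLED_GRID.start_nm}-{MODELLED_GRID.stop_nm} nm at "
            f"{MODELLED_GRID.step_nm} nm)"
        )
    A = np.array([s.absorbance for s in calibration])
    anchor_idx = grid.index_of(anchor_nm)
    order = np.argsort(A[:, anchor_idx])  # ascending concentration proxy
    A = A[order]
    n = A.shape[0]
    if pair_mode == "all":
        pairs = [(hi, lo) for lo in range(n) for hi in range(lo + 1, n)]
    else:
        pairs = [(n - 1, lo) for lo in range(n - 1)]
    anchor_deltas = np.array([A[hi, anchor_idx] - A[lo, anchor_idx] for hi, lo in pairs])
    delta_matrix = np.array([A[hi, mask] - A[lo, mask] for hi, lo in pairs])
    return DeltaDataset(
        anchor_nm=anchor_nm,
        modelled_wavelengths=mwl,
        anchor_deltas=anchor_deltas,
        delta_matrix=delta_matrix,
    )


class ChloramineCompensation(BaseEstimator):
    """Per-wavelength linear model of decay offsets against the 245 nm anchor.

    For each modelled wavelength i (200-244.5 nm, 0.5 nm steps) an ordinary
    least-squares line ``delta_i = slope_i * delta_245 + intercept_i`` is fit
    to the pairwise differences of a pure-monochloramine dilution series.
    On clean Beer-Lambert data the slopes recover the absorptivity ratio
    eps(i)/eps(245) and the intercepts vanish; fitted intercepts are kept as
    a diagnostic of real-data deviations.

    Parameters
    ----------
    anchor_nm : float, default 245.0
        Anchor wavelength (the monochloramine absorbance maximum).
    pair_mode : {'all', 'baseline'}, default 'all'
        Which concentration pairs of the calibration series enter the fit.

    Attributes
    ----------
    slope_, intercept_ : ndarray of shape (90,)
        Per-wavelength line coefficients on the modelled grid.
    fit_r2_, fit_rmse_ : ndarray of shape (90,)
        Per-wavelength goodness of fit (squared Pearson correlation and
        root mean squared error of the line).
    modelled_wavelengths_ : ndarray of shape (90,)
    n_records_ : int
        Number of concentration pairs used.
    """

    def __init__(self, anchor_nm: float = ANCHOR_NM, pair_mode: str = "all"):
        self.anchor_nm = anchor_nm
        self.pair_mode = pair_mode

    # -- fitting -----------------------------------------------------------

    def fit(self, spectra: list[Spectrum], y=None) -> "ChloramineCompensation":
        """Fit from a pure-monochloramine calibration series (>= 3 spectra)."""
        data = compute_pairwise_deltas(spectra, self.anchor_nm, self.pair_mode)
        return self.fit_deltas(data)

    def fit_deltas(self, data: DeltaDataset) -> "ChloramineCompensation":
        """Fit from a precomputed :class:`DeltaDataset`."""
        x = data.anchor_deltas
        if x.shape[0] < 3:
            raise InsufficientCalibrationError(
                f"need >= 3 delta records, got {x.shape[0]}"
            )
        if np.ptp(x) <= 1e-15:
            raise NumericalError(
                "all anchor deltas are equal: calibration concentrations are "
                "degenerate, the per-wavelength lines are rank deficient"
            )
        Y = data.delta_matrix
        xc = x - x.mean()
        slope = (xc @ (Y - Y.mean(axis=0))) / (xc @ xc)
        intercept = Y.mean(axis=0) - slope * x.mean()
        fitted = np.outer(x, slope) + intercept
        resid = Y - fitted
        m = Y.shape[1]
        r2 = np.empty(m)
        rm = np.empty(m)
        for i in range(m):
            rm[i] = rmse(Y[:, i], fitted[:, i])
            if np.ptp(Y[:, i]) <= 1e-15 and rm[i] <= 1e-15:
                r2[i] = 1.0  # exact fit of a degenerate column
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    r2[i] = r_squared(Y[:, i], fitted[:, i])
        self.modelled_wavelengths_ = data.modelled_wavelengths
        self.slope_ = slope
        self.intercept_ = intercept
        self.fit_r2_ = np.nan_to_num(r2, nan=0.0)
        self.fit_rmse_ = rm
        self.n_records_ = int(x.shape[0])
        self.anchor_nm_ = float(data.anchor_nm)
        self.anchor_delta_range_ = (float(x.min()), float(x.max()))
        # log-quadratic fit of the slopes vs distance from the anchor: exact
        # for a Gaussian band, used to extrapolate the fall-off beyond the
        # anchor's mirror range (see _tail_delta)
        pos = slope > 0
        if pos.sum() >= 3:
            xq = data.modelled_wavelengths[pos] - self.anchor_nm_
            self._tail_coef_ = np.polyfit(xq, np.log(slope[pos]), 2)
        else:  # pragma: no cover - degenerate calibration
            self._tail_coef_ = None
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "slope_"):
            raise NotFittedError("ChloramineCompensation is not fitted")

    # -- prediction --------------------------------------------------------

    def predict_deltas(self, delta_anchor: float) -> np.ndarray:
        """Predicted decay offsets on the modelled grid for one anchor offset.

        A negative anchor (absorbance rose at 245 nm, which decay cannot
        produce) triggers a warning and zero compensation.
        """
        self._check_fitted()
        if delta_anchor < 0:
            warnings.warn(
                f"negative anchor delta {delta_anchor:.4g} AU (absorbance rose "
                "at 245 nm): applying zero compensation",
                RuntimeWarning,
            )
            return np.zeros_like(self.slope_)
        return self.slope_ * float(delta_anchor) + self.intercept_

    def _tail_delta(self, wavelength: float, delta_anchor: float) -> float:
        """Decay offset beyond the anchor via the mirrored-band assumption.

        The monochloramine band is symmetric about its 245 nm apex, so the
        offset at 245 + d is taken equal to the modelled offset at 245 - d.
        Beyond the mirror range the fall-off follows the band shape
        extrapolated from the fitted slopes (a log-quadratic, exact for a
        Gaussian band).  NOx quantification only uses wavelengths <= 245 nm,
        so this choice cannot affect concentrations.
        """
        mirror = 2.0 * self.anchor_nm_ - wavelength
        mwl = self.modelled_wavelengths_
        if mirror >= mwl[0] - 1e-9:
            pred = self.slope_ * delta_anchor + self.intercept_
            return float(np.interp(mirror, mwl, pred))
        if self._tail_coef_ is None:  # pragma: no cover
            return 0.0
        slope = math.exp(np.polyval(self._tail_coef_, wavelength - self.anchor_nm_))
        return slope * delta_anchor

    def estimate_decay_spectrum(
        self, baseline: Spectrum, delta_anchor: float
    ) -> Spectrum:
        """Baseline minus predicted decay offsets: the spectrum at time t
        attributable to NOM + remaining monochloramine only."""
        self._check_fitted()
        grid = baseline.grid
        if not (grid.contains(self.modelled_wavelengths_[0]) and grid.contains(self.anchor_nm_)):
            raise SpectrumValidationError(
                "baseline grid must cover the modelled range and the anchor"
            )
        deltas = self.predict_deltas(delta_anchor)
        effective_anchor = max(float(delta_anchor), 0.0)
        wl = grid.wavelengths
        est = baseline.absorbance.astype(float).copy()
        for j, lam in enumerate(wl):
            if lam < self.modelled_wavelengths_[0] - 1e-9:
                continue  # below the modelled range: no compensation
            if lam <= self.modelled_wavelengths_[-1] + 1e-9:
                est[j] -= float(np.interp(lam, self.modelled_wavelengths_, deltas))
            elif abs(lam - self.anchor_nm_) <= 1e-9:
                est[j] -= effective_anchor
            else:
                est[j] -= self._tail_delta(lam, effective_anchor)
        return Spectrum(
            grid=grid,
            absorbance=est,
            pathlength_cm=baseline.pathlength_cm,
            timestamp=baseline.timestamp,
            label=f"decay_estimate({baseline.label})",
        )

    def isolate(self, baseline: Spectrum, sample: Spectrum) -> NOxSpectrum:
        """Full compensation step: observed anchor offset -> predicted decay
        spectrum -> isolated NOx difference spectrum."""
        if baseline.grid != sample.grid:
            raise SpectrumValidationError("baseline and sample grids differ")
        delta_anchor = baseline.value_at(self.anchor_nm) - sample.value_at(self.anchor_nm)
        estimated = self.estimate_decay_spectrum(baseline, delta_anchor)
        out = isolate_nox(sample, estimated)
        return NOxSpectrum(
            grid=out.grid,
            absorbance=out.absorbance,
            anchor_delta=float(delta_anchor),
            baseline_timestamp=baseline.timestamp,
            sample_timestamp=sample.timestamp,
            label=sample.label,
        )

    def transform(self, series: list[Spectrum]) -> list[NOxSpectrum]:
        """Isolate NOx spectra for a time series; the first spectrum is the
        baseline (re-baseline by passing a different leading spectrum)."""
        if len(series) < 2:
            raise SpectrumValidationError("a series needs a baseline plus >= 1 sample")
        baseline = series[0]
        return [self.isolate(baseline, s) for s in series[1:]]

    # -- persistence -------------------------------------------------------

    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "schema_version": SCHEMA_VERSION,
            "kind": "chloramine_compensation",
            "anchor_nm": self.anchor_nm_,
            "pair_mode": self.pair_mode,
            "wavelengths_nm": [float(w) for w in self.modelled_wavelengths_],
            "slope": [float(v) for v in self.slope_],
            "intercept": [float(v) for v in self.intercept_],
            "fit_r2": [float(v) for v in self.fit_r2_],
            "fit_rmse": [float(v) for v in self.fit_rmse_],
            "tail_logslope_coef": (
                None if self._tail_coef_ is None else [float(c) for c in self._tail_coef_]
            ),
            "provenance": {
                "n_records": self.n_records_,
                "anchor_delta_range_AU": list(self.anchor_delta_range_),
            },
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), sort_keys=True, indent=1) + "\n", encoding="utf-8"
        )

    @classmethod
    def from_dict(cls, d: dict) -> "ChloramineCompensation":
        model = cls(anchor_nm=d["anchor_nm"], pair_mode=d.get("pair_mode", "all"))
        model.modelled_wavelengths_ = np.asarray(d["wavelengths_nm"], dtype=float)
        model.slope_ = np.asarray(d["slope"], dtype=float)
        model.intercept_ = np.asarray(d["intercept"], dtype=float)
        model.fit_r2_ = np.asarray(d["fit_r2"], dtype=float)
        model.fit_rmse_ = np.asarray(d["fit_rmse"], dtype=float)
        model.n_records_ = int(d["provenance"]["n_records"])
        model.anchor_delta_range_ = tuple(d["provenance"]["anchor_delta_range_AU"])
        model.anchor_nm_ = float(d["anchor_nm"])
        coef = d.get("tail_logslope_coef")
        model._tail_coef_ = None if coef is None else np.asarray(coef, dtype=float)
        return model

    @classmethod
    def load(cls, path: str | Path) -> "ChloramineCompensation":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


# ---------------------------------------------------------------------------
# module-level operations (thin wrappers over the estimator)


def fit_compensation(data: DeltaDataset) -> ChloramineCompensation:
    """Fit the per-wavelength compensation lines from a delta dataset."""
    return ChloramineCompensation().fit_deltas(data)


def predict_deltas(model: ChloramineCompensation, delta_anchor: float) -> np.ndarray:
    return model.predict_deltas(delta_anchor)


def estimate_decay_spectrum(
    model: ChloramineCompensation, baseline: Spectrum, delta_anchor: float
) -> Spectrum:
    return model.estimate_decay_spectrum(baseline, delta_anchor)


def isolate_nox(sample: Spectrum, estimated_decay: Spectrum) -> NOxSpectrum:
    """Sample spectrum minus estimated decay spectrum = NOx spectrum."""
    if sample.grid != estimated_decay.grid:
        raise SpectrumValidationError("sample and decay-estimate grids differ")
    return NOxSpectrum(
        grid=sample.grid,
        absorbance=sample.absorbance - estimated_decay.absorbance,
        sample_timestamp=sample.timestamp,
        baseline_timestamp=estimated_decay.timestamp,
        label=sample.label,
    )
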