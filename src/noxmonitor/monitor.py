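"""End-to-end nitrification monitoring of a spectral time series.

For each spectrum after the baseline: observed 245 nm offset -> predicted
per-wavelength decay offsets -> estimated NOM + monochloramine spectrum ->
isolated NOx spectrum -> kernel-regression NOx-N estimate (optionally
locally calibrated) -> alert check.  The default alert threshold of
0.05 mg-N/L follows water-utility guidance that a nitrite rise of that size
indicates nitrification; it is applied here to the combined NOx-N change
and is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
import pandas as pd

from .compensation import ChloramineCompensation
from .errors import ConfigurationError, SpectrumValidationError
from .regression import LocalCalibration, NOxRegressor, predict_nox
from .spectra import DEFAULT_GRID, Spectrum, align_to_grid

DEFAULT_ALERT_THRESHOLD = 0.05  # mg-N/L


@dataclass(frozen=True)
class MonitoringRow:
    """Per-timestamp monitoring output."""

    timestamp: datetime | None
    label: str
    delta245_AU: float
    nox_rel_mgN_L: float
    nox_cal_mgN_L: float | None
    extrapolated: bool
    alert: bool


@dataclass
class MonitoringResult:
    """Monitoring series output: per-timestamp rows plus series metadata."""

    baseline_label: str
    threshold_mgN_L: float
    rows: list[MonitoringRow] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    baseline_nox_mgN_L: float = 0.0

    @property
    def n_alerts(self) -> int:
        return sum(r.alert for r in self.rows)

    @property
    def first_alert(self) -> MonitoringRow | None:
        for r in self.rows:
            if r.alert:
                return r
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": [
                    r.timestamp.isoformat() if r.timestamp else r.label for r in self.rows
                ],
                "delta245_AU": [r.delta245_AU for r in self.rows],
                "nox_rel_mgN_L": [r.nox_rel_mgN_L for r in self.rows],
                "nox_cal_mgN_L": [
                    "" if r.nox_cal_mgN_L is None else r.nox_cal_mgN_L for r in self.rows
                ],
                "extrapolated": [r.extrapolated for r in self.rows],
                "alert": [r.alert for r in self.rows],
            }
        )

    def summary(self) -> dict:
        return {
            "baseline": self.baseline_label,
            "baseline_nox_mgN_L": self.baseline_nox_mgN_L,
            "threshold_mgN_L": self.threshold_mgN_L,
            "n_timestamps": len(self.rows),
            "n_alerts": self.n_alerts,
            "first_alert": (
                self.first_alert.timestamp.isoformat()
                if self.first_alert and self.first_alert.timestamp
                else (self.first_alert.label if self.first_alert else None)
            ),
            "max_nox_rel_mgN_L": max((r.nox_rel_mgN_L for r in self.rows), default=0.0),
            "warnings": self.warnings,
        }


def run_monitoring(
    series: list[Spectrum],
    compensation: ChloramineCompensation,
    regressor: NOxRegressor,
    threshold: float = DEFAULT_ALERT_THRESHOLD,
    local_calibration: LocalCalibration | None = None,
    baseline_nox_mgN_L: float = 0.0,
) -> MonitoringResult:
    """Run the full pipeline over a time series; the first spectrum is the
    baseline.

    Timestamps, when present, must be strictly increasing.  The alert flag
    compares the locally calibrated estimate when a calibration is supplied,
    else the raw estimate, against the threshold.
    """
    if len(series) < 2:
        raise ConfigurationError("monitoring needs a baseline plus >= 1 spectrum")
    stamps = [s.timestamp for s in series]
    if all(t is not None for t in stamps):
        if any(b <= a for a, b in zip(stamps, stamps[1:])):  # type: ignore[operator]
            raise SpectrumValidationError("series timestamps must be strictly increasing")
    target = DEFAULT_GRID
    if not all(
        s.grid.contains(target.start_nm) and s.grid.contains(target.stop_nm) for s in series
    ):
        target = series[0].grid
    aligned = [align_to_grid(s, target) for s in series]
    baseline = aligned[0]
    result = MonitoringResult(
        baseline_label=baseline.label or "baseline",
        threshold_mgN_L=threshold,
        baseline_nox_mgN_L=baseline_nox_mgN_L,
    )
    for sample in aligned[1:]:
        delta245 = baseline.value_at(compensation.anchor_nm_) - sample.value_at(
            compensation.anchor_nm_
        )
        if delta245 < 0:
            result.warnings.append(
                f"{sample.label or sample.timestamp}: negative anchor delta "
                f"{delta245:.4g} AU (absorbance rose at 245 nm); no compensation applied"
            )
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            nox = compensation.isolate(baseline, sample)
        raw, extrapolated = predict_nox(regressor, nox)
        if extrapolated:
            result.warnings.append(
                f"{sample.label or sample.timestamp}: prediction beyond the "
                f"{regressor.max_label_:g} mg-N/L training ceiling (extrapolated)"
            )
        cal = (
            float(local_calibration.predict(np.array([raw]))[0])
            if local_calibration is not None
            else None
        )
        value_for_alert = cal if cal is not None else raw
        result.rows.append(
            MonitoringRow(
                timestamp=sample.timestamp,
                label=sample.label,
                delta245_AU=float(delta245),
                nox_rel_mgN_L=raw,
                nox_cal_mgN_L=cal,
                extrapolated=extrapolated,
                alert=value_for_alert >= threshold,
            )
        )
    return result
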