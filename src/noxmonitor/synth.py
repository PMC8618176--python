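"""Synthetic UV-Vis spectra with known ground truth.

Generates component extinction curves, Beer-Lambert mixtures, and
chloramine-decay / nitrification time courses for the four light-absorbing
constituents of chloraminated drinking water in the 200-300 nm window:

* monochloramine (NH2Cl) -- single symmetric band peaking at 245 nm;
* nitrite (as N)         -- primary band at 210 nm, weak secondary at 355 nm;
* nitrate (as N)         -- primary band at 205 nm with a long-wavelength
                            shoulder, weak secondary at 302 nm;
* NOM (as DOC)           -- featureless exponential continuum decreasing
                            with wavelength.

Free ammonia and free chlorine are treated as spectrally inert at drinking
water concentrations, and dichloramine is excluded (its residual is kept
below 0.1 mg/L by high-pH chloramination in practice).  Band positions,
orderings (nitrate absorbs more strongly than nitrite per mg-N at their
peaks) and crossings are fixed by the chemistry; absolute absorptivity
amplitudes are realistic free parameters of the generator.

Absorptivity units: AU per (mg/L) per cm for chemical species (per mg-N/L
for the nitrogen species) and AU per (mg-C/L) per cm for NOM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from datetime import datetime, timedelta

import numpy as np

from .errors import ConfigurationError, NoxMonitorError
from .spectra import (
    DEFAULT_GRID,
    DEFAULT_PATHLENGTH_CM,
    Spectrum,
    WavelengthGrid,
)

SPECIES = ("monochloramine", "nitrite_N", "nitrate_N", "NOM")

# Band parameters: (center nm, width sigma nm, amplitude AU cm^-1 (mg/L)^-1,
# cutoff distance nm or None).  Nitrogen-species bands are truncated
# Gaussians that reach exactly zero at the cutoff: real nitrate and nitrite
# are transparent (<0.1% of peak absorptivity) between their primary band
# and the weak secondary band, and that transparency at the 245 nm anchor is
# what lets the decay offset there be read as monochloramine-only.  The
# nitrite secondary sits at 355 nm and the nitrate secondary at 302 nm; both
# are far too weak to quantify below ~10 mg-N/L, which is why the method
# works from the primary bands only.
_BANDS: dict[str, list[tuple[float, float, float, float | None]]] = {
    "monochloramine": [(245.0, 22.0, 0.0086, None)],
    "nitrite_N": [(210.0, 10.0, 0.30, 29.0), (355.0, 12.0, 0.004, 40.0)],
    "nitrate_N": [
        (205.0, 8.0, 0.45, 33.0),
        (220.0, 10.0, 0.02, 19.0),
        (302.0, 12.0, 0.0015, 42.0),
    ],
}
# NOM continuum: amp * exp(-k * (lambda - 200))
_NOM_AMP = 0.055
_NOM_K = 0.015

_EPOCH = datetime(2021, 1, 1)


@dataclass(frozen=True)
class ExtinctionCurve:
    """Per-wavelength absorptivity of one species on a grid."""

    species: str
    grid: WavelengthGrid
    epsilon: np.ndarray


def _band(
    wl: np.ndarray, center: float, sigma: float, amp: float, cutoff: float | None
) -> np.ndarray:
    """Gaussian band, optionally truncated to exact zero beyond ``cutoff`` nm.

    The truncated form ``amp * max(0, g - g_cut) / (1 - g_cut)`` keeps the
    apex amplitude while pinning the far tails at zero, matching how real
    ion bands vanish between their primary and secondary peaks.
    """
    g = np.exp(-0.5 * ((wl - center) / sigma) ** 2)
    if cutoff is None:
        return amp * g
    g_cut = math.exp(-0.5 * (cutoff / sigma) ** 2)
    return amp * np.maximum(g - g_cut, 0.0) / (1.0 - g_cut)


def component_curve(species: str, grid: WavelengthGrid = DEFAULT_GRID) -> ExtinctionCurve:
    """Deterministic extinction curve of one species on a grid."""
    if species not in SPECIES:
        raise ValueError(f"unknown species {species!r}; expected one of {SPECIES}")
    wl = grid.wavelengths
    if species == "NOM":
        eps = _NOM_AMP * np.exp(-_NOM_K * (wl - 200.0))
    else:
        eps = np.zeros_like(wl)
        for center, sigma, amp, cutoff in _BANDS[species]:
            eps += _band(wl, center, sigma, amp, cutoff)
    return ExtinctionCurve(species=species, grid=grid, epsilon=eps)


@dataclass(frozen=True)
class MixtureState:
    """Ground-truth concentrations of one water sample.

    Free ammonia (``c_nh3_N``) is tracked for nitrogen bookkeeping but
    contributes no absorbance.
    """

    c_nh2cl: float = 0.0  # mg/L
    c_no2_N: float = 0.0  # mg-N/L
    c_no3_N: float = 0.0  # mg-N/L
    c_nh3_N: float = 0.0  # mg-N/L, spectrally inert
    c_doc: float = 0.0  # mg-C/L

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")

    @property
    def c_nox_N(self) -> float:
        return self.c_no2_N + self.c_no3_N


def compose_spectrum(
    state: MixtureState,
    grid: WavelengthGrid = DEFAULT_GRID,
    pathlength_cm: float = DEFAULT_PATHLENGTH_CM,
    noise_sd: float = 0.0,
    saturation_AU: float | None = None,
    seed: int | None = None,
    timestamp: datetime | None = None,
    label: str = "",
) -> Spectrum:
    """Beer-Lambert superposition of the mixture's components plus noise.

    ``A(lambda) = L * sum_s eps_s(lambda) * c_s + N(0, noise_sd)``, clipped
    at ``saturation_AU`` when given (an idealised hard detector ceiling).
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    wl = grid.wavelengths
    a = np.zeros_like(wl)
    for species, conc in (
        ("monochloramine", state.c_nh2cl),
        ("nitrite_N", state.c_no2_N),
        ("nitrate_N", state.c_no3_N),
        ("NOM", state.c_doc),
    ):
        if conc:
            a += conc * component_curve(species, grid).epsilon
    a *= pathlength_cm
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        a = a + rng.normal(0.0, noise_sd, size=a.shape)
    if saturation_AU is not None:
        a = np.minimum(a, saturation_AU)
    return Spectrum(
        grid=grid,
        absorbance=a,
        pathlength_cm=pathlength_cm,
        timestamp=timestamp,
        label=label,
    )


def apparent_peak_nm(
    s: Spectrum, window: tuple[float, float] | None = None, tol_AU: float = 1e-12
) -> float:
    """Wavelength of maximum absorbance; midpoint of the plateau if saturated.

    A detector ceiling flattens a band apex into a plateau of equal maxima;
    the conventional peak-picking rule then reports the plateau midpoint,
    which is how a saturated asymmetric band shows an apparent peak shift.
    """
    wl = s.grid.wavelengths
    ab = s.absorbance
    if window is not None:
        mask = (wl >= window[0] - 1e-9) & (wl <= window[1] + 1e-9)
        wl, ab = wl[mask], ab[mask]
    peak = ab.max()
    at_peak = wl[ab >= peak - tol_AU]
    return float(0.5 * (at_peak[0] + at_peak[-1]))


@dataclass(frozen=True)
class DecayScenario:
    """A chloramine-decay / nitrification time course.

    Monochloramine decays first-order at ``k_decay``; each mg of NH2Cl lost
    releases ``ammonia_yield`` mg-N of free ammonia, which joins any initial
    free ammonia in a convertible pool.  After ``nitrification_onset`` the
    pool converts to NOx-N along a logistic curve of rate
    ``nitrification_rate`` (normalised so conversion is exactly zero at
    t = 0), split between nitrite and nitrate by ``nitrite_fraction``.
    DOC drifts linearly by ``doc_drift`` over the horizon.
    """

    initial: MixtureState
    k_decay: float = 0.0  # 1/day
    nitrification_onset: float = 0.0  # day
    nitrification_rate: float = 0.0  # 1/day
    doc_drift: float = 0.0  # mg-C/L over the horizon, |drift| <= 0.2
    horizon_days: float = 56.0
    sample_times: tuple[float, ...] = tuple(float(t) for t in range(0, 57, 7))
    noise_sd: float = 0.0  # AU
    seed: int = 0
    ammonia_yield: float = 0.25  # mg-N released per mg NH2Cl decayed
    nitrite_fraction: float = 0.5  # share of converted N appearing as nitrite

    def __post_init__(self) -> None:
        if self.k_decay < 0:
            raise ValueError("k_decay must be >= 0")
        if self.horizon_days <= 0:
            raise ValueError("horizon_days must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.sample_times:
            raise ValueError("sample_times must not be empty")
        if not 0.0 <= self.nitrite_fraction <= 1.0:
            raise ValueError("nitrite_fraction must be in [0, 1]")
        if abs(self.doc_drift) > 0.2 + 1e-12:
            raise ValueError("DOC is assumed stable: |doc_drift| must be <= 0.2 mg-C/L")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sample_times"] = list(self.sample_times)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DecayScenario":
        d = dict(d)
        try:
            d["initial"] = MixtureState(**d.get("initial", {}))
            if "sample_times" in d:
                d["sample_times"] = tuple(float(t) for t in d["sample_times"])
            return cls(**d)
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigurationError(f"invalid scenario: {exc}") from exc


def state_at(scenario: DecayScenario, t: float) -> MixtureState:
    """Ground-truth mixture state of a scenario at time ``t`` (days)."""
    init = scenario.initial
    c_nh2cl = init.c_nh2cl * math.exp(-scenario.k_decay * t)
    released = scenario.ammonia_yield * (init.c_nh2cl - c_nh2cl)
    pool = init.c_nh3_N + released
    if scenario.nitrification_rate > 0:
        f = lambda x: 1.0 / (
            1.0 + math.exp(-scenario.nitrification_rate * (x - scenario.nitrification_onset))
        )
        f0 = f(0.0)
        g = max(0.0, (f(t) - f0) / (1.0 - f0))
    else:
        g = 0.0
    converted = pool * g
    doc = init.c_doc + scenario.doc_drift * t / scenario.horizon_days
    return MixtureState(
        c_nh2cl=c_nh2cl,
        c_no2_N=init.c_no2_N + scenario.nitrite_fraction * converted,
        c_no3_N=init.c_no3_N + (1.0 - scenario.nitrite_fraction) * converted,
        c_nh3_N=pool - converted,
        c_doc=doc,
    )


def simulate_decay_series(
    scenario: DecayScenario,
    grid: WavelengthGrid = DEFAULT_GRID,
    pathlength_cm: float = DEFAULT_PATHLENGTH_CM,
) -> tuple[list[Spectrum], list[MixtureState]]:
    """One spectrum and ground-truth state per sample time.

    Nitrogen bookkeeping is conserved: released ammonia-N plus initial free
    ammonia-N equals converted NOx-N plus remaining free ammonia-N at every
    time point.  Same seed, same series, bit for bit.
    """
    rng = np.random.default_rng(scenario.seed)
    spectra: list[Spectrum] = []
    states: list[MixtureState] = []
    for t in scenario.sample_times:
        st = state_at(scenario, float(t))
        ts = _EPOCH + timedelta(days=float(t))
        noise_seed = int(rng.integers(0, 2**31 - 1)) if scenario.noise_sd > 0 else None
        spectra.append(
            compose_spectrum(
                st,
                grid=grid,
                pathlength_cm=pathlength_cm,
                noise_sd=scenario.noise_sd,
                seed=noise_seed,
                timestamp=ts,
                label=ts.isoformat(),
            )
        )
        states.append(st)
    return spectra, states


# ---------------------------------------------------------------------------
# standards and training sets

_ATOMIC_MASS = {"K": 39.098, "N": 14.007, "O": 15.999, "Na": 22.990}
_MOLAR_MASS = {
    "KNO3": _ATOMIC_MASS["K"] + _ATOMIC_MASS["N"] + 3 * _ATOMIC_MASS["O"],
    "NaNO2": _ATOMIC_MASS["Na"] + _ATOMIC_MASS["N"] + 2 * _ATOMIC_MASS["O"],
}


def standard_solution_mass(
    compound: str, target_mg_N_per_L: float, volume_L: float
) -> float:
    """Grams of dry salt needed for a standard of given nitrogen concentration.

    The nitrogen basis is explicit: the returned mass yields
    ``target_mg_N_per_L`` milligrams of N per litre, not milligrams of the
    anion.
    """
    if compound not in _MOLAR_MASS:
        raise ValueError(f"unknown compound {compound!r}; expected KNO3 or NaNO2")
    if target_mg_N_per_L < 0:
        raise ValueError("target concentration must be >= 0")
    if volume_L <= 0:
        raise ValueError("volume must be > 0")
    mg = target_mg_N_per_L * volume_L * _MOLAR_MASS[compound] / _ATOMIC_MASS["N"]
    return mg / 1000.0


#: default standard levels for the NOx training mixtures (mg-N/L each species)
DEFAULT_NOX_LEVELS = (
    0.0, 0.001, 0.005, 0.01, 0.025, 0.05, 0.1, 0.15,
    0.2, 0.3, 0.45, 0.6, 0.8, 1.0, 1.2,
)
#: per-species ceiling of the training design (combined ceiling is twice this)
MAX_TRAINING_LEVEL = 1.2


def make_nox_training_set(
    grid: WavelengthGrid = DEFAULT_GRID,
    nitrite_levels: tuple[float, ...] | None = None,
    nitrate_levels: tuple[float, ...] | None = None,
    noise_sd: float = 0.001,
    seed: int = 0,
    pathlength_cm: float = DEFAULT_PATHLENGTH_CM,
) -> tuple[list[Spectrum], np.ndarray]:
    """Cartesian nitrite x nitrate standard mixtures with combined-N labels.

    Mixtures contain only the two nitrogen species (standards in ultrapure
    water); each label is ``c_no2_N + c_no3_N``, up to 2.4 mg-N/L with the
    default per-species levels.
    """
    nitrite_levels = DEFAULT_NOX_LEVELS if nitrite_levels is None else tuple(nitrite_levels)
    nitrate_levels = DEFAULT_NOX_LEVELS if nitrate_levels is None else tuple(nitrate_levels)
    for lv in (*nitrite_levels, *nitrate_levels):
        if lv < 0:
            raise ValueError(f"standard levels must be >= 0, got {lv}")
        if lv > MAX_TRAINING_LEVEL + 1e-12:
            raise ValueError(
                f"standard level {lv} exceeds the {MAX_TRAINING_LEVEL} mg-N/L "
                "per-species design ceiling"
            )
    rng = np.random.default_rng(seed)
    spectra: list[Spectrum] = []
    labels: list[float] = []
    for c_no2 in nitrite_levels:
        for c_no3 in nitrate_levels:
            state = MixtureState(c_no2_N=c_no2, c_no3_N=c_no3)
            noise_seed = int(rng.integers(0, 2**31 - 1)) if noise_sd > 0 else None
            spectra.append(
                compose_spectrum(
                    state,
                    grid=grid,
                    pathlength_cm=pathlength_cm,
                    noise_sd=noise_sd,
                    seed=noise_seed,
                    label=f"no2_{c_no2}_no3_{c_no3}",
                )
            )
            labels.append(c_no2 + c_no3)
    return spectra, np.asarray(labels)


def monochloramine_dilution_series(
    concentrations: tuple[float, ...] = tuple(np.linspace(0.2, 5.0, 10).round(6)),
    grid: WavelengthGrid = DEFAULT_GRID,
    doc: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    pathlength_cm: float = DEFAULT_PATHLENGTH_CM,
) -> tuple[list[Spectrum], tuple[float, ...]]:
    """Pure-monochloramine calibration spectra over 0.2-5 mg/L.

    Emulates the successive-dilution standards used to establish the
    per-wavelength decay compensation; returned in ascending concentration.
    """
    conc = tuple(sorted(float(c) for c in concentrations))
    rng = np.random.default_rng(seed)
    spectra = []
    for c in conc:
        noise_seed = int(rng.integers(0, 2**31 - 1)) if noise_sd > 0 else None
        spectra.append(
            compose_spectrum(
                MixtureState(c_nh2cl=c, c_doc=doc),
                grid=grid,
                pathlength_cm=pathlength_cm,
                noise_sd=noise_sd,
                seed=noise_seed,
                label=f"nh2cl_{c:g}",
            )
        )
    return spectra, conc


def preset_scenarios(noise_sd: float = 0.001, seed: int = 0) -> dict[str, DecayScenario]:
    """Six bench-test scenarios: unprocessed / filtered / enhanced water at
    two initial monochloramine levels (4.3 and 1.3 mg/L).

    Filtering removes most nitrifying bacteria (conversion suppressed);
    enhancement adds back the filter retentate plus 0.8 mg-N/L ammonia
    (conversion accelerated).  The high-residual enhanced sample still
    nitrifies more slowly than the low-residual one because the stronger
    disinfectant residual suppresses microbial growth.
    """
    weekly = tuple(float(t) for t in range(0, 57, 7))
    out: dict[str, DecayScenario] = {}
    for i, (c0, site) in enumerate(((4.3, "wtp"), (1.3, "net")), start=0):
        base = MixtureState(c_nh2cl=c0, c_doc=1.0)
        enhanced = MixtureState(c_nh2cl=c0, c_doc=1.0, c_nh3_N=0.8)
        variants = {
            f"sample{3 * i + 1}_{site}_unprocessed": DecayScenario(
                initial=base, k_decay=0.06, nitrification_onset=21.0,
                nitrification_rate=0.08, sample_times=weekly,
                noise_sd=noise_sd, seed=seed + 3 * i + 1,
            ),
            f"sample{3 * i + 2}_{site}_filtered": DecayScenario(
                initial=base, k_decay=0.04, nitrification_rate=0.0,
                sample_times=weekly, noise_sd=noise_sd, seed=seed + 3 * i + 2,
            ),
            f"sample{3 * i + 3}_{site}_enhanced": DecayScenario(
                initial=enhanced, k_decay=0.10,
                nitrification_onset=7.0 if c0 < 2 else 21.0,
                nitrification_rate=0.30 if c0 < 2 else 0.10,
                sample_times=weekly, noise_sd=noise_sd, seed=seed + 3 * i + 3,
            ),
        }
        out.update(variants)
    return out
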