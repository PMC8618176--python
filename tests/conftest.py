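import numpy as np
import pytest
from hypothesis import settings

import noxmonitor as nm

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_calibration():
    """Noise-free 10-level pure-monochloramine dilution series, 0.2-5 mg/L."""
    spectra, conc = nm.monochloramine_dilution_series(noise_sd=0.0)
    return spectra, conc


@pytest.fixture(scope="session")
def clean_compensation(clean_calibration):
    spectra, _ = clean_calibration
    return nm.ChloramineCompensation().fit(spectra)


@pytest.fixture(scope="session")
def clean_training():
    """Noise-free nitrite x nitrate standards design with combined labels."""
    spectra, y = nm.make_nox_training_set(noise_sd=0.0)
    X = nm.features_from_spectra(spectra)
    return X, y


@pytest.fixture(scope="session")
def clean_model_report(clean_training):
    X, y = clean_training
    return nm.grid_search_train(X, y, seed=1)


@pytest.fixture(scope="session")
def noisy_model_report():
    spectra, y = nm.make_nox_training_set(seed=3)  # default 0.001 AU noise
    X = nm.features_from_spectra(spectra)
    return nm.grid_search_train(X, y, seed=1)


@pytest.fixture(scope="session")
def nitrifying_scenario():
    """Noise-free nitrifying time course reaching ~0.5 mg-N/L by day 56."""
    return nm.DecayScenario(
        initial=nm.MixtureState(c_nh2cl=1.3, c_doc=1.0, c_nh3_N=0.2),
        k_decay=0.05,
        nitrification_onset=14.0,
        nitrification_rate=0.15,
        noise_sd=0.0,
        sample_times=tuple(float(t) for t in range(0, 57, 7)),
    )


@pytest.fixture(scope="session")
def nitrifying_run(nitrifying_scenario, clean_compensation, clean_model_report):
    """End-to-end monitoring of the noise-free nitrifying series.

    Returns (MonitoringResult, truth) where truth is the injected relative
    combined NOx-N per post-baseline timestamp.
    """
    model, _ = clean_model_report
    series, states = nm.simulate_decay_series(nitrifying_scenario)
    result = nm.run_monitoring(series, clean_compensation, model)
    truth = np.array([s.c_nox_N for s in states[1:]]) - states[0].c_nox_N
    return result, truth
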