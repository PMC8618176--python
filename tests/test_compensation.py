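"""Delta-245 anchored per-wavelength compensation: fit, predict, isolate."""

import numpy as np
import pytest

import noxmonitor as nm
from noxmonitor.errors import (
    InsufficientCalibrationError,
    NotFittedError,
    NumericalError,
    SpectrumValidationError,
)

GRID = nm.DEFAULT_GRID
WL = GRID.wavelengths
I245 = GRID.index_of(245.0)


def _nh2cl_series(concentrations, noise_sd=0.0, seed=0):
    spectra, _ = nm.monochloramine_dilution_series(
        concentrations=tuple(concentrations), noise_sd=noise_sd, seed=seed
    )
    return spectra


class TestPairwiseDeltas:
    @pytest.mark.parametrize("n,expected", [(3, 3), (5, 10), (10, 45)])
    def test_all_pairs_count(self, n, expected):
        spectra = _nh2cl_series(np.linspace(0.5, 5.0, n))
        data = nm.compute_pairwise_deltas(spectra)
        assert data.anchor_deltas.shape == (expected,)
        assert data.delta_matrix.shape == (expected, 90)

    def test_anchor_deltas_nonnegative(self):
        data = nm.compute_pairwise_deltas(_nh2cl_series([0.2, 1.0, 3.0, 5.0]))
        assert np.all(data.anchor_deltas >= 0.0)

    def test_identical_spectra_give_zero_record(self):
        spectra = _nh2cl_series([1.0, 1.0, 3.0])
        data = nm.compute_pairwise_deltas(spectra)
        zero_rows = np.all(data.delta_matrix == 0.0, axis=1)
        assert zero_rows.sum() == 1

    def test_beer_lambert_ratio_oracle(self):
        """Every noise-free record satisfies delta_i/delta_245 = eps_i/eps_245."""
        spectra = _nh2cl_series(np.linspace(0.2, 5.0, 6))
        data = nm.compute_pairwise_deltas(spectra)
        eps = nm.component_curve("monochloramine").epsilon
        ratio = eps[:90] / eps[I245]
        for k in range(data.anchor_deltas.size):
            np.testing.assert_allclose(
                data.delta_matrix[k] / data.anchor_deltas[k], ratio, atol=1e-9
            )

    def test_too_few_spectra_rejected(self):
        with pytest.raises(InsufficientCalibrationError):
            nm.compute_pairwise_deltas(_nh2cl_series([1.0, 2.0]))

    def test_baseline_pair_mode(self):
        spectra = _nh2cl_series(np.linspace(0.5, 5.0, 6))
        data = nm.compute_pairwise_deltas(spectra, pair_mode="baseline")
        assert data.anchor_deltas.shape == (5,)


class TestFitCompensation:
    def test_exact_line_recovered(self):
        """Records lying on delta_i = 0.4 * delta_245 give slope 0.4, R2=1."""
        anchors = np.array([0.1, 0.2, 0.3, 0.4])
        mat = np.outer(anchors, np.full(90, 0.4))
        data = nm.DeltaDataset(
            anchor_nm=245.0,
            modelled_wavelengths=nm.MODELLED_GRID.wavelengths,
            anchor_deltas=anchors,
            delta_matrix=mat,
        )
        model = nm.fit_compensation(data)
        np.testing.assert_allclose(model.slope_, 0.4, atol=1e-12)
        np.testing.assert_allclose(model.intercept_, 0.0, atol=1e-12)
        np.testing.assert_allclose(model.fit_r2_, 1.0, atol=1e-12)
        np.testing.assert_allclose(model.fit_rmse_, 0.0, atol=1e-12)

    def test_noise_free_slopes_match_extinction_ratio(self, clean_compensation):
        eps = nm.component_curve("monochloramine").epsilon
        ratio = eps[:90] / eps[I245]
        np.testing.assert_allclose(clean_compensation.slope_, ratio, atol=1e-9)
        np.testing.assert_allclose(clean_compensation.intercept_, 0.0, atol=1e-9)

    def test_noisy_fit_quality_bound(self):
        """Seeded 0.001 AU noise keeps every per-wavelength R2 above 0.93."""
        spectra, _ = nm.monochloramine_dilution_series(noise_sd=0.001, seed=42)
        model = nm.ChloramineCompensation().fit(spectra)
        assert model.fit_r2_.min() > 0.93

    def test_fit_quality_improves_toward_anchor(self):
        """With wavelength-independent noise the line tightens near 245 nm."""
        spectra, _ = nm.monochloramine_dilution_series(noise_sd=0.001, seed=7)
        model = nm.ChloramineCompensation().fit(spectra)
        wl = model.modelled_wavelengths_
        near = (wl >= 240.0) & (wl <= 244.5)
        far = (wl >= 200.0) & (wl <= 204.5)
        # R2 rises toward the anchor because the signal variance grows with
        # the slope while wavelength-independent noise stays flat
        assert model.fit_r2_[near].mean() >= model.fit_r2_[far].mean()

    def test_degenerate_anchor_spread_rejected(self):
        anchors = np.full(4, 0.2)
        data = nm.DeltaDataset(
            anchor_nm=245.0,
            modelled_wavelengths=nm.MODELLED_GRID.wavelengths,
            anchor_deltas=anchors,
            delta_matrix=np.zeros((4, 90)),
        )
        with pytest.raises(NumericalError):
            nm.fit_compensation(data)


class TestPredictDeltas:
    def test_zero_anchor_zero_prediction(self, clean_compensation):
        np.testing.assert_allclose(
            clean_compensation.predict_deltas(0.0), 0.0, atol=1e-9
        )

    def test_linearity_in_anchor(self, clean_compensation):
        d1 = clean_compensation.predict_deltas(0.1)
        d2 = clean_compensation.predict_deltas(0.2)
        np.testing.assert_allclose(d2, 2.0 * d1, atol=1e-9)

    def test_held_out_pair_prediction(self):
        """Deltas of an unseen concentration pair are predicted to 1e-6 AU."""
        train = _nh2cl_series([0.2, 0.8, 1.5, 2.5, 4.0, 5.0])
        model = nm.ChloramineCompensation().fit(train)
        held = _nh2cl_series([1.1, 3.3])
        true_delta = held[1].absorbance - held[0].absorbance
        anchor = true_delta[I245]
        np.testing.assert_allclose(
            model.predict_deltas(anchor), true_delta[:90], atol=1e-6
        )

    def test_negative_anchor_warns_and_zeroes(self, clean_compensation):
        with pytest.warns(RuntimeWarning):
            out = clean_compensation.predict_deltas(-0.05)
        assert np.all(out == 0.0)

    def test_unfitted_model_rejected(self):
        with pytest.raises(NotFittedError):
            nm.ChloramineCompensation().predict_deltas(0.1)


class TestDecayEstimate:
    def test_zero_deltas_return_baseline(self, clean_compensation):
        base = nm.compose_spectrum(nm.MixtureState(c_nh2cl=2.0, c_doc=1.0))
        est = clean_compensation.estimate_decay_spectrum(base, 0.0)
        np.testing.assert_allclose(est.absorbance, base.absorbance, atol=1e-9)

    def test_estimate_below_baseline_for_positive_anchor(self, clean_compensation):
        base = nm.compose_spectrum(nm.MixtureState(c_nh2cl=3.0, c_doc=1.0))
        est = clean_compensation.estimate_decay_spectrum(base, 0.05)
        mask = (WL >= 200.0) & (WL <= 244.5)
        assert np.all(est.absorbance[mask] <= base.absorbance[mask] + 1e-12)

    def test_decay_only_series_estimate_matches_observed(self, clean_compensation):
        """With no NOx, the estimated decay spectrum is the observed one."""
        sc = nm.DecayScenario(
            initial=nm.MixtureState(c_nh2cl=3.0, c_doc=1.0), k_decay=0.08
        )
        spectra, _ = nm.simulate_decay_series(sc)
        base = spectra[0]
        for sample in spectra[1:]:
            anchor = base.absorbance[I245] - sample.absorbance[I245]
            est = clean_compensation.estimate_decay_spectrum(base, anchor)
            np.testing.assert_allclose(est.absorbance, sample.absorbance, atol=1e-9)


class TestIsolateNOx:
    def test_sample_equal_to_estimate_gives_zero(self):
        s = nm.compose_spectrum(nm.MixtureState(c_nh2cl=1.0, c_doc=1.0))
        out = nm.isolate_nox(s, s)
        assert np.all(out.absorbance == 0.0)

    def test_zero_decay_reduces_to_plain_subtraction(self, clean_compensation):
        """With delta_245 = 0 the isolated spectrum is exactly S_t - S_0."""
        base = nm.compose_spectrum(nm.MixtureState(c_nh2cl=2.0, c_doc=1.0))
        st = nm.MixtureState(c_nh2cl=2.0, c_no2_N=0.2, c_no3_N=0.1, c_doc=1.0)
        sample = nm.compose_spectrum(st)
        nox = clean_compensation.isolate(base, sample)
        np.testing.assert_allclose(
            nox.absorbance, sample.absorbance - base.absorbance, atol=1e-9
        )

    def test_grid_mismatch_rejected(self):
        a = nm.compose_spectrum(nm.MixtureState(c_nh2cl=1.0))
        b = nm.compose_spectrum(nm.MixtureState(c_nh2cl=1.0), grid=nm.MODELLED_GRID)
        with pytest.raises(SpectrumValidationError):
            nm.isolate_nox(a, b)

    def test_monochloramine_only_series_isolates_nothing(self, clean_compensation):
        """Noise-free decay-only series: isolated NOx is <= 1e-9 AU everywhere."""
        sc = nm.DecayScenario(
            initial=nm.MixtureState(c_nh2cl=4.0, c_doc=1.2), k_decay=0.12
        )
        spectra, _ = nm.simulate_decay_series(sc)
        for nox in clean_compensation.transform(spectra):
            assert np.abs(nox.absorbance).max() <= 1e-9

    def test_nitrifying_series_recovers_injected_component(
        self, clean_compensation, nitrifying_scenario
    ):
        """Isolated spectra match the injected NOx component in 200-240 nm."""
        spectra, states = nm.simulate_decay_series(nitrifying_scenario)
        noxes = clean_compensation.transform(spectra)
        mask = (WL >= 200.0) & (WL <= 240.0)
        for nox, st in zip(noxes, states[1:]):
            injected = nm.compose_spectrum(
                nm.MixtureState(c_no2_N=st.c_no2_N, c_no3_N=st.c_no3_N)
            )
            np.testing.assert_allclose(
                nox.absorbance[mask], injected.absorbance[mask], atol=2e-9
            )

    def test_end_to_end_algebraic_identity(self, clean_compensation):
        """NOx(i) = S_t(i) - S_0(i) + predicted delta_i on the modelled grid."""
        base = nm.compose_spectrum(nm.MixtureState(c_nh2cl=2.5, c_doc=1.0))
        sample = nm.compose_spectrum(
            nm.MixtureState(c_nh2cl=1.7, c_no2_N=0.15, c_no3_N=0.1, c_doc=1.0)
        )
        anchor = base.absorbance[I245] - sample.absorbance[I245]
        deltas = clean_compensation.predict_deltas(anchor)
        nox = clean_compensation.isolate(base, sample)
        lhs = nox.absorbance[:90]
        rhs = sample.absorbance[:90] - base.absorbance[:90] + deltas
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_clipped_view_is_nonnegative(self, clean_compensation):
        base = nm.compose_spectrum(nm.MixtureState(c_nh2cl=2.0), noise_sd=0.002, seed=1)
        sample = nm.compose_spectrum(nm.MixtureState(c_nh2cl=1.9), noise_sd=0.002, seed=2)
        nox = clean_compensation.isolate(base, sample)
        assert nox.absorbance.min() < 0.0  # noise produces negatives
        assert nox.clipped().min() == 0.0


class TestPersistence:
    def test_json_round_trip(self, clean_compensation, tmp_path):
        p = tmp_path / "comp.json"
        clean_compensation.save(p)
        back = nm.ChloramineCompensation.load(p)
        np.testing.assert_array_equal(back.slope_, clean_compensation.slope_)
        np.testing.assert_array_equal(back.intercept_, clean_compensation.intercept_)
        base = nm.compose_spectrum(nm.MixtureState(c_nh2cl=2.0, c_doc=1.0))
        np.testing.assert_array_equal(
            back.estimate_decay_spectrum(base, 0.03).absorbance,
            clean_compensation.estimate_decay_spectrum(base, 0.03).absorbance,
        )

    def test_refit_is_deterministic(self):
        spectra, _ = nm.monochloramine_dilution_series(noise_sd=0.001, seed=5)
        a = nm.ChloramineCompensation().fit(spectra)
        b = nm.ChloramineCompensation().fit(spectra)
        np.testing.assert_array_equal(a.slope_, b.slope_)
        assert a.to_dict() == b.to_dict()
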