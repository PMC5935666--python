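"""Calibration, noise estimation, mixture fitting, and model selection."""

import numpy as np
import pytest

import fluorens as fl
from fluorens.deconvolution import find_reference_peak, information_criterion


def make_reference_spectrum(raw_position=-119.400, noise_sd=0.002, seed=0):
    axis = fl.FrequencyAxis.from_window(-118.5, -120.5, 4096)
    peak = fl.LorentzianPeak(raw_position, 0.02, 1.0)
    return fl.simulate_static_spectrum([peak], axis, noise_sd=noise_sd, seed=seed)


class TestCalibration:
    def test_offset_applied_to_all_shifts(self, axis2048, single_peak):
        ref = make_reference_spectrum(-119.400)
        sp = fl.simulate_static_spectrum([single_peak], axis2048)
        cal = fl.calibrate_axis(sp, -119.400, -119.522, reference_spectrum=ref)
        # defined (-119.522) - found (~-119.400): everything moves upfield ~0.122
        assert cal.metadata["calibration_offset_ppm"] == pytest.approx(-0.122, abs=0.002)
        np.testing.assert_allclose(
            cal.ppm, sp.ppm + cal.metadata["calibration_offset_ppm"]
        )

    def test_calibrated_reference_lands_exactly_on_defined_shift(self):
        ref = make_reference_spectrum(-119.400, noise_sd=0.0)
        cal = fl.calibrate_axis(ref, -119.400, -119.522)
        found = find_reference_peak(cal, -119.522)
        assert found == pytest.approx(-119.522, abs=1e-9)

    def test_already_calibrated_spectrum_is_identity(self):
        ref = make_reference_spectrum(fl.KF_REFERENCE_SHIFT_PPM, noise_sd=0.0)
        cal = fl.calibrate_axis(ref, fl.KF_REFERENCE_SHIFT_PPM)
        assert cal.metadata["calibration_offset_ppm"] == pytest.approx(0.0, abs=1e-6)

    def test_missing_reference_peak_rejected(self):
        axis = fl.FrequencyAxis.from_window(-118.5, -120.5, 2048)
        flat = fl.simulate_static_spectrum([], axis, noise_sd=0.01, seed=1)
        with pytest.raises(ValueError, match="no reference peak"):
            fl.calibrate_axis(flat, -119.4)


class TestNoiseEstimation:
    def test_recovers_gaussian_sd(self):
        axis = fl.FrequencyAxis.from_window(-80.0, -88.0, 8192)
        sp = fl.simulate_static_spectrum([], axis, noise_sd=1.0, seed=3)
        est = fl.estimate_noise(sp, (-86.0, -82.0))
        assert 0.95 <= est <= 1.05

    def test_noise_free_flat_spectrum_gives_zero(self):
        axis = fl.FrequencyAxis.from_window(-80.0, -88.0, 1024)
        sp = fl.simulate_static_spectrum([], axis)
        assert fl.estimate_noise(sp, (-86.0, -82.0)) == 0.0

    def test_window_overlapping_peak_rejected(self, axis2048, single_peak):
        sp = fl.simulate_static_spectrum([single_peak], axis2048, noise_sd=0.01, seed=1)
        with pytest.raises(ValueError, match="overlap"):
            fl.estimate_noise(sp, (single_peak.center - 0.3, single_peak.center + 0.3))

    def test_too_few_points_rejected(self, axis1024):
        sp = fl.simulate_static_spectrum([], axis1024, noise_sd=0.1, seed=0)
        with pytest.raises(ValueError, match="at least 50"):
            fl.estimate_noise(sp, (-83.01, -83.02))


class TestMixtureFit:
    def test_noise_free_single_peak_exact_round_trip(self, axis2048, single_peak):
        sp = fl.simulate_static_spectrum([single_peak], axis2048)
        res = fl.fit_lorentzian_mixture(sp, 1, noise_sd=1e-9)
        p = res.peaks[0]
        assert p.center == pytest.approx(single_peak.center, rel=1e-6)
        assert p.fwhm == pytest.approx(single_peak.fwhm, rel=1e-6)
        assert p.area == pytest.approx(single_peak.area, rel=1e-6)
        assert res.converged

    def test_noisy_single_peak_recovery(self, axis2048, single_peak):
        noise = single_peak.height / 50.0
        sp = fl.simulate_static_spectrum([single_peak], axis2048, noise_sd=noise, seed=9)
        res = fl.fit_lorentzian_mixture(sp, 1, noise_sd=noise)
        p = res.peaks[0]
        assert p.center == pytest.approx(single_peak.center, abs=0.002)
        assert p.area == pytest.approx(single_peak.area, rel=0.03)
        assert p.fwhm == pytest.approx(single_peak.fwhm, rel=0.05)

    def test_two_resolved_peaks_recovered(self, axis2048, two_resolved_peaks):
        noise = two_resolved_peaks[0].height / 30.0
        sp = fl.simulate_static_spectrum(two_resolved_peaks, axis2048,
                                         noise_sd=noise, seed=11)
        res = fl.fit_lorentzian_mixture(sp, 2, noise_sd=noise)
        centers = sorted(p.center for p in res.peaks)
        truth = sorted(p.center for p in two_resolved_peaks)
        for c, t in zip(centers, truth):
            assert c == pytest.approx(t, abs=0.005)

    def test_phase_constraint_honored(self, axis2048, single_peak):
        phased = fl.LorentzianPeak(single_peak.center, single_peak.fwhm,
                                   single_peak.area, phase=0.05)
        sp = fl.simulate_static_spectrum([phased], axis2048)
        res = fl.fit_lorentzian_mixture(sp, 1, noise_sd=1e-9)
        assert abs(res.peaks[0].phase - res.global_phase) <= np.pi / 50 + 1e-9

    def test_exceeding_max_peaks_rejected(self, axis2048, single_peak):
        sp = fl.simulate_static_spectrum([single_peak], axis2048)
        with pytest.raises(ValueError, match="exceeds configured maximum"):
            fl.fit_lorentzian_mixture(sp, 11)


class TestModelSelection:
    def test_criterion_table_retained_and_selected_is_minimum(
        self, axis2048, single_peak
    ):
        noise = single_peak.height / 50.0
        sp = fl.simulate_static_spectrum([single_peak], axis2048, noise_sd=noise, seed=2)
        res = fl.deconvolve(sp, max_peaks=3, noise_sd=noise)
        finite = {n: v for n, v in res.criterion_table.items() if np.isfinite(v)}
        assert res.selected_n == min(finite, key=lambda n: (finite[n], n))
        assert res.selected_n == 1

    def test_two_peaks_at_three_fwhm_selected(self, axis2048):
        peaks = [fl.LorentzianPeak(-83.8, 0.12, 1.0),
                 fl.LorentzianPeak(-84.16, 0.12, 0.9)]
        noise = peaks[0].height / 30.0
        sp = fl.simulate_static_spectrum(peaks, axis2048, noise_sd=noise, seed=5)
        res = fl.deconvolve(sp, max_peaks=4, noise_sd=noise)
        assert res.selected_n == 2

    def test_unresolvable_doublet_collapses_to_one(self, axis2048):
        """Two identical peaks FWHM/10 apart at SNR 10: documented resolution
        limit, parsimony wins."""
        peaks = [fl.LorentzianPeak(-83.80, 0.12, 0.5),
                 fl.LorentzianPeak(-83.812, 0.12, 0.5)]
        noise = peaks[0].height / 10.0
        sp = fl.simulate_static_spectrum(peaks, axis2048, noise_sd=noise, seed=6)
        res = fl.deconvolve(sp, max_peaks=3, noise_sd=noise)
        assert res.selected_n == 1

    def test_rss_non_increasing_with_n_but_criterion_penalizes(
        self, axis2048, single_peak
    ):
        noise = single_peak.height / 50.0
        sp = fl.simulate_static_spectrum([single_peak], axis2048, noise_sd=noise, seed=8)
        res = fl.deconvolve(sp, max_peaks=3, noise_sd=noise)
        rss = res.rss_table
        assert rss[1] >= rss[2] - 1e-9 and rss[2] >= rss[3] - 1e-9
        assert res.criterion_table[1] < res.criterion_table[3]

    def test_area_sum_matches_integral_noise_free(self, axis2048, two_resolved_peaks):
        sp = fl.simulate_static_spectrum(two_resolved_peaks, axis2048)
        res = fl.deconvolve(sp, max_peaks=3, noise_sd=1e-9)
        total_fit = sum(p.area for p in res.peaks)
        assert total_fit == pytest.approx(sum(p.area for p in two_resolved_peaks),
                                          rel=0.01)

    def test_invariance_under_intensity_rescaling(self, axis2048, single_peak):
        noise = single_peak.height / 40.0
        sp = fl.simulate_static_spectrum([single_peak], axis2048, noise_sd=noise, seed=4)
        scaled = fl.Spectrum(sp.axis, sp.intensity * 7.0, dict(sp.metadata))
        a = fl.deconvolve(sp, max_peaks=2, noise_sd=noise)
        b = fl.deconvolve(scaled, max_peaks=2, noise_sd=noise * 7.0)
        assert a.selected_n == b.selected_n
        assert b.peaks[0].center == pytest.approx(a.peaks[0].center, abs=1e-4)
        assert b.peaks[0].area == pytest.approx(7.0 * a.peaks[0].area, rel=1e-3)

    def test_contaminant_flagging(self, axis2048):
        peaks = [fl.LorentzianPeak(-84.0, 0.2, 1.0),
                 fl.LorentzianPeak(fl.FREE_BTFA_PPM, 0.015, 0.05)]
        sp = fl.simulate_static_spectrum(peaks, axis2048, noise_sd=0.005, seed=3)
        res = fl.deconvolve(sp, max_peaks=3, noise_sd=0.005,
                            contaminant_position=fl.FREE_BTFA_PPM)
        flags = [p.is_contaminant for p in res.peaks]
        assert sum(flags) == 1

    def test_fwhm_consistent_with_r2_linewidth(self, axis2048):
        """Cross-module check: fitted FWHM of an exchange-free simulated peak
        obeys FWHM(Hz) = R2/pi within 3%."""
        r2 = 100.0
        model = fl.ExchangeModel.two_site(-84.0, -80.5, r2, 1e4, 1.0, 0.0)
        sp = fl.simulate_exchange_spectrum(model, axis2048)
        res = fl.fit_lorentzian_mixture(sp, 1, noise_sd=1e-12)
        fwhm_hz = res.peaks[0].fwhm * axis2048.spectrometer_freq
        assert fwhm_hz == pytest.approx(r2 / np.pi, rel=0.03)

    def test_information_criterion_values(self):
        # BIC = k ln n + RSS/sigma^2 + const; check ordering logic directly
        a = information_criterion(100.0, 1000, 6, 1.0, "BIC")
        b = information_criterion(100.0, 1000, 10, 1.0, "BIC")
        assert b - a == pytest.approx(4 * np.log(1000))
        with pytest.raises(ValueError):
            information_criterion(1.0, 10, 2, 1.0, "elbow")
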