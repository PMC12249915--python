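"""Synthetic spectra, Stejskal-Tanner decays, and parameter recovery."""

import math

import numpy as np
import pytest

from cdformulate.binding import association_constant, fraction_from_K
from cdformulate.nmr_synth import (
    DecaySeries,
    DosyAcquisition,
    PeakModel,
    default_dosy_acquisition,
    end_to_end_recovery,
    fit_diffusion,
    integrate_region,
    simulate_decay,
    synthesize_spectrum,
)

SFRQ = 599.8  # MHz


def spectrum_of(peaks, noise_sigma=0.0, seed=None, n_points=32768):
    return synthesize_spectrum(
        peaks, ppm_min=0.0, ppm_max=10.0, n_points=n_points,
        spectrometer_frequency=SFRQ, noise_sigma=noise_sigma, seed=seed,
    )


class TestSpectrumSynthesis:
    def test_lorentzian_window_integral_matches_closed_form(self):
        # fraction of a unit Lorentzian within +/- 10 half-widths of centre
        # is (2/pi)·atan(10) = 0.93655 (closed form, checked by quadrature)
        peak = PeakModel(center=5.0, fwhm=6.0, area=1.0)
        hwhm_ppm = peak.fwhm / SFRQ / 2.0
        spec = spectrum_of([peak], n_points=2**18)
        window = (5.0 - 10 * hwhm_ppm, 5.0 + 10 * hwhm_ppm)
        integral = integrate_region(spec, window, baseline=False)
        assert integral == pytest.approx(2 / math.pi * math.atan(10.0), abs=1e-3)

    def test_total_integral_equals_sum_of_areas(self):
        peaks = [
            PeakModel(center=7.0, fwhm=2.0, area=1.0),
            PeakModel(center=8.1, fwhm=2.0, area=0.27,
                      satellite_J=210.0, satellite_fraction=0.011),
        ]
        spec = spectrum_of(peaks, n_points=2**17)
        total = integrate_region(spec, (0.5, 9.5), baseline=False)
        assert total == pytest.approx(1.27, abs=1.27e-2)

    def test_satellite_doublet_separation_is_J(self):
        peak = PeakModel(center=8.1, fwhm=1.0, area=1.0,
                         satellite_J=210.0, satellite_fraction=0.011)
        spec = spectrum_of([peak], n_points=2**18)
        half_sep_ppm = 210.0 / 2.0 / SFRQ
        for sign in (-1, +1):
            expected = 8.1 + sign * half_sep_ppm
            window = np.abs(spec.axis - expected) < 0.05
            peak_ppm = spec.axis[window][np.argmax(spec.intensity[window])]
            assert peak_ppm == pytest.approx(expected, abs=2e-4)

    def test_zero_noise_is_deterministic_across_seeds(self):
        peaks = [PeakModel(center=5.0, fwhm=2.0)]
        a = spectrum_of(peaks, seed=1)
        b = spectrum_of(peaks, seed=2)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_seeded_noise_is_reproducible(self):
        peaks = [PeakModel(center=5.0, fwhm=2.0)]
        a = spectrum_of(peaks, noise_sigma=0.1, seed=7)
        b = spectrum_of(peaks, noise_sigma=0.1, seed=7)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_peak_outside_axis_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            spectrum_of([PeakModel(center=12.0, fwhm=2.0)])


class TestIntegration:
    def test_empty_region_integrates_to_zero(self):
        spec = spectrum_of([PeakModel(center=8.0, fwhm=1.0)])
        assert integrate_region(spec, (1.0, 2.0)) == pytest.approx(0.0, abs=1e-6)

    def test_window_outside_axis_rejected(self):
        spec = spectrum_of([PeakModel(center=8.0, fwhm=1.0)])
        with pytest.raises(ValueError, match="outside"):
            integrate_region(spec, (9.0, 11.0))

    @pytest.mark.parametrize("true_ratio", [0.27, 0.77])
    def test_integral_ratio_recovery_at_snr_100(self, true_ratio):
        # drug reference signal at 7 ppm set to 1; formate singlet at 8.1 ppm
        peaks = [
            PeakModel(center=7.0, fwhm=2.0, area=1.0),
            PeakModel(center=8.1, fwhm=2.0, area=true_ratio,
                      satellite_J=210.0, satellite_fraction=0.011),
        ]
        clean = spectrum_of(peaks, n_points=2**16)
        sigma = clean.intensity.max() / 100.0
        spec = spectrum_of(peaks, noise_sigma=sigma, seed=11, n_points=2**16)
        ref = integrate_region(spec, (6.7, 7.3))
        formate = integrate_region(spec, (7.8, 8.4))
        assert formate / ref == pytest.approx(true_ratio, abs=0.02)


class TestDecaySimulation:
    def test_default_acquisition_b_factor(self):
        # hand evaluation of gamma^2 g^2 delta^2 (Delta - delta/3) at 25 G/cm
        acq = default_dosy_acquisition()
        assert len(acq.gradients) == 16
        assert acq.gradients[0] == pytest.approx(0.03)
        assert acq.b_factors[-1] == pytest.approx(3.5665e9, rel=1e-4)

    def test_noiseless_decay_monotone_and_normalised(self):
        series = simulate_decay(2.68e-10, I0=3.0)
        assert np.all(np.diff(series.intensities) < 0)
        assert series.intensities[0] == pytest.approx(
            3.0 * np.exp(-2.68e-10 * series.acquisition.b_factors[0])
        )

    def test_zero_gradient_returns_I0(self):
        acq = DosyAcquisition(gradients=(0.0, 0.1, 0.2))
        series = simulate_decay(2.68e-10, acq, I0=5.0)
        assert series.intensities[0] == 5.0

    def test_log_ratio_identity(self):
        # ln(I1/I2) = -D (b1 - b2) exactly in the noiseless case
        D = 3.16e-10
        series = simulate_decay(D)
        b = series.acquisition.b_factors
        lhs = np.log(series.intensities[2] / series.intensities[9])
        assert lhs == pytest.approx(-D * (b[2] - b[9]), rel=1e-12)

    def test_invalid_acquisition_rejected(self):
        with pytest.raises(ValueError):
            DosyAcquisition(gradients=(0.25, 0.03))  # not increasing
        with pytest.raises(ValueError):
            DosyAcquisition(gradients=(0.03, 0.25), big_delta=1e-4)


class TestDiffusionFit:
    def test_noiseless_fit_is_exact(self):
        series = simulate_decay(2.68e-10, I0=2.0)
        fit = fit_diffusion(series)
        assert fit.D == pytest.approx(2.68e-10, rel=1e-8)
        assert fit.I0 == pytest.approx(2.0, rel=1e-8)

    def test_estimate_invariant_to_intensity_scale(self):
        rng = np.random.default_rng(5)
        noisy = simulate_decay(2.68e-10, I0=1.0, noise_sigma=0.01, rng=rng)
        scaled = DecaySeries(
            acquisition=noisy.acquisition, intensities=noisy.intensities * 1e6
        )
        assert fit_diffusion(scaled).D == pytest.approx(
            fit_diffusion(noisy).D, rel=1e-9
        )

    def test_monte_carlo_median_error_under_two_percent(self):
        D = 2.68e-10
        errors = []
        for seed in range(1, 201):
            fit = fit_diffusion(simulate_decay(D, noise_sigma=0.01, seed=seed))
            errors.append(abs(fit.D - D) / D)
        assert np.median(errors) < 0.02

    def test_scatter_scales_with_noise(self):
        D = 2.68e-10
        def spread(sigma):
            fits = [
                fit_diffusion(simulate_decay(D, noise_sigma=sigma, seed=s)).D
                for s in range(1, 81)
            ]
            return np.std(fits)
        ratio = spread(0.02) / spread(0.01)
        assert ratio == pytest.approx(2.0, rel=0.3)

    def test_too_few_points_rejected(self):
        acq = DosyAcquisition(gradients=(0.03, 0.25))
        series = simulate_decay(2.68e-10, acq)
        with pytest.raises(ValueError):
            fit_diffusion(series)


class TestEndToEndRecovery:
    CONDITIONS = dict(
        c_guest=1.917e-3, c_host=7.667e-3, D_free=3.16e-10, D_host=1.79e-10
    )

    def test_zero_noise_inverts_the_pipeline(self):
        recovered = end_to_end_recovery(
            true_K=77.0, snr=np.inf, n_replicates=1, seed=0, **self.CONDITIONS
        )
        assert recovered[0] == pytest.approx(77.0, rel=1e-6)

    def test_recovery_median_within_15_percent_at_snr_100(self):
        recovered = end_to_end_recovery(
            true_K=77.0, snr=100.0, n_replicates=200, seed=1, **self.CONDITIONS
        )
        assert np.median(recovered) == pytest.approx(77.0, rel=0.15)

    def test_recovered_median_monotone_in_true_K(self):
        medians = [
            np.median(
                end_to_end_recovery(
                    true_K=K, snr=100.0, n_replicates=60, seed=3, **self.CONDITIONS
                )
            )
            for K in (20.0, 77.0, 300.0)
        ]
        assert medians[0] < medians[1] < medians[2]

    def test_consistency_with_direct_speciation(self):
        # the simulated observed D reproduces the bound fraction it encodes
        f = fraction_from_K(77.0, **{k: self.CONDITIONS[k] for k in ("c_guest", "c_host")})
        K_back = association_constant(
            f, self.CONDITIONS["c_guest"], self.CONDITIONS["c_host"]
        ).K
        assert K_back == pytest.approx(77.0, rel=1e-9)
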