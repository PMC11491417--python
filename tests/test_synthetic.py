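"""Forward model: FIDs, calibration series and leaching time courses."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluorquant.core import NoiseModel, PeakSpec, paper_acquisition
from fluorquant.kinetics import LeachingModel
from fluorquant.peaks import fit_lorentzian
from fluorquant.processing import fourier_transform, process_fid
from fluorquant.quantify import fit_calibration
from fluorquant.synthetic import (
    default_noise_model,
    sigma_for_snr,
    simulate_calibration_series,
    simulate_fid,
    simulate_leaching_series,
    simulate_spectrum,
)
from fluorquant.workflow import build_calibration


class TestSimulateFid:
    def test_no_peaks_no_noise_is_silent(self, acq):
        fid = simulate_fid([], acq, NoiseModel(sigma_per_scan=0.0))
        assert np.all(fid.samples == 0)

    def test_on_resonance_peak_is_pure_decay(self, acq):
        peak = PeakSpec(center=acq.carrier_offset, area=5.0, fwhm=10.0)
        fid = simulate_fid([peak], acq)
        assert np.allclose(fid.samples.imag, 0.0, atol=1e-9)
        # strictly decreasing real envelope
        assert np.all(np.diff(fid.samples.real) < 0)

    def test_peak_outside_window_rejected(self, acq):
        with pytest.raises(ValueError, match="spectral window"):
            simulate_fid([PeakSpec(center=0.0, area=1.0, fwhm=5.0)], acq)

    def test_nonpositive_fwhm_rejected(self):
        with pytest.raises(ValueError):
            PeakSpec(center=-120.0, area=1.0, fwhm=0.0)

    def test_area_round_trip_fully_relaxed(self, acq, relaxed_peak):
        """Simulated area is recovered through FT + fit to 1e-6 relative."""
        fid = simulate_fid([relaxed_peak], acq)
        spec = fourier_transform(fid, zero_fill_factor=2)
        fit = fit_lorentzian(spec, relaxed_peak.center, window=1.0)
        assert fit.area == pytest.approx(relaxed_peak.area, rel=1e-6)
        assert fit.fwhm == pytest.approx(relaxed_peak.fwhm, rel=1e-6)

    def test_round_trip_through_default_processing(self, acq):
        """simulate → process (lb 2) → fit recovers area to 1e-4 relative;
        apodization broadens the line but conserves its integral."""
        peak = PeakSpec(center=-120.0, area=7.5, fwhm=20.0)
        spec = process_fid(simulate_fid([peak], acq), line_broadening=2.0)
        fit = fit_lorentzian(spec, -120.0, window=1.0)
        assert fit.area == pytest.approx(7.5, rel=1e-4)

    def test_signal_averaging_snr_scales_sqrt_n_scans(self):
        """Doubling n_scans raises spectral SNR by sqrt(2) within MC error."""
        rng_seeds = range(8)
        snrs = {}
        for n_scans in (1600, 3200):
            acq = paper_acquisition(n_scans=n_scans)
            noise = NoiseModel(sigma_per_scan=5e5)
            peak = PeakSpec(center=-120.0, area=20.0, fwhm=5.0)
            vals = []
            for s in rng_seeds:
                spec = simulate_spectrum(
                    [peak], acq, noise, rng=np.random.default_rng(s)
                )
                region = spec.slice_ppm(-112.0, -104.0)
                sd = np.std(spec.real[region])
                vals.append(spec.real.max() / sd)
            snrs[n_scans] = np.mean(vals)
        ratio = snrs[3200] / snrs[1600]
        assert ratio == pytest.approx(math.sqrt(2.0), rel=0.15)

    def test_sigma_for_snr_hits_target(self, acq):
        """The closed-form noise calibration lands near its target SNR."""
        sigma = sigma_for_snr(acq, area=20.0, fwhm=5.0, snr=100.0)
        noise = NoiseModel(sigma_per_scan=sigma)
        peak = PeakSpec(center=-120.0, area=20.0, fwhm=5.0)
        vals = []
        for s in range(6):
            fid = simulate_fid([peak], acq, noise, rng=np.random.default_rng(s))
            spec = fourier_transform(fid, 2)  # no apodization: the calibrated chain
            region = spec.slice_ppm(-112.0, -104.0)
            vals.append(spec.real.max() / np.std(spec.real[region]))
        assert np.mean(vals) == pytest.approx(100.0, rel=0.25)


class TestLeachingSeries:
    TRUTH = LeachingModel(A=31.0, B=0.6, C=0.4, k1=0.5, k2=0.05)

    def test_initial_condition_zero_when_amplitudes_sum_to_one(self):
        model = LeachingModel(A=10.0, B=0.7, C=0.3, k1=1.0, k2=0.1)
        (s,) = simulate_leaching_series(model, [0.0])
        assert s.concentration == pytest.approx(0.0, abs=1e-12)

    def test_plateau_limit(self):
        (s,) = simulate_leaching_series(self.TRUTH, [1e6])
        assert s.concentration == pytest.approx(31.0, rel=1e-9)

    def test_direct_substitution_oracle(self):
        """c(10 h) equals the formula evaluated term by term."""
        expected = 31.0 * (
            1.0 - 0.6 * math.exp(-0.5 * 10.0) - 0.4 * math.exp(-0.05 * 10.0)
        )
        (s,) = simulate_leaching_series(self.TRUTH, [10.0])
        assert s.concentration == pytest.approx(expected, rel=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            simulate_leaching_series(self.TRUTH, [-1.0])

    def test_noise_is_reproducible_and_floored(self):
        t = np.arange(0, 50, dtype=float)
        a = simulate_leaching_series(self.TRUTH, t, per_point_sd=5.0, seed=3)
        b = simulate_leaching_series(self.TRUTH, t, per_point_sd=5.0, seed=3)
        assert [s.concentration for s in a] == [s.concentration for s in b]
        assert min(s.concentration for s in a) >= 0.0

    def test_time_jitter_stays_within_five_minutes(self):
        t = np.arange(1, 20, dtype=float)
        out = simulate_leaching_series(self.TRUTH, t, seed=1, time_jitter=True)
        deltas = np.abs(np.array([s.time for s in out]) - t)
        assert np.all(deltas <= 5.0 / 60.0 + 1e-12)

    @given(
        b=st.floats(0.01, 0.99),
        k1=st.floats(0.05, 5.0),
        k2=st.floats(0.001, 0.05),
        frac=st.floats(0.0, 1.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_noiseless_curve_is_nondecreasing(self, b, k1, k2, frac):
        c = (1.0 - b) * frac  # keep B + C <= 1
        model = LeachingModel(A=20.0, B=b, C=c, k1=k1, k2=k2)
        t = np.linspace(0, 200, 300)
        out = simulate_leaching_series(model, t)
        conc = np.array([s.concentration for s in out])
        assert np.all(np.diff(conc) >= -1e-10)


class TestCalibrationSeries:
    def test_blank_standard_has_no_peak(self, acq):
        series = simulate_calibration_series([0.0], acq=acq, seed=0)
        conc, spec = series[0]
        assert conc == 0.0
        # nothing but noise: the maximum is at noise level, not a 0-area peak
        region = spec.slice_ppm(-112.0, -104.0)
        sd = np.std(spec.real[region])
        assert spec.real.max() < 8.0 * sd

    def test_noiseless_series_is_exactly_linear(self, acq):
        concs = [1.0, 10.0, 50.0, 100.0]
        series = simulate_calibration_series(
            concs, acq=acq, noise=NoiseModel(sigma_per_scan=0.0)
        )
        areas = [fit_lorentzian(s, -120.0, window=1.0).area for _, s in series]
        cal = fit_calibration(list(zip(concs, areas)))
        assert cal.r_squared == pytest.approx(1.0, abs=1e-9)
        assert cal.intercept == pytest.approx(0.0, abs=1e-6 * max(areas))

    def test_default_scenario_r_squared(self, acq):
        """Seven log-spaced standards at the default noise give R² > 0.99."""
        concs = list(np.geomspace(1.0, 100.0, 7))
        series = simulate_calibration_series(concs, acq=acq, seed=42)
        cal = build_calibration(series)
        assert cal.fit.r_squared > 0.99

    def test_negative_concentration_rejected(self, acq):
        with pytest.raises(ValueError):
            simulate_calibration_series([-1.0], acq=acq)
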