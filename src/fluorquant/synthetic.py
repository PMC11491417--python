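"""Synthetic ¹⁹F spectra, calibration series and leaching time courses.

The forward model is the standard one for a pulse-acquire experiment: each
resonance contributes a decaying complex exponential

    s_p(t) = a_p · exp(i·(2π·ν_p·t + φ_p)) · exp(−t / T2*)

with offset frequency ν_p = (δ_p − δ_carrier)·f0 (Hz), T2* = 1/(π·fwhm), and
amplitude a_p = 2·area·f0 chosen so the frequency-domain absorption line
integrates to ``area`` on the ppm axis (the one-sided transform of a unit
step-decay integrates to a/2 per Hz). Noise is additive complex circular
Gaussian in the time domain — flat in the frequency domain — with the SD of
an ``n``-scan average equal to ``sigma_per_scan/sqrt(n)``, so spectral SNR
grows as sqrt(n_scans).

Defaults emulate the study conditions: SW 45,455 Hz around a −120 ppm
carrier, 6,400 scans, fluoride at −120 ppm and 5-fluoroindole at −126 ppm,
~5 Hz linewidths, and a noise level giving a 20 μM fluoride peak an SNR of
roughly 100.
"""

from __future__ import annotations

import math

import numpy as np

from .core import FID, AcquisitionParameters, NoiseModel, PeakSpec, Spectrum, paper_acquisition
from .kinetics import LeachingModel, TimeCourseSample, evaluate_model
from .processing import process_fid

__all__ = [
    "DEFAULT_FWHM_HZ",
    "DEFAULT_RESPONSE",
    "FLUORIDE_PPM",
    "FLUOROINDOLE_PPM",
    "default_noise_model",
    "sigma_for_snr",
    "simulate_fid",
    "simulate_spectrum",
    "simulate_calibration_series",
    "simulate_leaching_series",
    "add_baseline_artifact",
    "fig1_peaks",
]

#: Chemical shift of free fluoride in aqueous buffer (ppm).
FLUORIDE_PPM = -120.0
#: Chemical shift of 5-fluoroindole (ppm).
FLUOROINDOLE_PPM = -126.0
#: Default linewidth for simulated resonances (Hz).
DEFAULT_FWHM_HZ = 5.0
#: Detector response: peak area (ppm-axis units) per μM of analyte.
DEFAULT_RESPONSE = 1.0


def sigma_for_snr(
    acq: AcquisitionParameters,
    area: float,
    fwhm: float = DEFAULT_FWHM_HZ,
    snr: float = 100.0,
    zero_fill_factor: int = 2,
) -> float:
    """Per-scan time-domain noise SD giving a target spectral SNR.

    Inverts the forward model: a peak of the given ppm-axis ``area`` and
    ``fwhm`` has absorption height 2·area·f0·T2·(1 − e^(−T_acq/T2)) in the
    dwell-scaled spectrum, while white time noise of per-component SD σ_t
    produces spectral noise SD σ_t·sqrt(N)/SW. The returned value is scaled
    up by sqrt(n_scans) so that an n_scan average lands at the target.
    """
    t2 = 1.0 / (math.pi * fwhm)
    amp = 2.0 * area * acq.spectrometer_frequency
    height = amp * t2 * (1.0 - math.exp(-acq.acquisition_time / t2))
    sigma_f = height / snr
    sigma_t = sigma_f * acq.spectral_width / math.sqrt(acq.n_complex_points)
    return sigma_t * math.sqrt(acq.n_scans)


def default_noise_model(seed: int | None = None, acq: AcquisitionParameters | None = None) -> NoiseModel:
    """Noise model calibrated so a 20 μM peak has SNR ≈ 100 after 6,400 scans."""
    acq = acq or paper_acquisition()
    sigma = sigma_for_snr(acq, area=20.0 * DEFAULT_RESPONSE)
    return NoiseModel(sigma_per_scan=sigma, seed=seed)


def fig1_peaks(
    fluoride_um: float = 20.0,
    fluoroindole_um: float = 20.0,
    fwhm: float = DEFAULT_FWHM_HZ,
    response: float = DEFAULT_RESPONSE,
) -> list[PeakSpec]:
    """The two-resonance scenario: fluoride at −120 ppm, 5-fluoroindole at −126 ppm."""
    peaks = []
    if fluoride_um > 0:
        peaks.append(PeakSpec(center=FLUORIDE_PPM, area=response * fluoride_um, fwhm=fwhm))
    if fluoroindole_um > 0:
        peaks.append(
            PeakSpec(center=FLUOROINDOLE_PPM, area=response * fluoroindole_um, fwhm=fwhm)
        )
    return peaks


def simulate_fid(
    peaks: list[PeakSpec],
    acq: AcquisitionParameters,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | None = None,
) -> FID:
    """Simulate the time-domain signal of a set of Lorentzian resonances.

    Every peak centre must lie inside the spectral window. The returned FID
    is the n_scan average: coherent signal at full amplitude, noise SD
    ``sigma_per_scan/sqrt(n_scans)`` per quadrature component.
    """
    low, high = acq.window_ppm
    for p in peaks:
        if not (low <= p.center <= high):
            raise ValueError(
                f"peak at {p.center} ppm outside spectral window [{low:.2f}, {high:.2f}] ppm"
            )
    t = acq.time_axis()
    samples = np.zeros(acq.n_complex_points, dtype=complex)
    for p in peaks:
        nu = acq.ppm_to_hz(p.center)
        amp = 2.0 * p.area * acq.spectrometer_frequency
        samples += amp * np.exp(
            (2j * math.pi * nu - 1.0 / p.t2_star) * t + 1j * p.phase
        )
    if noise is not None and noise.sigma_per_scan > 0:
        if rng is None:
            rng = np.random.default_rng(noise.seed)
        sig = noise.effective_sigma(acq.n_scans)
        samples = samples + sig * (
            rng.standard_normal(len(t)) + 1j * rng.standard_normal(len(t))
        )
    return FID(samples, acq)


def simulate_spectrum(
    peaks: list[PeakSpec],
    acq: AcquisitionParameters | None = None,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | None = None,
    line_broadening: float = 2.0,
    zero_fill_factor: int = 2,
) -> Spectrum:
    """Simulate and process in one step (apodize, FT, no phasing needed)."""
    acq = acq or paper_acquisition()
    fid = simulate_fid(peaks, acq, noise, rng=rng)
    return process_fid(fid, line_broadening=line_broadening, zero_fill_factor=zero_fill_factor)


def simulate_calibration_series(
    concentrations: list[float],
    response: float = DEFAULT_RESPONSE,
    acq: AcquisitionParameters | None = None,
    noise: NoiseModel | None = None,
    fwhm: float = DEFAULT_FWHM_HZ,
    seed: int | None = None,
) -> list[tuple[float, Spectrum]]:
    """Simulate one processed spectrum per fluoride standard.

    Each standard carries a fluoride peak at −120 ppm with area
    ``response·concentration``; a zero concentration yields a noise-only
    blank. ``seed`` (or ``noise.seed``) drives one RNG shared across the
    series so every spectrum gets independent noise.
    """
    acq = acq or paper_acquisition()
    if noise is None:
        noise = default_noise_model(acq=acq)
    if any(c < 0 for c in concentrations):
        raise ValueError("concentrations must be >= 0")
    rng = np.random.default_rng(seed if seed is not None else noise.seed)
    out = []
    for conc in concentrations:
        peaks = (
            [PeakSpec(center=FLUORIDE_PPM, area=response * conc, fwhm=fwhm)]
            if conc > 0
            else []
        )
        out.append((conc, simulate_spectrum(peaks, acq, noise, rng=rng)))
    return out


def simulate_leaching_series(
    model: LeachingModel,
    times: list[float] | np.ndarray,
    per_point_sd: float = 0.0,
    relative_sd: float = 0.0,
    seed: int | None = None,
    time_jitter: bool = False,
) -> list[TimeCourseSample]:
    """Simulate a fluoride leaching time course from a bi-exponential truth.

    Observations are c(t) = A·(1 − B·e^(−k1·t) − C·e^(−k2·t)) plus Gaussian
    noise with SD sqrt(per_point_sd² + (relative_sd·c)²), floored at zero.
    ``time_jitter`` adds a uniform ±5 min perturbation to each nominal time
    (off by default; sampling on the hour is the norm).
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted ascending")
    if per_point_sd < 0 or relative_sd < 0:
        raise ValueError("noise SDs must be >= 0")
    rng = np.random.default_rng(seed)
    t_obs = times.copy()
    if time_jitter:
        t_obs = np.maximum(times + rng.uniform(-5.0 / 60.0, 5.0 / 60.0, len(times)), 0.0)
    clean = evaluate_model(model, t_obs)
    clean = np.atleast_1d(np.asarray(clean, dtype=float))
    sd = np.sqrt(per_point_sd**2 + (relative_sd * clean) ** 2)
    noisy = clean + np.where(sd > 0, rng.standard_normal(len(t_obs)) * sd, 0.0)
    noisy = np.maximum(noisy, 0.0)
    return [TimeCourseSample(float(t), float(c)) for t, c in zip(t_obs, noisy)]


def add_baseline_artifact(spec: Spectrum, coefficients: list[float]) -> Spectrum:
    """Add a smooth polynomial baseline to the real part (robustness testing).

    ``coefficients`` are polynomial coefficients in increasing degree over a
    normalised axis spanning [−1, 1] across the window — a stand-in for the
    broad baseline roll that acoustic ringing leaves in real spectra.
    """
    x = np.linspace(-1.0, 1.0, len(spec))
    baseline = np.polynomial.polynomial.polyval(x, np.asarray(coefficients, dtype=float))
    return Spectrum(spec.ppm_axis.copy(), spec.intensity + baseline, spec.acq)
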