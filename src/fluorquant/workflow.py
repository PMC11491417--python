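"""End-to-end quantification workflows.

These helpers chain the stages — simulate (or load), process, fit, integrate,
calibrate, invert — the way the analysis is actually run: a standards series
establishes the area-vs-concentration line, unknown spectra are fitted at the
fluoride shift and inverted through it, and blanks certify a limit of
detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import AcquisitionParameters, NoiseModel, Spectrum, paper_acquisition
from .peaks import (
    FitFailure,
    NoiseEstimate,
    detect_peaks,
    estimate_noise,
    fit_lorentzian,
    integrate_peak,
    normalise_area,
)
from .quantify import CalibrationFit, ConcentrationEstimate, fit_calibration, invert_calibration, limit_of_detection
from .synthetic import (
    DEFAULT_FWHM_HZ,
    DEFAULT_RESPONSE,
    FLUORIDE_PPM,
    default_noise_model,
    simulate_calibration_series,
    simulate_spectrum,
)

__all__ = [
    "DEFAULT_STANDARDS_UM",
    "Calibration",
    "measure_fluoride_area",
    "build_calibration",
    "estimate_unknown",
    "quantify_replicate",
    "blank_lod",
    "NOISE_REGION_PPM",
]

#: Seven standards log-spaced over the 1–100 μM range of the standards series.
DEFAULT_STANDARDS_UM: tuple[float, ...] = tuple(
    float(c) for c in np.geomspace(1.0, 100.0, 7)
)

#: Signal-free region used for noise estimation (well upfield of −126 ppm is
#: avoided; this sits between the window edge and the fluoride resonance).
NOISE_REGION_PPM: tuple[float, float] = (-112.0, -104.0)


@dataclass
class Calibration:
    """A fitted standards line plus the area scale it was built on."""

    fit: CalibrationFit
    reference_area: float  # raw area of the top standard (normalisation scale)
    fwhm_hz: float  # median fitted linewidth across standards


def measure_fluoride_area(
    spec: Spectrum,
    center_guess: float = FLUORIDE_PPM,
    window: float = 1.0,
    mode: str = "analytic",
    absent_ok: bool = False,
) -> tuple[float, float, object]:
    """Fit and integrate the fluoride peak of one spectrum.

    Returns (area, standard error, fit). With ``absent_ok`` a failed fit —
    the expected outcome for a blank — yields area 0 instead of raising.
    """
    try:
        fit = fit_lorentzian(spec, center_guess, window=window)
    except FitFailure:
        if absent_ok:
            return 0.0, float("nan"), None
        raise
    area, unc = integrate_peak(fit, mode=mode, spec=spec)
    return area, unc, fit


def build_calibration(
    series: list[tuple[float, Spectrum]],
    normalise: bool = True,
    window: float = 1.0,
    mode: str = "analytic",
) -> Calibration:
    """Fit areas for each standard and regress area on concentration.

    With ``normalise`` (default) areas are divided by the top standard's
    area, mapping it to 1 — the dimensionless scale used for plotting
    standards curves. Normalisation rescales slope and residuals together,
    so inverted concentrations are unchanged.
    """
    measured: list[tuple[float, float]] = []
    widths: list[float] = []
    for conc, spec in series:
        area, _, fit = measure_fluoride_area(
            spec, window=window, mode=mode, absent_ok=(conc == 0)
        )
        measured.append((conc, area))
        if fit is not None:
            widths.append(fit.fwhm)
    reference = max(a for _, a in measured)
    if normalise:
        measured = [(c, normalise_area(a, reference)) for c, a in measured]
        scale = reference
    else:
        scale = 1.0
    cal = fit_calibration(measured)
    return Calibration(fit=cal, reference_area=scale, fwhm_hz=float(np.median(widths)))


def estimate_unknown(
    spec: Spectrum,
    cal: Calibration,
    m_reps: int = 1,
    confidence: float = 0.95,
    window: float = 1.0,
    mode: str = "analytic",
    absent_ok: bool = False,
) -> ConcentrationEstimate:
    """Invert one unknown spectrum through the standards line."""
    area, _, _ = measure_fluoride_area(spec, window=window, mode=mode, absent_ok=absent_ok)
    y = area / cal.reference_area
    return invert_calibration(cal.fit, y, m_reps=m_reps, confidence=confidence)


def quantify_replicate(
    unknown_um: float,
    seed: int,
    standards_um: tuple[float, ...] = DEFAULT_STANDARDS_UM,
    response: float = DEFAULT_RESPONSE,
    acq: AcquisitionParameters | None = None,
    noise: NoiseModel | None = None,
    fwhm: float = DEFAULT_FWHM_HZ,
) -> ConcentrationEstimate:
    """One full simulated quantification: standards + one unknown, inverted.

    Simulates a fresh calibration series and a fresh unknown spectrum at the
    given true concentration, then runs the measurement pipeline on both.
    """
    acq = acq or paper_acquisition()
    if noise is None:
        noise = default_noise_model(acq=acq)
    rng = np.random.default_rng(seed)
    series = simulate_calibration_series(
        list(standards_um), response=response, acq=acq, noise=noise, fwhm=fwhm,
        seed=int(rng.integers(2**31 - 1)),
    )
    cal = build_calibration(series)
    from .core import PeakSpec

    peaks = (
        [PeakSpec(center=FLUORIDE_PPM, area=response * unknown_um, fwhm=fwhm)]
        if unknown_um > 0
        else []
    )
    unknown_spec = simulate_spectrum(peaks, acq, noise, rng=rng)
    return estimate_unknown(unknown_spec, cal, absent_ok=(unknown_um == 0))


def blank_lod(
    cal: Calibration,
    n_blanks: int = 20,
    seed: int | None = None,
    acq: AcquisitionParameters | None = None,
    noise: NoiseModel | None = None,
    region: tuple[float, float] = NOISE_REGION_PPM,
    k: float = 3.0,
) -> tuple[float, list[float]]:
    """Limit of detection certified from simulated blank spectra.

    Simulates ``n_blanks`` fluoride-free spectra, estimates the spectral
    noise SD in a signal-free region of each, and converts the median into
    a concentration through the calibration slope. Noise is placed on the
    calibration's (normalised) area scale before division by the slope.
    Returns (LOD in μM, per-blank noise SDs on the raw intensity scale).
    """
    acq = acq or paper_acquisition()
    if noise is None:
        noise = default_noise_model(acq=acq)
    rng = np.random.default_rng(seed)
    sds: list[float] = []
    lods: list[float] = []
    for _ in range(n_blanks):
        spec = simulate_spectrum([], acq, noise, rng=rng)
        est = estimate_noise(spec, region)
        sds.append(est.sd)
        scaled = NoiseEstimate(
            sd=est.sd / cal.reference_area,
            region=est.region,
            point_spacing_ppm=est.point_spacing_ppm,
        )
        lods.append(
            limit_of_detection(
                cal.fit, scaled, fwhm_hz=cal.fwhm_hz, k=k,
                spectrometer_frequency=acq.spectrometer_frequency,
            )
        )
    return float(np.median(lods)), sds
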