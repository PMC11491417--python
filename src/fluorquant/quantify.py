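"""Standards calibration and inverse prediction of fluoride concentration.

Known sodium-fluoride standards give (concentration, peak area) pairs; an
ordinary least-squares line through them is inverted to estimate unknown
concentrations. The uncertainty on the inverted estimate is the classical
inverse-prediction interval

    x̂ ± t(1−α/2, n−2) · (s/|m|) · sqrt(1/m_reps + 1/n + (x̂ − x̄)²/Sxx)

where m is the slope, s the residual SD of the calibration, n the number of
standards, m_reps the number of averaged unknown measurements and Sxx the
concentration spread. Fieller's construction is available for slopes close
to zero. A 3σ limit of detection converts the area uncertainty of a
noise-only measurement into the smallest certifiable concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import F19_FREQUENCY_MHZ
from .peaks import NoiseEstimate

__all__ = [
    "CalibrationFit",
    "ConcentrationEstimate",
    "fit_calibration",
    "invert_calibration",
    "limit_of_detection",
]


@dataclass(frozen=True)
class CalibrationFit:
    """OLS line through the standards plus inverse-prediction statistics.

    ``slope`` in area per μM, ``intercept`` in area units, ``residual_sd``
    the root mean squared residual on n−2 degrees of freedom, ``x_mean`` and
    ``sxx`` the concentration mean and spread Σ(x−x̄)².
    """

    slope: float
    intercept: float
    n: int
    residual_sd: float
    x_mean: float
    sxx: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("calibration needs at least 3 standards")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        if self.sxx <= 0:
            raise ValueError("standards must span distinct concentrations")

    def predict(self, concentration: float | np.ndarray):
        return self.intercept + self.slope * np.asarray(concentration)

    @property
    def se_slope(self) -> float:
        return self.residual_sd / math.sqrt(self.sxx)


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Inverted concentration with its prediction interval (μM)."""

    estimate: float
    interval: tuple[float, float]
    confidence: float = 0.95

    def __post_init__(self) -> None:
        low, high = self.interval
        if not (low <= self.estimate <= high):
            raise ValueError("estimate must lie inside its interval")

    @property
    def half_width(self) -> float:
        return (self.interval[1] - self.interval[0]) / 2.0


class UnboundedIntervalError(RuntimeError):
    """Slope indistinguishable from zero: the inverse interval is unbounded."""


def fit_calibration(standards: list[tuple[float, float]]) -> CalibrationFit:
    """Ordinary least squares of peak area on concentration.

    ``standards`` holds (concentration μM, area) pairs, one per replicate;
    at least three distinct concentrations are required.
    """
    arr = np.asarray(standards, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("standards must be (concentration, area) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct concentrations")
    n = len(x)
    x_mean = float(np.mean(x))
    sxx = float(np.sum((x - x_mean) ** 2))
    if sxx <= 0:
        raise ValueError("zero concentration spread")
    slope = float(np.sum((x - x_mean) * (y - np.mean(y))) / sxx)
    intercept = float(np.mean(y) - slope * x_mean)
    resid = y - (intercept + slope * x)
    rss = float(np.sum(resid**2))
    tss = float(np.sum((y - np.mean(y)) ** 2))
    residual_sd = math.sqrt(rss / (n - 2)) if n > 2 else 0.0
    r_squared = 1.0 - rss / tss if tss > 0 else 1.0
    return CalibrationFit(
        slope=slope,
        intercept=intercept,
        n=n,
        residual_sd=residual_sd,
        x_mean=x_mean,
        sxx=sxx,
        r_squared=r_squared,
    )


def invert_calibration(
    cal: CalibrationFit,
    measured_area: float,
    m_reps: int = 1,
    confidence: float = 0.95,
    method: str = "classical",
) -> ConcentrationEstimate:
    """Estimate the concentration whose expected area is ``measured_area``.

    ``measured_area`` is the mean of ``m_reps`` replicate measurements of
    the unknown. ``method`` selects the classical linear-approximation
    interval (default) or Fieller's exact construction, which stays valid
    when the slope is poorly determined.
    """
    if not math.isfinite(measured_area):
        raise ValueError("measured_area must be finite")
    if m_reps < 1:
        raise ValueError("m_reps must be >= 1")
    if cal.slope == 0:
        raise UnboundedIntervalError("calibration slope is exactly zero")
    alpha = 1.0 - confidence
    tcrit = float(stats.t.ppf(1.0 - alpha / 2.0, cal.n - 2))
    x_hat = (measured_area - cal.intercept) / cal.slope

    if method == "classical":
        if cal.residual_sd > 0 and abs(cal.slope) / cal.se_slope <= tcrit:
            raise UnboundedIntervalError(
                "slope not distinguishable from zero at the stated confidence"
            )
        half = (
            tcrit
            * (cal.residual_sd / abs(cal.slope))
            * math.sqrt(1.0 / m_reps + 1.0 / cal.n + (x_hat - cal.x_mean) ** 2 / cal.sxx)
        )
        return ConcentrationEstimate(
            estimate=float(x_hat),
            interval=(float(x_hat - half), float(x_hat + half)),
            confidence=confidence,
        )
    if method != "fieller":
        raise ValueError("method must be 'classical' or 'fieller'")

    # Fieller: solve the quadratic in x from (ȳ0 − b − m·x)² = t²·Var(ȳ0 − b − m·x)
    s2 = cal.residual_sd**2
    g = (tcrit**2 * s2) / (cal.slope**2 * cal.sxx)
    if g >= 1.0:
        raise UnboundedIntervalError("Fieller interval is unbounded (g >= 1)")
    d = x_hat - cal.x_mean
    centre = cal.x_mean + d / (1.0 - g)
    rad = (
        tcrit
        * (cal.residual_sd / abs(cal.slope))
        / (1.0 - g)
        * math.sqrt(d**2 / cal.sxx + (1.0 - g) * (1.0 / m_reps + 1.0 / cal.n))
    )
    return ConcentrationEstimate(
        estimate=float(x_hat),
        interval=(float(min(centre - rad, x_hat)), float(max(centre + rad, x_hat))),
        confidence=confidence,
    )


def limit_of_detection(
    cal: CalibrationFit,
    noise: NoiseEstimate,
    fwhm_hz: float,
    k: float = 3.0,
    spectrometer_frequency: float = F19_FREQUENCY_MHZ,
) -> float:
    """k·σ limit of detection in μM from the calibration slope.

    The area uncertainty of a noise-only measurement is that of a
    least-squares amplitude fit of a known Lorentzian shape to white noise:
    σ_A = sd · sqrt(Δ · π · w) with Δ the ppm point spacing and w the
    linewidth in ppm. The LOD is the concentration whose expected area
    equals k times that uncertainty. Doubling the noise SD doubles the LOD;
    a noiseless spectrum has LOD 0.
    """
    if cal.slope <= 0:
        raise ValueError("LOD requires a positive calibration slope")
    if fwhm_hz <= 0:
        raise ValueError("fwhm_hz must be > 0")
    if not math.isfinite(noise.point_spacing_ppm):
        raise ValueError("noise estimate lacks the spectrum point spacing")
    w_ppm = fwhm_hz / spectrometer_frequency
    sigma_area = noise.sd * math.sqrt(noise.point_spacing_ppm * math.pi * w_ppm)
    return k * sigma_area / cal.slope
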