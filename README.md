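# fluorquant

Quantitative ¹⁹F NMR analysis of fluoride contamination leaching from
glass NMR tubes — for NMR spectroscopists and analytical chemists who need
to quantify micromolar free fluoride, model its release kinetics, certify
non-detections, and test whether fluoride binds their protein.

New borosilicate (type I) NMR tubes leach free fluoride (a sharp ¹⁹F
resonance near −120 ppm in aqueous buffer) at micromolar levels over tens
of hours. Because ¹⁹F NMR is prized precisely for its empty background,
this artefact matters. `fluorquant` implements the full analysis chain:

* **Simulation** — FIDs from Lorentzian resonances
  (s(t) = a·e^{i2πνt}·e^{−t/T2*}, T2* = 1/(π·fwhm)) at the study's
  acquisition settings (SW 45,455 Hz, carrier −120 ppm, 6,400 scans), with
  complex Gaussian noise obeying SNR ∝ √n_scans, so the whole pipeline is
  testable without measured data.
* **Processing** — exponential apodization, zero-filled FFT with
  first-point halving, phase and polynomial baseline correction, ppm axis
  decreasing left-to-right.
* **Peak analysis** — SNR-thresholded detection and Lorentzian fits
  L(δ) = (2A/π)·w/(4(δ−δ₀)² + w²) + b with Jacobian standard errors;
  analytic (fitted-A) and numeric (trapezoidal) integrals.
* **Quantification** — OLS calibration of peak area on standard
  concentration, inverted with the classical inverse-prediction interval
  x̂ ± t·(s/|m|)·√(1/m + 1/n + (x̂−x̄)²/Sxx), plus a 3σ limit of
  detection from blank noise through the calibration slope.
* **Kinetics** — multi-start nonlinear fits of the bi-exponential
  leaching model c(t) = A(1 − B·e^{−k1·t} − C·e^{−k2·t}), with plateau,
  rates, time-to-90%, and nested mono-exponential comparison.
* **CSP** — chemical shift perturbation of the fluoride resonance between
  protein-free and protein-containing samples, with significance from
  propagated centre errors.

## Worked example

```python
import numpy as np
from fluorquant import paper_acquisition, PeakSpec
from fluorquant.synthetic import (simulate_calibration_series,
                                  simulate_spectrum, default_noise_model)
from fluorquant.workflow import (DEFAULT_STANDARDS_UM, build_calibration,
                                 estimate_unknown, blank_lod)

acq = paper_acquisition()                      # SW 45,455 Hz, -120 ppm, 6,400 scans
noise = default_noise_model(acq=acq)           # 20 uM peak -> SNR ~ 100

# seven fluoride standards, 1-100 uM, one processed spectrum each
series = simulate_calibration_series(list(DEFAULT_STANDARDS_UM),
                                     acq=acq, noise=noise, seed=42)
cal = build_calibration(series)
print(f"calibration: R^2 = {cal.fit.r_squared:.5f}, "
      f"slope = {cal.fit.slope:.5f} per uM (normalised)")

# an unknown sample leached to 34 uM (area = 34 at unit response)
unknown = simulate_spectrum([PeakSpec(center=-120.0, area=34.0, fwhm=5.0)],
                            acq, noise, rng=np.random.default_rng(7))
est = estimate_unknown(unknown, cal)
print(f"unknown: {est.estimate:.1f} uM, 95% prediction interval "
      f"({est.interval[0]:.1f}, {est.interval[1]:.1f}) uM")

lod, _ = blank_lod(cal, n_blanks=20, seed=11, acq=acq)
print(f"limit of detection: {lod:.2f} uM")
```

prints

```
calibration: R^2 = 0.99995, slope = 0.01000 per uM (normalised)
unknown: 33.4 uM, 95% prediction interval (32.6, 34.2) uM
limit of detection: 0.36 uM
```

The calibration is linear to R² ≈ 1 over two decades; the unknown
simulated at 34 μM is recovered with a sub-μM prediction interval; and the
blank-certified detection limit sits well below 1 μM, the level at which a
missing −120 ppm peak certifies a rinsed tube as clean.

A `fluorquant` console command exposes the same stages
(`simulate`, `process`, `fit-peaks`, `calibrate`, `quantify`, `kinetics`,
`csp`, `run`); e.g.

```sh
fluorquant quantify --standards standards.csv --unknown spectrum.tsv --confidence 0.95
fluorquant kinetics --input timecourse.csv --starts 20 --seed 7
```

All file formats are plain TSV/CSV/JSON; see `docs/methods.md` for the
model, defaults and their rationale.

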