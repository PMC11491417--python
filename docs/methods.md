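# Methods

## The measurement problem

Borosilicate (type I) glass NMR tubes leach free fluoride into aqueous
buffer at micromolar levels over tens of hours — enough to contaminate ¹⁹F
experiments, which rely on fluorine's near-absence from biological
backgrounds. `fluorquant` implements the complete quantitative analysis
around that observation: simulate ¹⁹F spectra of fluoride-containing
samples, process them, quantify fluoride against a sodium-fluoride
standards series, model the leaching kinetics, certify non-detections with
a limit of detection, and measure binding-induced chemical shift
perturbations.

Because the measured spectra behind the reported concentrations are not
part of this repository, the synthetic-data module is a first-class
component: it generates spectra with the statistical structure the analysis
assumes, at the acquisition settings the measurements used, so every
downstream stage is testable end to end.

## Forward model (synthetic_data)

Each resonance contributes a decaying complex exponential to the FID:

    s_p(t) = a_p · exp(i(2π ν_p t + φ_p)) · exp(−t/T2*),

with offset frequency ν_p = (δ_p − δ_carrier)·f₀ (δ in ppm, f₀ the ¹⁹F
basic frequency in MHz), T2* = 1/(π·fwhm), and amplitude a_p = 2·area·f₀ so
that the fully relaxed absorption line integrates to `area` on the ppm
axis. Single Lorentzian lines only: no J-coupling, exchange broadening or
field inhomogeneity.

Default acquisition matches the study conditions: spectral width 45,455 Hz,
8,192 complex points (0.18 s), carrier −120.00 ppm, 6,400 scans, 0.5 s
relaxation delay, f₀ = 752.7 MHz (the ¹⁹F frequency at 18.8 T). The
published point count is ambiguous against the published 0.09 s acquisition
time; `paper_acquisition(points="total_real")` selects the 4,096-complex
reading that reconciles it. Both axes derive from points/SW.

Noise is additive complex circular Gaussian in the time domain (flat in the
frequency domain, the standard assumption). Co-adding n scans leaves signal
amplitude fixed and scales noise as 1/√n, so SNR ∝ √n_scans. The default
`sigma_per_scan` is computed in closed form (`sigma_for_snr`) so that a
20 μM fluoride peak (area 20, fwhm 5 Hz) reaches SNR ≈ 100 after 6,400
scans — consistent with the clean appearance of measured spectra at that
concentration. The detector response defaults to 1 area-unit per μM; all
calibrated quantities are invariant to this scale.

Leaching time courses follow c(t) = A(1 − B·e^(−k1·t) − C·e^(−k2·t)) with
Gaussian noise of SD √(per_point_sd² + (relative_sd·c)²), floored at zero.
Sampling is on an exact hourly grid; a uniform ±5 min jitter is available
but off by default.

What the generator does *not* emulate: temperature drift, radiation
damping, lineshape asymmetry from poor shimming, solvent backgrounds, and
acoustic ringing beyond an optional smooth polynomial baseline
(`add_baseline_artifact`). Passing tests therefore demonstrate correctness
of the analysis under idealised single-Lorentzian statistics, not
robustness to every instrumental artefact of real spectra.

## Processing (spectral_processing)

Exponential apodization (default 2 Hz, adds exactly its value to every
fwhm, conserves areas), zero-fill ×2, FFT scaled by the dwell time with the
first point halved (removes the one-sided-signal baseline offset; a plain
DFT is selectable for energy-conservation checks), ppm axis decreasing left
to right via ν = (δ − δ_carrier)·f₀. Zero-order autophasing minimises the
negative-area penalty of the real part over a grid refined by Brent search;
first-order phasing is accepted but not searched, since FIDs sampled from
t = 0 need none. Baseline correction fits a polynomial (default order 1) to
signal-free regions and subtracts it from the real part.

A deliberate physical consequence of this chain: at the default 5 Hz
linewidth the 0.18 s FID retains ≈ 6% of its amplitude at truncation, so
noiseless fitted areas read ~2% high and widths several % high. This bias
is identical for standards and unknowns and cancels exactly through the
calibration; the closed-form round-trip identities (area recovery to 1e-6,
zero-fill invariance to 0.5%) hold in the fully relaxed regime (fwhm ≳
20 Hz at this acquisition time), where the tests exercise them.

## Peak analysis (peak_analysis)

Noise is the robust SD (1.4826 × MAD) of the real part over a stated
peak-free region. Detection thresholds contiguous runs of ≥ 2 points above
snr_threshold × SD (default 3) and reports one centre per run, height
ordered; with zero-filled (correlated) noise, 3σ still admits occasional
noise-level false positives — by design, matching the stated false-positive
behaviour of threshold detection — while 5σ blanks are clean.

Lineshape fits use L(δ) = (2A/π)·w/(4(δ−δ₀)² + w²) + b over a ±1 ppm
window (constant local baseline b; width reported in Hz). Initial values
come from the data near the supplied centre, with two fallback starts
anchored at the centre; a converged negative-amplitude solution raises an
explicit fit failure (it is a fit of noise). Standard errors come from the
Jacobian covariance. Peaks closer than twice the window are fitted jointly
(`fit_two_lorentzians`). The default quantification integral is the
analytic fitted A — immune to window truncation, which removes the
(2/π)·arctan(2m) fraction captured by a ±m·fwhm numeric window — with
trapezoidal numeric integration retained as a cross-check.

## Quantification (quantification)

Ordinary least squares of area on concentration over ≥ 3 distinct
standards; areas are normalised to the top standard by default (a pure
rescaling that cancels in inversion). Unknowns invert through
x̂ = (ȳ − b)/m with the classical inverse-prediction interval

    x̂ ± t(1−α/2, n−2) · (s/|m|) · √(1/m + 1/n + (x̂ − x̄)²/Sxx),

which Monte Carlo confirms covers at ~95% under the generator's
homoscedastic area noise. Fieller's construction is available behind a flag
for poorly determined slopes; a slope not distinguishable from zero at the
stated confidence raises an unbounded-interval error rather than returning
a misleading interval. The intercept is estimated, not forced through the
origin (leached blanks may carry offset); a constrained option exists.

The limit of detection is the concentration whose expected area equals
3 × the area uncertainty of a noise-only measurement. That uncertainty is
taken as the least-squares amplitude-fit uncertainty for a known Lorentzian
shape in white noise, σ_A = sd·√(Δ·π·w) (Δ the ppm point spacing, w the
linewidth in ppm; ∫L² = 1/(πw) for a unit-area Lorentzian), matching the
package's analytic quantification mode. At default settings this certifies
LOD ≈ 0.35 μM, comfortably below the 1 μM non-detection bound it exists to
support. LOD is linear in the noise SD and zero for noiseless spectra.

## Kinetics (kinetics)

The bi-exponential model is fitted by multi-start trust-region least
squares (default 20 starts): plateau seeded from the late-time mean, rate
pairs log-spaced over [1/t_max, 10/t_min], amplitudes from a linear solve
at fixed rates. B + C = 1 is *not* imposed by default — the first
measurement may already miss part of the fast phase, so the extrapolated
t = 0 value is reported rather than assumed zero — with
`constrain_origin` available for physically anchored fits. The k1 ≥ k2
ordering is enforced by relabelling, making reported parameters unique
under the (B,k1)↔(C,k2) label symmetry. Rates within a factor 1.2 are
flagged degenerate; a mono-exponential comparison fit is always attached
and an F-test (5%) flags when the simpler model suffices. Condition
comparisons report plateau ratio, initial-rate ratio A(Bk1 + Ck2), and
time-to-90%-of-plateau via root bracketing.

## Chemical shift perturbation (csp)

Scalar 1D CSP: the fluoride centre is fitted in a free and a bound
spectrum and differenced, positive meaning downfield (higher ppm) in the
bound state. Detection inside the search window uses a conservative 5σ
threshold so the "exactly one peak" precondition is not spoiled by noise
excursions; ambiguity raises an error naming the candidates. Significance
is |CSP| > 3 × the combined centre standard error. At the default SNR the
centre precision is ~6×10⁻⁵ ppm, so shifts of 0.01 ppm (and indeed
0.001 ppm) are detected with near-certain power while 10⁻⁴ ppm is not.

## Reproducibility and problem sizes

All stochastic operations take explicit seeds; pipeline stages derive
distinct sub-seeds from the single config seed, so identical configs
produce byte-identical artifacts. The acceptance script's Monte Carlo sizes
— 50 replicates per quantification target, 50 kinetics replicates of 92
hourly points, 20 blanks, 1,000 coverage draws in the test suite — were
chosen to put the Monte Carlo error of each reported median well below the
tolerance it is judged against while keeping a full run around a minute.

## Known limitations

* Single-Lorentzian lines; no Voigt/Gaussian shapes, no deconvolution of
  more than two overlapped peaks.
* The ppm axis trusts the carrier; no lock-based re-referencing to CFCl₃.
* Calibration assumes homoscedastic area noise (true under the generator;
  approximately true for real spectra at constant linewidth); no weighted
  fits.
* No Arrhenius modelling across temperatures — each condition is fitted
  independently and compared descriptively.
* Truncation bias at narrow linewidths is faithful to the physics and
  cancels in calibrated quantities, but absolute areas of slowly decaying
  lines read a few percent high unless apodized or acquired longer.
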