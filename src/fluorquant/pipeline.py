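"""Configurable end-to-end runs.

A :class:`RunConfig` describes which stages to execute — simulate, process,
peak fitting, quantification, kinetics, CSP — with all stage parameters and
a single global seed. Stage-specific seeds are derived deterministically
from the global one, so an identical config yields byte-identical outputs.
Each run writes its artifacts plus a manifest recording inputs, parameters
and derived seeds.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .core import (
    FID,
    AcquisitionParameters,
    NoiseModel,
    PeakSpec,
    paper_acquisition,
    read_fid_tsv,
    read_spectrum_tsv,
    write_fid_tsv,
    write_spectrum_tsv,
)
from .csp import compute_csp
from .kinetics import LeachingModel, fit_leaching, time_to_fraction
from .peaks import detect_peaks, estimate_noise, fit_lorentzian, peak_table
from .processing import process_fid
from .quantify import fit_calibration, invert_calibration
from .synthetic import default_noise_model, simulate_fid
from .workflow import (
    DEFAULT_STANDARDS_UM,
    NOISE_REGION_PPM,
    Calibration,
    build_calibration,
    estimate_unknown,
)

__all__ = ["RunConfig", "run_pipeline", "derive_seed"]

_STAGE_OFFSETS = {
    "simulate": 11,
    "process": 23,
    "peaks": 37,
    "quantify": 53,
    "kinetics": 71,
    "csp": 89,
}


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (global_seed * 1009 + _STAGE_OFFSETS[stage]) % (2**31 - 1)


class PeakConfig(BaseModel):
    center: float
    area: float
    fwhm: float = 5.0
    phase: float = 0.0


class AcquisitionConfig(BaseModel):
    spectral_width: float = 45455.0
    n_complex_points: int = 8192
    carrier_offset: float = -120.0
    spectrometer_frequency: float = 752.7
    n_scans: int = 6400
    relaxation_delay: float = 0.5
    temperature: float = 298.0

    def build(self) -> AcquisitionParameters:
        return AcquisitionParameters(**self.model_dump())


class SimulateStage(BaseModel):
    peaks: list[PeakConfig] = Field(default_factory=list)
    sigma_per_scan: float | None = None  # None → SNR-matched default


class ProcessStage(BaseModel):
    line_broadening: float = 2.0
    zero_fill_factor: int = 2
    phi0: float = 0.0
    phi1: float = 0.0
    auto_phase: bool = False
    baseline_order: int | None = None
    exclusion_windows: list[tuple[float, float]] = Field(default_factory=list)
    input_fid: str | None = None  # read instead of using the simulate stage


class PeaksStage(BaseModel):
    snr_threshold: float = 3.0
    fit_window: float = 1.0
    noise_region: tuple[float, float] = NOISE_REGION_PPM


class QuantifyStage(BaseModel):
    standards_csv: str | None = None  # concentration_um, area
    standards_um: list[float] = Field(default_factory=lambda: list(DEFAULT_STANDARDS_UM))
    unknown_spectrum: str | None = None  # TSV path; None → spectrum from this run
    confidence: float = 0.95
    m_reps: int = 1

    @field_validator("confidence")
    @classmethod
    def _conf(cls, v):
        if not 0 < v < 1:
            raise ValueError("confidence must be in (0, 1)")
        return v


class KineticsStage(BaseModel):
    input_csv: str  # time_h, area_or_concentration
    n_starts: int = 20
    constrain_origin: bool = False


class CspStage(BaseModel):
    free_spectrum: str
    bound_spectrum: str
    search_window: tuple[float, float] = (-121.0, -119.0)


class RunConfig(BaseModel):
    """Full pipeline description; serialises losslessly to and from JSON."""

    seed: int = 0
    outdir: str = "fluorquant_run"
    log_level: str = "INFO"
    acquisition: AcquisitionConfig = Field(default_factory=AcquisitionConfig)
    simulate: SimulateStage | None = None
    process: ProcessStage | None = None
    peaks: PeaksStage | None = None
    quantify: QuantifyStage | None = None
    kinetics: KineticsStage | None = None
    csp: CspStage | None = None

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate_json(Path(path).read_text())

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=1))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order and write artifacts + manifest.

    Returns the manifest dictionary. A stage failure is recorded in the
    manifest and re-raised after earlier artifacts are preserved on disk.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    acq = config.acquisition.build()
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "config": json.loads(config.model_dump_json()),
    }
    fid: FID | None = None
    spectrum = None

    def record(stage: str, **info):
        manifest["stages"][stage] = info
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))

    try:
        if config.simulate is not None:
            st = config.simulate
            peaks = [PeakSpec(p.center, p.area, p.fwhm, p.phase) for p in st.peaks]
            sigma = st.sigma_per_scan
            noise = (
                default_noise_model(acq=acq)
                if sigma is None
                else NoiseModel(sigma_per_scan=sigma)
            )
            seed = derive_seed(config.seed, "simulate")
            fid = simulate_fid(peaks, acq, noise, rng=np.random.default_rng(seed))
            write_fid_tsv(fid, outdir / "fid.tsv")
            record("simulate", artifact="fid.tsv", derived_seed=seed,
                   sigma_per_scan=noise.sigma_per_scan, n_peaks=len(peaks))

        if config.process is not None:
            st = config.process
            if st.input_fid is not None:
                fid = read_fid_tsv(st.input_fid)
            if fid is None:
                raise ValueError("process stage needs a simulated or input FID")
            spectrum = process_fid(
                fid,
                line_broadening=st.line_broadening,
                zero_fill_factor=st.zero_fill_factor,
                phi0=st.phi0,
                phi1=st.phi1,
                auto_phase=st.auto_phase,
                baseline_order=st.baseline_order,
                exclusion_windows=st.exclusion_windows or None,
            )
            write_spectrum_tsv(spectrum, outdir / "spectrum.tsv")
            record("process", artifact="spectrum.tsv")

        if config.peaks is not None:
            st = config.peaks
            if spectrum is None:
                raise ValueError("peaks stage needs a processed spectrum")
            noise_est = estimate_noise(spectrum, st.noise_region)
            centers = detect_peaks(spectrum, st.snr_threshold, noise=noise_est)
            fits = [fit_lorentzian(spectrum, c, window=st.fit_window) for c in centers]
            table = peak_table(fits, noise_est)
            table.to_csv(outdir / "peaks.csv", index=False)
            record("peaks", artifact="peaks.csv", n_peaks=len(fits),
                   noise_sd=noise_est.sd)

        if config.quantify is not None:
            st = config.quantify
            seed = derive_seed(config.seed, "quantify")
            if st.standards_csv is not None:
                df = pd.read_csv(st.standards_csv)
                pairs = list(zip(df["concentration_um"], df["area"]))
                ref = max(a for _, a in pairs)
                cal = Calibration(
                    fit=fit_calibration([(c, a / ref) for c, a in pairs]),
                    reference_area=ref,
                    fwhm_hz=float("nan"),
                )
            else:
                from .synthetic import simulate_calibration_series

                series = simulate_calibration_series(
                    st.standards_um, acq=acq, seed=seed
                )
                cal = build_calibration(series)
            target = (
                read_spectrum_tsv(st.unknown_spectrum)
                if st.unknown_spectrum is not None
                else spectrum
            )
            if target is None:
                raise ValueError("quantify stage needs an unknown spectrum")
            est = estimate_unknown(
                target, cal, m_reps=st.m_reps, confidence=st.confidence
            )
            result = {
                "estimate_um": est.estimate,
                "interval_um": list(est.interval),
                "confidence": est.confidence,
                "calibration": {
                    "slope": cal.fit.slope,
                    "intercept": cal.fit.intercept,
                    "r_squared": cal.fit.r_squared,
                    "residual_sd": cal.fit.residual_sd,
                    "n": cal.fit.n,
                },
            }
            (outdir / "quantify.json").write_text(json.dumps(result, indent=1))
            record("quantify", artifact="quantify.json", derived_seed=seed, **result)

        if config.kinetics is not None:
            st = config.kinetics
            df = pd.read_csv(st.input_csv)
            data = np.column_stack([df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy()])
            seed = derive_seed(config.seed, "kinetics")
            kfit = fit_leaching(
                data, n_starts=st.n_starts, seed=seed,
                constrain_origin=st.constrain_origin,
            )
            m = kfit.model
            result = {
                "parameters": {"A": m.A, "B": m.B, "C": m.C, "k1": m.k1, "k2": m.k2},
                "standard_errors": kfit.standard_errors,
                "rss": kfit.rss,
                "n_points": kfit.n_points,
                "plateau": m.A,
                "time_to_90pct_h": time_to_fraction(m, 0.9),
                "degenerate_rates": kfit.degenerate_rates,
            }
            (outdir / "kinetics.json").write_text(json.dumps(result, indent=1))
            record("kinetics", artifact="kinetics.json", derived_seed=seed)

        if config.csp is not None:
            st = config.csp
            free = read_spectrum_tsv(st.free_spectrum)
            bound = read_spectrum_tsv(st.bound_spectrum)
            pert = compute_csp(free, bound, search_window=st.search_window)
            result = {
                "delta_free_ppm": pert.delta_free,
                "delta_bound_ppm": pert.delta_bound,
                "csp_ppm": pert.csp,
                "significance": pert.significance,
                "perturbed": pert.perturbed,
            }
            (outdir / "csp.json").write_text(json.dumps(result, indent=1))
            record("csp", artifact="csp.json", **result)
    except Exception as err:  # preserve prior artifacts, mark the failure
        manifest["failed_stage"] = str(err)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
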