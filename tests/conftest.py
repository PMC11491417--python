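import numpy as np
import pytest

from fluorquant.core import NoiseModel, PeakSpec, paper_acquisition
from fluorquant.processing import fourier_transform
from fluorquant.synthetic import default_noise_model, simulate_fid, simulate_spectrum


@pytest.fixture(scope="session")
def acq():
    """Study acquisition parameters: SW 45,455 Hz, −120 ppm carrier, 6,400 scans."""
    return paper_acquisition()


@pytest.fixture(scope="session")
def default_noise(acq):
    return default_noise_model(acq=acq)


@pytest.fixture()
def relaxed_peak():
    """A line wide enough (30 Hz) that the FID fully decays within 0.18 s,
    so closed-form Lorentzian identities hold without truncation effects."""
    return PeakSpec(center=-120.0, area=20.0, fwhm=30.0)


@pytest.fixture()
def relaxed_spectrum(acq, relaxed_peak):
    fid = simulate_fid([relaxed_peak], acq)
    return fourier_transform(fid, zero_fill_factor=2)


@pytest.fixture()
def fig1_spectrum(acq, default_noise):
    """Two-resonance scenario at realistic noise: fluoride −120 ppm,
    5-fluoroindole −126 ppm, both 20 μM-equivalent."""
    peaks = [
        PeakSpec(center=-120.0, area=20.0, fwhm=10.0),
        PeakSpec(center=-126.0, area=20.0, fwhm=10.0),
    ]
    return simulate_spectrum(peaks, acq, default_noise, rng=np.random.default_rng(2024))
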