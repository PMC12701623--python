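import numpy as np
import pytest

from osstap import segmentation as seg
from osstap import synthetic as syn

#: short analysis window used throughout the tests to keep FFTs cheap:
#: 0.1 s at 44.1 kHz still captures essentially all burst energy.
SMALL_FFT = 4410


def build_spectrum_set(
    condition: str,
    n_recordings: int = 2,
    n_blows: int = 10,
    seed0: int = 0,
    fft_length: int = SMALL_FFT,
    **kwargs,
) -> seg.SpectrumSet:
    """Simulate recordings and run the full segmentation pipeline."""
    spectra = []
    for i in range(n_recordings):
        rec = syn.generate_impaction_recording(condition, n_blows, seed=seed0 + i, **kwargs)
        spectra.extend(seg.segment_recording(rec, fft_length=fft_length).spectra)
    return seg.SpectrumSet(condition=condition, spectra=spectra)


def gaussian_set(
    condition: str,
    n: int,
    n_bins: int,
    rng: np.random.Generator,
    mean: np.ndarray | float = 0.0,
    sd: float = 1.0,
) -> seg.SpectrumSet:
    """Spectrum set with iid Gaussian 'amplitudes' for statistical checks.

    The inference machinery only needs a shared bin grid, not unit-sum rows.
    """
    freqs = np.arange(n_bins, dtype=float)
    matrix = rng.normal(0.0, sd, size=(n, n_bins)) + mean
    return seg.SpectrumSet.from_matrix(condition, freqs, matrix)


@pytest.fixture(scope="session")
def fit_set() -> seg.SpectrumSet:
    return build_spectrum_set("fit", seed0=100)


@pytest.fixture(scope="session")
def fracture_set() -> seg.SpectrumSet:
    return build_spectrum_set("fracture", seed0=200)


@pytest.fixture(scope="session")
def loose_set() -> seg.SpectrumSet:
    return build_spectrum_set("loose", seed0=300)
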