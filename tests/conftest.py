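import numpy as np
import pytest

from aisleep.signal_io import EpochedSignal
from aisleep.spectral import FrequencyGrid, SpectralDecomposition

FS = 100.0
SPE = 3000


def pink_noise(rng: np.random.Generator, n: int, alpha: float = 1.5, scale: float = 20.0) -> np.ndarray:
    """1/f^alpha noise via spectral shaping (independent of the package's own)."""
    spectrum = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, d=1.0 / FS)
    shaping = np.ones_like(freqs)
    shaping[1:] = freqs[1:] ** (-alpha / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spectrum * shaping, n)
    return x / x.std() * scale


def make_grid(fmax: float = 50.0, res: float = 0.2) -> FrequencyGrid:
    freqs = np.arange(0.0, fmax + res / 2, res)
    return FrequencyGrid(freqs, res)


def make_decomposition(osc: np.ndarray, grid: FrequencyGrid | None = None) -> SpectralDecomposition:
    grid = grid or make_grid()
    assert osc.shape[1] == grid.frequencies.size
    return SpectralDecomposition(np.zeros_like(osc), osc, grid)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def pink_epochs():
    """50 epochs of pure 1/f^1.5 noise as an EpochedSignal."""
    rng = np.random.default_rng(7)
    epochs = np.stack([pink_noise(rng, SPE) for _ in range(50)])
    return EpochedSignal(epochs, FS)


@pytest.fixture(scope="session")
def small_night():
    """One 240-epoch synthetic night: (recording, ground-truth hypnogram)."""
    from aisleep.synthetic import NightSpec, generate_night

    spec = NightSpec(n_epochs=240, seed=0)
    rec, hyp = generate_night(spec)
    return rec, hyp


@pytest.fixture(scope="session")
def staged_small(small_night):
    """The small night run through the full pipeline once (shared, ~30 s)."""
    from aisleep.staging import StagingConfig, run_aisleep

    rec, hyp = small_night
    stages, densities, intermediates = run_aisleep(rec, StagingConfig())
    return hyp, stages, densities, intermediates
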