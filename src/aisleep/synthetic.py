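"""Seedable generator of ground-truthed synthetic overnight EEG.

Each stage gets a distinct spectral recipe on top of a shared 1/f
background: gamma-band noise for open-eye Wake, a sustained alpha rhythm for
closed-eye Wake, fast-spindle bursts for N2 (sparser in N3), high-amplitude
slow-oscillation trains for N3, and low-amplitude theta for N1/REM. N1 and
REM are spectrally identical by design, so separating them exercises the
temporal-smoothing logic rather than the spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, lfilter

from aisleep.signal_io import (
    N1,
    N2,
    N3,
    REM,
    WAKE,
    EEGRecording,
    Hypnogram,
    write_edf,
)

__all__ = [
    "NightSpec",
    "generate_hypnogram",
    "synthesize_night",
    "generate_night",
    "write_edf",
]

FS = 100.0
EPOCH_S = 30.0
SPE = int(FS * EPOCH_S)  # samples per epoch

_STAGES = (WAKE, N1, N2, N3, REM)

#: semi-Markov transition probabilities between distinct stages
_TRANSITIONS = {
    WAKE: ((N1, 0.75), (N2, 0.25)),
    N1: ((N2, 0.70), (WAKE, 0.15), (REM, 0.15)),
    N2: ((N3, 0.45), (REM, 0.35), (N1, 0.10), (WAKE, 0.10)),
    N3: ((N2, 0.75), (WAKE, 0.15), (REM, 0.10)),
    REM: ((N2, 0.40), (N1, 0.35), (WAKE, 0.25)),
}


@dataclass
class NightSpec:
    """Stage-conditioned recipe parameters for one synthetic night."""

    n_epochs: int = 960
    seed: int = 0
    # shared 1/f background
    background_exponent: float = 1.5
    background_scale_uv: float = 15.0
    # open-eye Wake: gamma-band noise
    gamma_band: tuple[float, float] = (25.0, 50.0)
    gamma_amp_uv: float = 12.0
    # closed-eye Wake: alpha rhythm (narrowband noise around alpha_freq_hz)
    alpha_freq_hz: float = 10.0
    alpha_bandwidth_hz: float = 1.0
    alpha_amp_uv: float = 30.0
    wake_open_prob: float = 0.5
    # N2/N3: fast spindles (center sampled per night)
    spindle_freq_range: tuple[float, float] = (12.5, 15.5)
    spindle_amp_uv: float = 25.0
    spindle_rate_n2: tuple[int, int] = (4, 8)
    spindle_rate_n3: tuple[int, int] = (2, 5)
    # N3: slow oscillations
    so_freq_range: tuple[float, float] = (0.6, 1.1)
    so_amp_uv: float = 80.0  # half peak-to-peak; PTP = 160 µV > 75 criterion
    so_coverage: tuple[float, float] = (0.35, 0.6)
    # N1/REM: low-amplitude mixed-frequency theta (kept mostly below the
    # 5-20 Hz oscillatory-strength window so it does not mimic alpha)
    theta_band: tuple[float, float] = (3.0, 6.0)
    theta_amp_uv: float = 6.0
    # mean run lengths (epochs) of the semi-Markov stage model
    mean_run_epochs: dict = field(
        default_factory=lambda: {WAKE: 20, N1: 4, N2: 25, N3: 20, REM: 30}
    )
    # optional amplitude-spike injection for artifact-guard tests
    artifact_epoch_indices: tuple = ()
    artifact_amp_uv: float = 600.0

    def __post_init__(self) -> None:
        if self.n_epochs < 40:
            raise ValueError("n_epochs must be >= 40")
        for name in ("background_scale_uv", "gamma_amp_uv", "alpha_amp_uv",
                     "spindle_amp_uv", "so_amp_uv", "theta_amp_uv"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def generate_hypnogram(spec: NightSpec) -> Hypnogram:
    """Sample a stage sequence beginning and ending in Wake.

    Run durations are geometric with the stage's configured mean; transitions
    follow the fixed stage-graph probabilities. Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    stages: list[int] = []
    current = WAKE
    while len(stages) < spec.n_epochs:
        mean = spec.mean_run_epochs[current]
        duration = int(rng.geometric(1.0 / mean))
        stages.extend([current] * duration)
        nxt, probs = zip(*_TRANSITIONS[current])
        current = int(rng.choice(nxt, p=probs))
    codes = np.asarray(stages[: spec.n_epochs], dtype=np.int64)
    # force the trailing run to Wake
    last = codes[-1]
    if last != WAKE:
        t = codes.size - 1
        while t >= 0 and codes[t] == last:
            t -= 1
        codes[t + 1 :] = WAKE
    return Hypnogram(codes)


def _stage_runs(codes: np.ndarray) -> list[tuple[int, int, int]]:
    """(stage, start, end) runs of a code sequence."""
    runs = []
    start = 0
    for t in range(1, codes.size + 1):
        if t == codes.size or codes[t] != codes[start]:
            runs.append((int(codes[start]), start, t))
            start = t
    return runs


def _pink_noise(rng: np.random.Generator, n: int, exponent: float, scale: float) -> np.ndarray:
    """1/f^exponent noise by spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / FS)
    shaping = np.ones_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    shaping[0] = 0.0
    shaped = np.fft.irfft(spectrum * shaping, n)
    return shaped * (scale / shaped.std())


def _band_noise(rng: np.random.Generator, n: int, band: tuple[float, float], amp: float) -> np.ndarray:
    high = min(band[1], 0.499 * FS)  # keep the filter edge below Nyquist
    b, a = butter(4, (band[0], high), btype="bandpass", fs=FS)
    noise = lfilter(b, a, rng.standard_normal(n))
    std = noise.std()
    return noise * (amp / std) if std > 0 else noise


def _spindle_packets(
    rng: np.random.Generator, out: np.ndarray, f_sp: float, amp: float, k: int
) -> None:
    """Add k Hann-enveloped spindle bursts (0.5-1.5 s) to one epoch buffer."""
    for _ in range(k):
        dur = rng.uniform(0.5, 1.5)
        m = int(dur * FS)
        start = rng.integers(0, SPE - m)
        tau = np.arange(m) / FS
        envelope = np.hanning(m)
        phase = rng.uniform(0, 2 * np.pi)
        out[start : start + m] += (
            amp * rng.uniform(0.8, 1.2) * envelope * np.sin(2 * np.pi * f_sp * tau + phase)
        )


def _so_train(rng: np.random.Generator, out: np.ndarray, spec: NightSpec) -> None:
    """Add a train of whole slow-oscillation cycles covering part of the epoch."""
    f_so = rng.uniform(*spec.so_freq_range)
    coverage = rng.uniform(*spec.so_coverage)
    n_cycles = max(1, int(round(coverage * EPOCH_S * f_so)))
    m = int(round(n_cycles / f_so * FS))
    m = min(m, SPE)
    start = rng.integers(0, SPE - m + 1)
    tau = np.arange(m) / FS
    # negative deflection first: matches the detector's wave convention
    out[start : start + m] += -spec.so_amp_uv * np.sin(2 * np.pi * f_so * tau)


def synthesize_night(h: Hypnogram, spec: NightSpec) -> EEGRecording:
    """Render a hypnogram into a 100 Hz µV signal with stage-conditioned content."""
    rng = np.random.default_rng((spec.seed, 1))
    n_epochs = len(h)
    n = n_epochs * SPE
    signal = _pink_noise(rng, n, spec.background_exponent, spec.background_scale_uv)

    f_sp = rng.uniform(*spec.spindle_freq_range)  # personalized per night

    first_wake_run = True
    for stage, start, end in _stage_runs(h.stages):
        i0, i1 = start * SPE, end * SPE
        run_len = i1 - i0
        if stage == WAKE:
            eyes_open = first_wake_run or rng.random() < spec.wake_open_prob
            first_wake_run = False
            if eyes_open:
                signal[i0:i1] += _band_noise(rng, run_len, spec.gamma_band, spec.gamma_amp_uv)
            else:
                half_bw = spec.alpha_bandwidth_hz / 2.0
                alpha_band = (spec.alpha_freq_hz - half_bw, spec.alpha_freq_hz + half_bw)
                signal[i0:i1] += _band_noise(rng, run_len, alpha_band, spec.alpha_amp_uv)
        elif stage == N2:
            for e in range(start, end):
                buf = signal[e * SPE : (e + 1) * SPE]
                k = int(rng.integers(spec.spindle_rate_n2[0], spec.spindle_rate_n2[1] + 1))
                _spindle_packets(rng, buf, f_sp, spec.spindle_amp_uv, k)
        elif stage == N3:
            for e in range(start, end):
                buf = signal[e * SPE : (e + 1) * SPE]
                _so_train(rng, buf, spec)
                k = int(rng.integers(spec.spindle_rate_n3[0], spec.spindle_rate_n3[1] + 1))
                _spindle_packets(rng, buf, f_sp, spec.spindle_amp_uv, k)
        else:  # N1 and REM share the low-amplitude mixed-frequency recipe
            signal[i0:i1] += _band_noise(rng, run_len, spec.theta_band, spec.theta_amp_uv)

    for e in spec.artifact_epoch_indices:
        center = e * SPE + SPE // 2
        signal[center : center + 20] += spec.artifact_amp_uv
    return EEGRecording(signal, FS, channel_label="synthetic Fpz-Cz")


def generate_night(spec: NightSpec) -> tuple[EEGRecording, Hypnogram]:
    """Convenience: sample a hypnogram and render its recording."""
    h = generate_hypnogram(spec)
    return synthesize_night(h, spec), h
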