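"""Per-epoch staging features: band powers, Otsu split, personalized spindle
band, slow-oscillation detection and derived series."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import filtfilt, find_peaks, firwin
from scipy.stats import gaussian_kde

from aisleep.signal_io import EEGRecording, EpochedSignal
from aisleep.spectral import FrequencyGrid, PSDMatrix, SpectralDecomposition


@dataclass
class FeatureSeries:
    """One real value per epoch."""

    values: np.ndarray
    kind: str

    def __len__(self) -> int:
        return int(self.values.shape[0])


@dataclass
class SpindleBand:
    """Personalized fast-spindle band: night-specific peak frequency ± 1 Hz."""

    f_peak: float
    fallback: bool = False

    @property
    def low(self) -> float:
        return self.f_peak - 1.0

    @property
    def high(self) -> float:
        return self.f_peak + 1.0


@dataclass
class SlowOscillationEvent:
    start_s: float
    end_s: float
    neg_peak_uv: float
    pos_peak_uv: float
    neg_duration_s: float
    pos_duration_s: float

    @property
    def ptp_uv(self) -> float:
        return self.pos_peak_uv - self.neg_peak_uv

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


class DegenerateDistributionError(ValueError):
    """Raised when a threshold cannot be derived from a constant series."""


# ---------------------------------------------------------------------------
# Band power and Otsu threshold
# ---------------------------------------------------------------------------


def band_power(
    values: np.ndarray, grid: FrequencyGrid, band: tuple[float, float]
) -> np.ndarray:
    """Per-epoch mean of dB values over bins with band_low < f < band_high."""
    low, high = band
    if high <= low:
        raise ValueError(f"malformed band {band}: expected low < high")
    mask = grid.band_mask(low, high, strict=True)
    if not mask.any():
        raise ValueError(f"band {band} selects no frequency bins")
    return values[:, mask].mean(axis=1)


def gamma_power(psd: PSDMatrix, band: tuple[float, float] = (25.0, 50.0)) -> FeatureSeries:
    return FeatureSeries(band_power(psd.values, psd.grid, band), "gamma_power_db")


def otsu_threshold(values: np.ndarray, n_bins: int = 256) -> float:
    """Histogram-bin-edge threshold maximizing between-class variance.

    Class membership is decided on the actual values (v < t vs v >= t) so the
    result matches exhaustive search over all interior bin edges; ties go to
    the lowest threshold. Constant input raises
    :class:`DegenerateDistributionError`.
    """
    values = np.asarray(values, dtype=np.float64)
    vmin, vmax = values.min(), values.max()
    if vmax == vmin:
        raise DegenerateDistributionError("constant input: no threshold exists")
    edges = np.linspace(vmin, vmax, n_bins + 1)[1:-1]
    srt = np.sort(values)
    csum = np.concatenate([[0.0], np.cumsum(srt)])
    n = srt.size
    # class 0 = values strictly below the edge
    k = np.searchsorted(srt, edges, side="left")
    total = csum[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = csum[k] / k
        mu1 = (total - csum[k]) / (n - k)
        bcv = (k / n) * ((n - k) / n) * (mu0 - mu1) ** 2
    bcv = np.where((k == 0) | (k == n), 0.0, bcv)
    return float(edges[int(np.argmax(bcv))])


# ---------------------------------------------------------------------------
# Personalized spindle band and spindle power
# ---------------------------------------------------------------------------


def personalized_spindle_band(
    dec: SpectralDecomposition,
    search: tuple[float, float] = (5.0, 20.0),
    target: float = 14.0,
    prefer: tuple[float, float] = (12.0, 16.0),
    grid_step: float = 0.05,
) -> SpindleBand:
    """Night-specific fast-spindle band from the smoothed oscillatory PSD.

    Each epoch contributes its peak oscillatory frequency within ``search``;
    a kernel-density curve over those peaks is evaluated on a ``grid_step``
    grid, and the band center is the local maximum closest to ``target``
    (preferring maxima inside ``prefer``). If no local maximum exists the
    center falls back to ``target`` with a warning flag.
    """
    lo, hi = search
    mask = dec.grid.band_mask(lo, hi, strict=False)
    freqs = dec.grid.frequencies[mask]
    f_i = freqs[np.argmax(dec.psd_osc[:, mask], axis=1)]

    if np.ptp(f_i) < 1e-12:  # all epochs peak at the same bin
        return SpindleBand(float(f_i[0]))

    density = gaussian_kde(f_i)  # Scott bandwidth
    f_grid = np.arange(lo, hi + grid_step / 2, grid_step)
    curve = density(f_grid)
    peaks, _ = find_peaks(curve)
    if peaks.size == 0:
        warnings.warn(
            "no local maximum of the peak-frequency density in the search range; "
            f"falling back to {target} Hz",
            stacklevel=2,
        )
        return SpindleBand(float(target), fallback=True)
    cand = f_grid[peaks]
    inside = cand[(cand >= prefer[0]) & (cand <= prefer[1])]
    pool = inside if inside.size else cand
    f_peak = float(pool[np.argmin(np.abs(pool - target))])
    return SpindleBand(f_peak)


def spindle_power(
    dec: SpectralDecomposition,
    band: SpindleBand,
    psd: PSDMatrix | None = None,
    source: str = "psd_osc",
) -> FeatureSeries:
    """Mean dB over the personalized band, from psd_osc (default) or the PSD."""
    if source == "psd_osc":
        values = band_power(dec.psd_osc, dec.grid, (band.low, band.high))
    elif source == "psd":
        if psd is None:
            raise ValueError("source='psd' requires the PSD matrix")
        values = band_power(psd.values, psd.grid, (band.low, band.high))
    else:
        raise ValueError(f"unknown spindle power source {source!r}")
    return FeatureSeries(values, "spindle_power_db")


# ---------------------------------------------------------------------------
# Slow oscillations
# ---------------------------------------------------------------------------


def _bandpass_zero_phase(
    x: np.ndarray, fs: float, low: float, high: float, transition: float
) -> np.ndarray:
    numtaps = int(round(3.3 * fs / transition))
    numtaps = min(numtaps, max(3, x.size // 3 - 1))
    numtaps += 1 - numtaps % 2  # odd
    taps = firwin(numtaps, [low, high], pass_zero=False, fs=fs)
    padlen = min(3 * numtaps, x.size - 1)
    return filtfilt(taps, [1.0], x, padlen=padlen)


def detect_slow_oscillations(
    rec: EEGRecording,
    band: tuple[float, float] = (0.5, 2.0),
    transition: float = 0.2,
    ptp_min_uv: float = 75.0,
    neg_duration_s: tuple[float, float] = (0.3, 1.5),
    pos_duration_s: tuple[float, float] = (0.1, 1.0),
    neg_peak_max_uv: float = -10.0,
    pos_peak_min_uv: float = 10.0,
) -> list[SlowOscillationEvent]:
    """Detect slow oscillations on the 0.5-2 Hz band-passed signal.

    Candidate waves span successive negative-going zero crossings (negative
    deflection first, then positive); a candidate becomes an event iff all
    five criteria hold: peak-to-peak amplitude > 75 µV, negative deflection
    0.3-1.5 s, positive deflection 0.1-1.0 s, negative peak < -10 µV,
    positive peak > 10 µV.
    """
    if rec.duration_s < 4.0:
        raise ValueError("recording shorter than 4 s")
    fs = rec.sampling_rate
    filt = _bandpass_zero_phase(rec.samples, fs, band[0], band[1], transition)

    neg_going = np.flatnonzero((filt[:-1] >= 0) & (filt[1:] < 0)) + 1
    pos_going = np.flatnonzero((filt[:-1] < 0) & (filt[1:] >= 0)) + 1

    events: list[SlowOscillationEvent] = []
    for start, end in zip(neg_going[:-1], neg_going[1:]):
        mid_candidates = pos_going[(pos_going > start) & (pos_going < end)]
        if mid_candidates.size == 0:
            continue
        mid = int(mid_candidates[0])
        neg_dur = (mid - start) / fs
        pos_dur = (end - mid) / fs
        neg_peak = float(filt[start:mid].min())
        pos_peak = float(filt[mid:end].max())
        if not (pos_peak - neg_peak > ptp_min_uv):
            continue
        if not (neg_duration_s[0] < neg_dur < neg_duration_s[1]):
            continue
        if not (pos_duration_s[0] < pos_dur < pos_duration_s[1]):
            continue
        if not (neg_peak < neg_peak_max_uv and pos_peak > pos_peak_min_uv):
            continue
        events.append(
            SlowOscillationEvent(
                start_s=start / fs,
                end_s=end / fs,
                neg_peak_uv=neg_peak,
                pos_peak_uv=pos_peak,
                neg_duration_s=neg_dur,
                pos_duration_s=pos_dur,
            )
        )
    return events


def so_percentage(
    events: list[SlowOscillationEvent], ep: EpochedSignal
) -> FeatureSeries:
    """Summed event duration overlapping each 30-s epoch, divided by 30 s.

    Events straddling an epoch boundary are split proportionally.
    """
    dur = ep.epoch_duration_s
    out = np.zeros(ep.n_epochs)
    for ev in events:
        first = max(int(ev.start_s // dur), 0)
        last = min(int(np.ceil(ev.end_s / dur)), ep.n_epochs)
        for i in range(first, last):
            overlap = min(ev.end_s, (i + 1) * dur) - max(ev.start_s, i * dur)
            if overlap > 0:
                out[i] += overlap
    return FeatureSeries(np.clip(out / dur, 0.0, 1.0), "so_percentage")


# ---------------------------------------------------------------------------
# Oscillatory strength
# ---------------------------------------------------------------------------


def std_osc(
    dec: SpectralDecomposition, band: tuple[float, float] = (5.0, 20.0)
) -> FeatureSeries:
    """Per-epoch std of the oscillatory PSD over bins with 5 < f < 20 Hz."""
    mask = dec.grid.band_mask(band[0], band[1], strict=True)
    return FeatureSeries(dec.psd_osc[:, mask].std(axis=1, ddof=0), "std_osc")


def std_overall(dec: SpectralDecomposition) -> float:
    """Std of the entire oscillatory PSD matrix (the whole-night reference)."""
    return float(dec.psd_osc.std(ddof=0))


def artifact_epochs(ep: EpochedSignal, amplitude_uv: float = 500.0) -> np.ndarray:
    """Boolean mask of epochs whose absolute amplitude exceeds the guard."""
    return np.max(np.abs(ep.epochs), axis=1) > amplitude_uv
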