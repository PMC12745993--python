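"""Reading/writing EEG recordings and hypnograms, and 30-s epoch segmentation.

EDF (European Data Format) support is implemented directly on top of numpy:
the format is a fixed-width ASCII header followed by 16-bit little-endian
integer data records, which keeps the package free of binary-IO dependencies.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy.signal import resample_poly

TARGET_RATE = 100.0
EPOCH_DURATION_S = 30.0

#: stage codes shared across the package
WAKE, N1, N2, N3, REM, UNKNOWN = 0, 1, 2, 3, 4, 5

_STAGE_TOKENS = {
    "W": WAKE,
    "WAKE": WAKE,
    "N1": N1,
    "N2": N2,
    "N3": N3,
    "REM": REM,
    "0": WAKE,
    "1": N1,
    "2": N2,
    "3": N3,
    "4": REM,
    "5": UNKNOWN,
}

# R&K vocabulary -> AASM codes; S3 and S4 merge into N3, movement/unknown drop.
_RK_TOKENS = {
    "W": WAKE,
    "S1": N1,
    "S2": N2,
    "S3": N3,
    "S4": N3,
    "REM": REM,
    "R": REM,
}
_RK_DROP = {"MOVEMENT", "UNKNOWN", "?", "M"}


class SignalIOError(Exception):
    """Raised for malformed files or violated IO preconditions."""


@dataclass
class EEGRecording:
    """A single-channel EEG trace in microvolts."""

    samples: np.ndarray
    sampling_rate: float
    channel_label: str = "EEG"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class EpochedSignal:
    """Non-overlapping 30-s epochs of an :class:`EEGRecording`."""

    epochs: np.ndarray  # (n_epochs, samples_per_epoch)
    sampling_rate: float
    epoch_duration_s: float = EPOCH_DURATION_S

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def samples_per_epoch(self) -> int:
        return self.epochs.shape[1]


@dataclass
class Hypnogram:
    """Per-epoch stage codes: 0 Wake, 1 N1, 2 N2, 3 N3, 4 REM, 5 Unknown."""

    stages: np.ndarray

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype=np.int64)
        if self.stages.size and not np.all((self.stages >= 0) & (self.stages <= 5)):
            raise ValueError("stage codes must lie in {0..5}")

    def __len__(self) -> int:
        return int(self.stages.shape[0])

    def copy(self) -> "Hypnogram":
        return Hypnogram(self.stages.copy())


# ---------------------------------------------------------------------------
# EDF codec
# ---------------------------------------------------------------------------

_EDF_HEADER_FIXED = 256
_PER_SIGNAL_BYTES = 256


def _ascii(field_bytes: bytes) -> str:
    return field_bytes.decode("ascii", errors="replace").strip()


def _read_edf_header(fh: io.BufferedReader) -> dict:
    fixed = fh.read(_EDF_HEADER_FIXED)
    if len(fixed) < _EDF_HEADER_FIXED:
        raise SignalIOError("not an EDF file: truncated header")
    version = _ascii(fixed[0:8])
    if not version.startswith("0"):
        raise SignalIOError(f"not an EDF file: unexpected version field {version!r}")
    n_records = int(_ascii(fixed[236:244]))
    record_duration = float(_ascii(fixed[244:252]))
    n_signals = int(_ascii(fixed[252:256]))
    per = fh.read(_PER_SIGNAL_BYTES * n_signals)
    if len(per) < _PER_SIGNAL_BYTES * n_signals:
        raise SignalIOError("not an EDF file: truncated signal header")

    def fields(offset: int, width: int) -> list[str]:
        base = offset * n_signals
        return [
            _ascii(per[base + i * width : base + (i + 1) * width])
            for i in range(n_signals)
        ]

    labels = fields(0, 16)
    dims = fields(16 + 80, 8)
    phys_min = [float(x) for x in fields(16 + 80 + 8, 8)]
    phys_max = [float(x) for x in fields(16 + 80 + 8 + 8, 8)]
    dig_min = [int(x) for x in fields(16 + 80 + 8 + 8 + 8, 8)]
    dig_max = [int(x) for x in fields(16 + 80 + 8 + 8 + 8 + 8, 8)]
    spr = [int(x) for x in fields(16 + 80 + 8 * 5 + 80, 8)]
    return {
        "n_records": n_records,
        "record_duration": record_duration,
        "n_signals": n_signals,
        "labels": labels,
        "dims": dims,
        "phys_min": phys_min,
        "phys_max": phys_max,
        "dig_min": dig_min,
        "dig_max": dig_max,
        "samples_per_record": spr,
    }


_UNIT_TO_UV = {"uv": 1.0, "µv": 1.0, "μv": 1.0, "mv": 1e3, "v": 1e6, "": 1.0}


def read_recording(path: str | os.PathLike, channel: str) -> EEGRecording:
    """Read one EDF channel as microvolts at 100 Hz (resampling if needed).

    Raises :class:`SignalIOError` listing available channels if ``channel`` is
    absent, or if the file is not valid EDF.
    """
    with open(path, "rb") as fh:
        hdr = _read_edf_header(fh)
        labels = hdr["labels"]
        if channel not in labels:
            raise SignalIOError(
                f"channel {channel!r} not found; available channels: {labels}"
            )
        idx = labels.index(channel)
        spr = hdr["samples_per_record"]
        total_per_record = sum(spr)
        raw = np.fromfile(fh, dtype="<i2")
    n_records = hdr["n_records"]
    if n_records < 0:  # unknown length marker (-1): infer from file size
        n_records = raw.size // total_per_record
    raw = raw[: n_records * total_per_record].reshape(n_records, total_per_record)
    offsets = np.cumsum([0] + spr)
    digital = raw[:, offsets[idx] : offsets[idx + 1]].astype(np.float64).ravel()

    pmin, pmax = hdr["phys_min"][idx], hdr["phys_max"][idx]
    dmin, dmax = hdr["dig_min"][idx], hdr["dig_max"][idx]
    if dmax == dmin:
        raise SignalIOError("invalid EDF: digital min equals digital max")
    gain = (pmax - pmin) / (dmax - dmin)
    physical = (digital - dmin) * gain + pmin
    unit = hdr["dims"][idx].lower()
    physical = physical * _UNIT_TO_UV.get(unit, 1.0)

    fs = spr[idx] / hdr["record_duration"]
    rec = EEGRecording(physical, fs, channel_label=channel)
    if abs(fs - TARGET_RATE) > 1e-9:
        rec = resample_recording(rec, TARGET_RATE)
    return rec


def resample_recording(rec: EEGRecording, target_rate: float) -> EEGRecording:
    """Polyphase anti-aliased resampling to ``target_rate``."""
    frac = Fraction(target_rate / rec.sampling_rate).limit_denominator(1000)
    out = resample_poly(rec.samples, frac.numerator, frac.denominator)
    return EEGRecording(out, target_rate, channel_label=rec.channel_label)


def write_edf(
    rec: EEGRecording,
    path: str | os.PathLike,
    physical_range_uv: float | None = None,
) -> None:
    """Write a single-channel recording as a standard EDF file.

    The signal is quantized to 16 bits over a symmetric physical range
    (the data's absolute maximum unless ``physical_range_uv`` is given).
    The sampling rate must be a positive integer so that one data record
    spans exactly one second.
    """
    fs = rec.sampling_rate
    if abs(fs - round(fs)) > 1e-9 or fs <= 0:
        raise SignalIOError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    samples = rec.samples
    if samples.size % fs:
        pad = fs - samples.size % fs
        samples = np.concatenate([samples, np.zeros(pad)])
    n_records = samples.size // fs

    if physical_range_uv is None:
        physical_range_uv = float(np.max(np.abs(samples))) if samples.size else 1.0
        physical_range_uv = max(physical_range_uv, 1.0)
    pmin, pmax = -physical_range_uv, physical_range_uv
    dmin, dmax = -32768, 32767
    gain = (pmax - pmin) / (dmax - dmin)
    digital = np.clip(np.round((samples - pmin) / gain) + dmin, dmin, dmax)
    digital = digital.astype("<i2")

    def pad_field(text: str, width: int) -> bytes:
        b = text.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    header = b"".join(
        [
            pad_field("0", 8),
            pad_field("X X X X", 80),
            pad_field("Startdate X X X X", 80),
            pad_field("01.01.00", 8),
            pad_field("00.00.00", 8),
            pad_field(str(_EDF_HEADER_FIXED + _PER_SIGNAL_BYTES), 8),
            pad_field("", 44),
            pad_field(str(n_records), 8),
            pad_field("1", 8),
            pad_field("1", 4),
            # per-signal fields (one signal)
            pad_field(rec.channel_label, 16),
            pad_field("", 80),
            pad_field("uV", 8),
            pad_field(f"{pmin:g}", 8),
            pad_field(f"{pmax:g}", 8),
            pad_field(str(dmin), 8),
            pad_field(str(dmax), 8),
            pad_field("", 80),
            pad_field(str(fs), 8),
            pad_field("", 32),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        digital.tofile(fh)


# ---------------------------------------------------------------------------
# Epoch segmentation
# ---------------------------------------------------------------------------


def segment_epochs(rec: EEGRecording) -> EpochedSignal:
    """Cut a recording into consecutive non-overlapping 30-s epochs.

    The epoch grid is anchored at sample 0; a trailing partial epoch is
    discarded. Raises :class:`SignalIOError` if the recording is shorter
    than one epoch.
    """
    spe = int(round(rec.sampling_rate * EPOCH_DURATION_S))
    n_epochs = rec.n_samples // spe
    if n_epochs < 1:
        raise SignalIOError(
            f"recording too short: {rec.duration_s:.1f} s < {EPOCH_DURATION_S:.0f} s"
        )
    epochs = rec.samples[: n_epochs * spe].reshape(n_epochs, spe)
    return EpochedSignal(epochs=epochs, sampling_rate=rec.sampling_rate)


def trim_recording(rec: EEGRecording, start_s: float, end_s: float) -> EEGRecording:
    """Restrict a recording to explicit [start_s, end_s) bounds in seconds."""
    if not 0 <= start_s < end_s:
        raise ValueError("require 0 <= start_s < end_s")
    i0 = int(round(start_s * rec.sampling_rate))
    i1 = min(int(round(end_s * rec.sampling_rate)), rec.n_samples)
    return EEGRecording(rec.samples[i0:i1], rec.sampling_rate, rec.channel_label)


# ---------------------------------------------------------------------------
# Hypnogram text IO
# ---------------------------------------------------------------------------


def read_hypnogram(path: str | os.PathLike) -> Hypnogram:
    """Read a single-column text hypnogram (one stage token per line).

    Recognized tokens: W/N1/N2/N3/REM (case-insensitive) or digits 0..5.
    Unknown tokens raise a parse error naming the offending line.
    """
    codes = []
    with open(path, "r", encoding="ascii") as fh:
        for lineno, line in enumerate(fh, start=1):
            token = line.strip()
            if not token or token.startswith("#"):
                continue
            code = _STAGE_TOKENS.get(token.upper())
            if code is None:
                raise SignalIOError(
                    f"{path}: line {lineno}: unrecognized stage token {token!r}"
                )
            codes.append(code)
    return Hypnogram(np.asarray(codes, dtype=np.int64))


def write_hypnogram(h: Hypnogram, path: str | os.PathLike) -> None:
    """Write one integer stage code per line (round-trips losslessly)."""
    with open(path, "w", encoding="ascii") as fh:
        for code in h.stages:
            fh.write(f"{int(code)}\n")


def merge_rk_stages(tokens: list[str]) -> tuple[Hypnogram, np.ndarray]:
    """Convert R&K tokens to AASM codes for evaluation.

    S3 and S4 merge into N3; MOVEMENT/UNKNOWN epochs are dropped. Returns the
    converted hypnogram and a boolean mask of kept epochs (aligned to input).
    """
    codes, kept = [], []
    for i, token in enumerate(tokens):
        t = token.strip().upper()
        if t in _RK_DROP:
            kept.append(False)
            continue
        if t not in _RK_TOKENS:
            raise SignalIOError(f"unrecognized R&K token {token!r} at position {i}")
        codes.append(_RK_TOKENS[t])
        kept.append(True)
    return Hypnogram(np.asarray(codes, dtype=np.int64)), np.asarray(kept, dtype=bool)
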