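"""Recording I/O, 1-second segmentation, and STFT spectrograms.

Recordings are 16-bit PCM mono WAV files sampled at 4 kHz. Each recording is
cut into contiguous, non-overlapping 1-second segments (a trailing partial
second is discarded), and every 4000-sample segment maps to a 129x32
magnitude spectrogram: FFT length 256, hop 128, Hann window, centred framing
with reflect padding. These are the only STFT parameters that produce the
129x32 shape from 4000 samples with power-of-two sizes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .errors import ContractError, FormatError

DEFAULT_FS = 4000
PCM_FULL_SCALE = 32768.0

#: STFT parameters fixed by the 129x32 output contract.
STFT_NFFT = 256
STFT_HOP = 128
SPECTROGRAM_SHAPE = (129, 32)

#: Default filename convention: ``<sensor_id>_<ISO8601>.wav``.
FILENAME_RE = re.compile(
    r"^(?P<sensor_id>[^_]+)_(?P<timestamp>\d{4}-\d{2}-\d{2}T\d{2}[-:]\d{2}[-:]\d{2}(?:Z|[+-]\d{2}[-:]?\d{2})?)$"
)


@dataclass
class Recording:
    """One sensor minute (nominally): integer samples plus metadata."""

    samples: np.ndarray
    fs: int = DEFAULT_FS
    sensor_id: str = "unknown"
    start_time: datetime | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.fs <= 0:
            raise ContractError(f"fs must be positive, got {self.fs}")
        if self.samples.ndim != 1:
            raise ContractError("samples must be one-dimensional")
        if self.samples.size and (
            self.samples.min() < -32768 or self.samples.max() > 32767
        ):
            raise ContractError("samples outside the 16-bit range")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def normalized(self) -> np.ndarray:
        """Samples scaled to [-1, 1) floats for DSP."""
        return self.samples.astype(np.float64) / PCM_FULL_SCALE


@dataclass
class Segment:
    """Exactly one second of normalized samples from a parent recording."""

    samples: np.ndarray
    index: int
    fs: int = DEFAULT_FS
    sensor_id: str = "unknown"
    start_time: datetime | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.index < 0:
            raise ContractError("segment index must be >= 0")
        if self.samples.size != self.fs:
            raise ContractError(
                f"segment must hold exactly fs={self.fs} samples, got {self.samples.size}"
            )


@dataclass
class Spectrogram:
    """Non-negative magnitude matrix, frequency bins x time frames."""

    magnitudes: np.ndarray
    bin_hz: float
    frame_s: float
    segment_index: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.magnitudes.shape


def parse_filename(path: str | Path) -> tuple[str, datetime | None]:
    """Extract (sensor_id, start_time) from the filename convention.

    Falls back to (stem, None) when the name does not match.
    """
    stem = Path(path).stem
    m = FILENAME_RE.match(stem)
    if m is None:
        return stem, None
    ts = m.group("timestamp").replace("Z", "+00:00")
    # allow '-' in place of ':' inside the time part (filesystem-safe names)
    if ts.count(":") == 0:
        date, _, time = ts.partition("T")
        time = time.replace("-", ":", 2)
        ts = f"{date}T{time}"
    try:
        dt = datetime.fromisoformat(ts)
    except ValueError:
        return m.group("sensor_id"), None
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return m.group("sensor_id"), dt


def read_recording(path: str | Path, filename_regex: re.Pattern | None = None) -> Recording:
    """Read a 16-bit PCM mono WAV file into a :class:`Recording`.

    Sensor id and start time are parsed from the filename convention
    ``<sensor_id>_<ISO8601>.wav``; non-matching names keep the stem as the
    sensor id with no timestamp. Lengths other than 60 s are accepted.
    """
    path = Path(path)
    fs, data = wavfile.read(path)
    if data.dtype != np.int16:
        raise FormatError(f"{path.name}: expected 16-bit PCM, got dtype {data.dtype}")
    if data.ndim != 1:
        raise FormatError(f"{path.name}: expected mono, got {data.ndim} channels")
    if filename_regex is not None:
        m = filename_regex.match(path.stem)
        sensor_id = m.group("sensor_id") if m else path.stem
        start_time = None
    else:
        sensor_id, start_time = parse_filename(path)
    return Recording(samples=data, fs=fs, sensor_id=sensor_id, start_time=start_time)


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording as 16-bit PCM mono WAV."""
    wavfile.write(Path(path), rec.fs, rec.samples.astype(np.int16))


def segment_signal(rec: Recording) -> list[Segment]:
    """Cut a recording into contiguous 1-s segments, dropping the trailing
    partial second. Segment ``i`` spans ``[i, i+1)`` seconds from the start.
    """
    n_full = rec.samples.size // rec.fs
    x = rec.normalized()
    return [
        Segment(
            samples=x[i * rec.fs : (i + 1) * rec.fs],
            index=i,
            fs=rec.fs,
            sensor_id=rec.sensor_id,
            start_time=rec.start_time,
        )
        for i in range(n_full)
    ]


def _hann(n: int) -> np.ndarray:
    return np.hanning(n)


def spectrogram(seg: Segment) -> Spectrogram:
    """Magnitude STFT of a 1-s segment; shape is exactly 129x32 at 4 kHz.

    Centred framing: the signal is reflect-padded by nfft//2 on each side so
    frame ``t`` is centred on sample ``t * hop``; with hop 128 this yields
    1 + floor(4000/128) = 32 frames and nfft//2 + 1 = 129 bins.
    """
    x = seg.samples
    if x.size != 4000:
        raise ContractError(f"spectrogram requires 4000-sample segments, got {x.size}")
    pad = STFT_NFFT // 2
    xp = np.pad(x, pad, mode="reflect")
    n_frames = 1 + x.size // STFT_HOP
    idx = np.arange(STFT_NFFT)[None, :] + STFT_HOP * np.arange(n_frames)[:, None]
    frames = xp[idx] * _hann(STFT_NFFT)[None, :]
    mags = np.abs(np.fft.rfft(frames, n=STFT_NFFT, axis=1)).T
    return Spectrogram(
        magnitudes=mags,
        bin_hz=seg.fs / STFT_NFFT,
        frame_s=STFT_HOP / seg.fs,
        segment_index=seg.index,
    )
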