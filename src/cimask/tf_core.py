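"""Waveform containers, WAV I/O and the short-time Fourier transform.

All downstream processing (mixing, masking, vocoding, metrics) consumes the
:class:`Waveform` and :class:`Spectrogram` types defined here.  The STFT uses
a periodic Hann analysis window at 50% overlap, which satisfies the
constant-overlap-add (COLA) condition so that :func:`istft` reconstructs the
fully-overlapped interior of a signal essentially exactly.

Conventions
-----------
* spectra are one-sided: ``fft_len // 2 + 1`` frequency bins;
* frames are zero-padded on the right when ``fft_len > frame_len``
  (used for the high-resolution 1024-point oracle analysis of 20 ms frames);
* frame count is ``floor((len(x) - frame_len) / hop) + 1`` — no boundary
  padding, so a signal shorter than one frame is an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly
from scipy.signal.windows import hann

__all__ = [
    "Waveform",
    "StftParams",
    "Spectrogram",
    "stft",
    "istft",
    "read_wav",
    "write_wav",
    "resample",
]

DEFAULT_FS = 16000


@dataclass
class Waveform:
    """A finite mono audio signal with its sampling rate in Hz."""

    samples: np.ndarray
    fs: int = DEFAULT_FS

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError(
                f"Waveform must be mono (1-D); got shape {self.samples.shape}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("Waveform contains NaN or Inf samples")
        if self.fs <= 0:
            raise ValueError(f"Sampling rate must be positive; got {self.fs}")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))


@dataclass
class StftParams:
    """Analysis framing: 20 ms frames at 50% overlap by default (16 kHz)."""

    frame_len: int = 320
    hop: int | None = None
    fft_len: int | None = None
    window: str = "hann"

    def __post_init__(self) -> None:
        if self.hop is None:
            self.hop = self.frame_len // 2
        if self.fft_len is None:
            self.fft_len = self.frame_len
        if self.frame_len <= 0 or self.hop <= 0:
            raise ValueError("frame_len and hop must be positive")
        if self.fft_len < self.frame_len:
            raise ValueError(
                f"fft_len ({self.fft_len}) must be >= frame_len ({self.frame_len})"
            )

    @property
    def n_bins(self) -> int:
        return self.fft_len // 2 + 1

    def get_window(self) -> np.ndarray:
        if self.window != "hann":
            raise ValueError(f"Unsupported window {self.window!r}; use 'hann'")
        # periodic Hann: COLA at hop = frame_len / 2
        return hann(self.frame_len, sym=False)

    def n_frames(self, n_samples: int) -> int:
        if n_samples < self.frame_len:
            raise ValueError(
                f"Signal of {n_samples} samples is shorter than one "
                f"{self.frame_len}-sample frame"
            )
        return (n_samples - self.frame_len) // self.hop + 1


@dataclass
class Spectrogram:
    """One-sided complex STFT: ``values[bin, frame]`` plus framing metadata."""

    values: np.ndarray
    params: StftParams
    fs: int = DEFAULT_FS
    n_samples: int | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.ndim != 2:
            raise ValueError("Spectrogram values must be 2-D (bin x frame)")
        if self.values.shape[0] != self.params.n_bins:
            raise ValueError(
                f"Expected {self.params.n_bins} one-sided bins, "
                f"got {self.values.shape[0]}"
            )

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)

    def phase(self) -> np.ndarray:
        return np.angle(self.values)

    def copy_with(self, values: np.ndarray) -> "Spectrogram":
        return Spectrogram(values, self.params, self.fs, self.n_samples)


def _frames(x: np.ndarray, p: StftParams) -> np.ndarray:
    n = p.n_frames(len(x))
    idx = np.arange(p.frame_len)[None, :] + p.hop * np.arange(n)[:, None]
    return x[idx]


def stft(x: Waveform, p: StftParams | None = None) -> Spectrogram:
    """One-sided STFT of ``x`` with Hann analysis window.

    Frames are windowed then zero-padded to ``fft_len``.  Raises if the
    signal is shorter than a single frame.
    """
    if p is None:
        p = StftParams()
    frames = _frames(x.samples, p) * p.get_window()
    spec = np.fft.rfft(frames, n=p.fft_len, axis=1).T
    return Spectrogram(spec, p, x.fs, n_samples=len(x))


def istft(S: Spectrogram) -> Waveform:
    """Overlap-add inverse STFT.

    The analysis window must satisfy COLA at the configured hop (checked);
    reconstruction divides by the summed window so interior samples of a
    round trip match to machine precision.
    """
    p = S.params
    win = p.get_window()
    _check_cola(win, p.hop)
    frames = np.fft.irfft(S.values.T, n=p.fft_len, axis=1)[:, : p.frame_len]
    n_out = S.n_samples if S.n_samples is not None else (
        (S.n_frames - 1) * p.hop + p.frame_len
    )
    extent = (S.n_frames - 1) * p.hop + p.frame_len
    y = np.zeros(max(n_out, extent))
    wsum = np.zeros_like(y)
    for i in range(S.n_frames):
        lo = i * p.hop
        y[lo : lo + p.frame_len] += frames[i]
        wsum[lo : lo + p.frame_len] += win
    nz = wsum > 1e-10
    y[nz] /= wsum[nz]
    return Waveform(y[:n_out], S.fs)


def _check_cola(win: np.ndarray, hop: int, tol: float = 1e-8) -> None:
    n = len(win)
    if n % hop != 0:
        raise ValueError(f"Hop {hop} must divide the frame length {n}")
    # the periodized overlap-add sum must be constant over one hop period
    period = win.reshape(n // hop, hop).sum(axis=0)
    if np.ptp(period) > tol * max(period.max(), 1e-30):
        raise ValueError(
            f"Window/hop ({n}/{hop}) does not satisfy constant overlap-add"
        )


def read_wav(path, resample_to: int | None = None) -> Waveform:
    """Read a mono RIFF WAV file (PCM16/24/32 or float) as float64 in [-1, 1].

    Stereo files are rejected.  ``resample_to`` converts the sampling rate
    with a polyphase resampler.
    """
    fs, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio, got shape {data.shape}")
    if data.dtype == np.int16:
        x = data / 32768.0
    elif data.dtype == np.int32:
        x = data / 2147483648.0
    elif data.dtype == np.uint8:
        x = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        x = data.astype(np.float64)
    else:
        raise ValueError(f"{path}: unsupported WAV encoding {data.dtype}")
    w = Waveform(x, int(fs))
    if resample_to is not None and resample_to != w.fs:
        w = resample(w, resample_to)
    return w


def write_wav(path, x: Waveform) -> None:
    """Write as float32 WAV (lossless round trip at float32 precision)."""
    wavfile.write(path, x.fs, x.samples.astype(np.float32))


def resample(x: Waveform, fs_new: int) -> Waveform:
    """Polyphase resampling to ``fs_new`` Hz."""
    if fs_new <= 0:
        raise ValueError("Target rate must be positive")
    if fs_new == x.fs:
        return Waveform(x.samples.copy(), x.fs)
    frac = Fraction(fs_new, x.fs).limit_denominator(1000)
    y = resample_poly(x.samples, frac.numerator, frac.denominator)
    return Waveform(y, fs_new)
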