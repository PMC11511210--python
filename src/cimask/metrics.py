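"""Objective intelligibility and quality metrics.

* :func:`stoi` — Short-Time Objective Intelligibility (Taal et al.), the
  standard correlation-based intelligibility predictor for normal hearing:
  one-third-octave band envelopes over 384 ms segments, with silent-frame
  removal and a -15 dB signal-to-distortion clipping bound.
* :func:`ncm` — Normalized Covariance Measure, a speech-transmission-index
  style predictor used for vocoded (cochlear-implant-processed) speech;
  operates on per-band temporal envelopes.
* :func:`pesq_mos_map` — the wideband ITU-T P.862.2 logistic mapping from a
  raw PESQ score to MOS-LQO.  The raw psychoacoustic score itself must come
  from a reference P.862 implementation supplied by the caller; only the
  output mapping is provided here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .tf_core import Waveform, resample
from .vocoder import VocoderConfig, channel_envelopes

__all__ = ["ScoreReport", "stoi", "ncm", "pesq_mos_map"]

EPS = np.finfo(np.float64).eps


@dataclass
class ScoreReport:
    metric: str
    value: float
    params: dict = field(default_factory=dict)

    def __float__(self) -> float:
        return float(self.value)


# ---------------------------------------------------------------- STOI ----

_STOI_FS = 10000
_STOI_FRAME = 256
_STOI_FFT = 512
_STOI_HOP = 128
_STOI_NBANDS = 15
_STOI_MINFREQ = 150.0
_STOI_SEG = 30          # 384 ms of 25.6 ms half-overlapped frames
_STOI_BETA = -15.0      # lower SDR clipping bound, dB
_STOI_DYN_RANGE = 40.0  # silent-frame threshold below the loudest frame, dB


def _stoi_window() -> np.ndarray:
    return np.hanning(_STOI_FRAME + 2)[1:-1]


def _frame_signal(x: np.ndarray) -> np.ndarray:
    n = (len(x) - _STOI_FRAME) // _STOI_HOP + 1
    idx = np.arange(_STOI_FRAME)[None, :] + _STOI_HOP * np.arange(n)[:, None]
    return x[idx]


def _remove_silent_frames(x: np.ndarray, y: np.ndarray):
    """Drop frames of the clean signal more than 40 dB below its loudest
    frame (same frames dropped from both signals), then overlap-add back."""
    w = _stoi_window()
    xf = _frame_signal(x) * w
    yf = _frame_signal(y) * w
    energies = 20 * np.log10(np.linalg.norm(xf, axis=1) + EPS)
    keep = energies > np.max(energies) - _STOI_DYN_RANGE
    xf, yf = xf[keep], yf[keep]
    n_out = (len(xf) - 1) * _STOI_HOP + _STOI_FRAME if len(xf) else 0
    xr = np.zeros(n_out)
    yr = np.zeros(n_out)
    for i in range(len(xf)):
        lo = i * _STOI_HOP
        xr[lo : lo + _STOI_FRAME] += xf[i]
        yr[lo : lo + _STOI_FRAME] += yf[i]
    return xr, yr


def _third_octave_matrix(fs: int) -> np.ndarray:
    f = np.linspace(0, fs, _STOI_FFT + 1)[: _STOI_FFT // 2 + 1]
    obm = np.zeros((_STOI_NBANDS, len(f)))
    k = np.arange(_STOI_NBANDS)
    f_lo = _STOI_MINFREQ * 2.0 ** ((2 * k - 1) / 6.0)
    f_hi = _STOI_MINFREQ * 2.0 ** ((2 * k + 1) / 6.0)
    for i in range(_STOI_NBANDS):
        lo = int(np.argmin((f - f_lo[i]) ** 2))
        hi = int(np.argmin((f - f_hi[i]) ** 2))
        obm[i, lo:hi] = 1.0
    return obm


def stoi(clean: Waveform, estimate: Waveform) -> ScoreReport:
    """Short-Time Objective Intelligibility of ``estimate`` given ``clean``.

    Both signals are resampled to 10 kHz; silent frames (judged on the
    clean reference) are removed from both; band envelopes over 15
    one-third-octave bands (from 150 Hz) are compared by correlation over
    384 ms segments after per-segment normalization and clipping at -15 dB
    signal-to-distortion ratio.  Score in [0, 1]; ~1 means fully
    intelligible.  Signals are trimmed to the shorter of the two.
    """
    if clean.fs != estimate.fs:
        raise ValueError("Sampling rates differ")
    n = min(len(clean), len(estimate))
    x = resample(Waveform(clean.samples[:n], clean.fs), _STOI_FS).samples
    y = resample(Waveform(estimate.samples[:n], estimate.fs), _STOI_FS).samples
    x, y = _remove_silent_frames(x, y)
    min_len = (_STOI_SEG - 1) * _STOI_HOP + _STOI_FRAME
    if len(x) < min_len:
        raise ValueError(
            "Signal too short for one STOI analysis segment after "
            "silent-frame removal"
        )

    w = _stoi_window()
    X = np.fft.rfft(_frame_signal(x) * w, n=_STOI_FFT, axis=1)
    Y = np.fft.rfft(_frame_signal(y) * w, n=_STOI_FFT, axis=1)
    obm = _third_octave_matrix(_STOI_FS)
    # band magnitudes, shape (J, M)
    Xb = np.sqrt(obm @ (np.abs(X.T) ** 2))
    Yb = np.sqrt(obm @ (np.abs(Y.T) ** 2))

    M = Xb.shape[1]
    c = 10.0 ** (-_STOI_BETA / 20.0)
    d_sum = 0.0
    n_seg = M - _STOI_SEG + 1
    for m in range(n_seg):
        xs = Xb[:, m : m + _STOI_SEG]
        ys = Yb[:, m : m + _STOI_SEG]
        alpha = np.linalg.norm(xs, axis=1) / (np.linalg.norm(ys, axis=1) + EPS)
        ys_n = np.minimum(ys * alpha[:, None], xs * (1 + c))
        xs_c = xs - xs.mean(axis=1, keepdims=True)
        ys_c = ys_n - ys_n.mean(axis=1, keepdims=True)
        xs_c /= np.linalg.norm(xs_c, axis=1, keepdims=True) + EPS
        ys_c /= np.linalg.norm(ys_c, axis=1, keepdims=True) + EPS
        d_sum += float(np.sum(xs_c * ys_c))
    value = d_sum / (_STOI_NBANDS * n_seg)
    return ScoreReport("STOI", float(np.clip(value, 0.0, 1.0)),
                       {"fs_internal": _STOI_FS, "n_bands": _STOI_NBANDS})


# ----------------------------------------------------------------- NCM ----


def ncm(
    clean_vocoded: Waveform,
    estimate_vocoded: Waveform,
    cfg: VocoderConfig | None = None,
    weights: np.ndarray | None = None,
    env_fs: int = 25,
) -> ScoreReport:
    """Normalized Covariance Measure between two (vocoded) signals.

    Per band i the normalized envelope covariance r_i maps to an apparent
    SNR 10 log10(r_i^2 / (1 - r_i^2)), clipped to [-15, 15] dB, then to a
    transmission index TI_i = (aSNR + 15) / 30; the score is the
    weight-averaged TI.  Bands default to the 8 vocoder analysis bands with
    uniform weights.  Following speech-transmission-index practice, the
    covariance is taken on envelopes resampled to ``env_fs`` Hz (default
    25 Hz), i.e. on the slow modulations that carry intelligibility;
    ``env_fs=None`` correlates at the full rate.  Zero-variance bands are
    skipped with a warning.
    """
    if clean_vocoded.fs != estimate_vocoded.fs:
        raise ValueError("Sampling rates differ")
    n = min(len(clean_vocoded), len(estimate_vocoded))
    if cfg is None:
        cfg = VocoderConfig()
    ex = channel_envelopes(Waveform(clean_vocoded.samples[:n], clean_vocoded.fs), cfg)
    ey = channel_envelopes(Waveform(estimate_vocoded.samples[:n], estimate_vocoded.fs), cfg)
    if env_fs is not None:
        from scipy.signal import resample_poly

        q = max(int(clean_vocoded.fs // env_fs), 1)
        ex = np.stack([resample_poly(e, 1, q) for e in ex])
        ey = np.stack([resample_poly(e, 1, q) for e in ey])
        if ex.shape[1] > 8:
            # drop filter onset/offset transients, which correlate any pair
            ex = ex[:, 2:-2]
            ey = ey[:, 2:-2]
    if weights is None:
        weights = np.ones(cfg.n_channels)
    weights = np.asarray(weights, dtype=np.float64)

    tis, used_w = [], []
    for i in range(cfg.n_channels):
        sx, sy = np.std(ex[i]), np.std(ey[i])
        if sx == 0.0 or sy == 0.0:
            warnings.warn(f"NCM: zero-variance envelope in band {i}; skipped")
            continue
        r = float(np.mean((ex[i] - ex[i].mean()) * (ey[i] - ey[i].mean())) / (sx * sy))
        r2 = min(r * r, 1.0 - 1e-15)
        asnr = np.clip(10.0 * np.log10(r2 / (1.0 - r2)), -15.0, 15.0)
        tis.append((asnr + 15.0) / 30.0)
        used_w.append(weights[i])
    if not tis:
        raise ValueError("NCM undefined: all bands had zero-variance envelopes")
    value = float(np.dot(used_w, tis) / np.sum(used_w))
    return ScoreReport("NCM", value, {"n_bands": len(tis)})


# ---------------------------------------------------------------- PESQ ----


def pesq_mos_map(raw: float) -> ScoreReport:
    """Wideband P.862.2 output mapping: raw PESQ score -> MOS-LQO.

    MOS = 0.999 + 4.0 / (1 + exp(-1.3669 raw + 3.8224)); strictly
    increasing with asymptotes 0.999 and 4.999.  ``raw`` must come from a
    reference P.862 scorer — it is not computed here.
    """
    raw = float(raw)
    if not np.isfinite(raw):
        raise ValueError("Raw PESQ score must be finite")
    value = 0.999 + (4.999 - 0.999) / (1.0 + np.exp(-1.3669 * raw + 3.8224))
    return ScoreReport("PESQ_MOS", float(value), {"raw": raw})
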