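"""Noisy-mixture construction at prescribed global SNR, plus speech-shaped noise.

Noise is always scaled (the clean reference is left untouched so it can serve
as the metric reference), and the scaled noise actually added is returned so
oracle masks can be computed from the exact clean/noise pair.  Training
mixtures draw random noise cuts from the head of a noise recording and test
mixtures from its tail, so that train and test never share noise samples.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import firwin2, lfilter, welch

from .tf_core import Waveform

__all__ = ["mix_at_snr", "random_cut", "make_ssn", "measure_snr"]


def measure_snr(clean: Waveform, noise: Waveform) -> float:
    """Global SNR = 10 log10(sum(clean^2) / sum(noise^2)) in dB."""
    es = float(np.sum(clean.samples**2))
    en = float(np.sum(noise.samples**2))
    if es == 0.0 or en == 0.0:
        raise ValueError("SNR undefined for an all-zero signal")
    return 10.0 * np.log10(es / en)


def mix_at_snr(
    clean: Waveform, noise: Waveform, snr_db: float
) -> tuple[Waveform, Waveform]:
    """Mix ``noise`` into ``clean`` at a global SNR of ``snr_db`` dB.

    The noise is truncated to the clean signal's length and scaled so that
    ``10 log10(E_clean / E_noise) == snr_db``; the mixture is their sum.
    Returns ``(mixture, scaled_noise)`` — the latter is needed to build
    oracle masks.  Raises for silent inputs (SNR undefined).
    """
    if clean.fs != noise.fs:
        raise ValueError(f"Sampling rates differ: {clean.fs} vs {noise.fs}")
    if len(noise) < len(clean):
        raise ValueError(
            f"Noise ({len(noise)}) shorter than clean signal ({len(clean)})"
        )
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite")
    n = noise.samples[: len(clean)]
    es = float(np.sum(clean.samples**2))
    en = float(np.sum(n**2))
    if es == 0.0:
        raise ValueError("Clean signal is silent; SNR undefined")
    if en == 0.0:
        raise ValueError("Noise segment is silent; SNR undefined")
    # es / (g^2 en) = 10^(snr/10)
    gain = np.sqrt(es / en * 10.0 ** (-snr_db / 10.0))
    scaled = Waveform(gain * n, clean.fs)
    mixture = Waveform(clean.samples + scaled.samples, clean.fs)
    return mixture, scaled


def random_cut(
    noise: Waveform,
    n_samples: int,
    region: str = "head",
    rng: np.random.Generator | None = None,
    region_seconds: float = 120.0,
) -> Waveform:
    """Draw a contiguous random segment from the head or tail of a recording.

    ``region='head'`` restricts the draw to the first ``region_seconds`` of
    the recording and ``'tail'`` to the last; a recording shorter than the
    region is used whole.  The start offset is uniform over all admissible
    positions and reproducible under a fixed ``rng``.
    """
    if rng is None:
        rng = np.random.default_rng()
    region_len = min(len(noise), int(round(region_seconds * noise.fs)))
    if region == "head":
        lo = 0
    elif region == "tail":
        lo = len(noise) - region_len
    else:
        raise ValueError(f"Unknown region {region!r}; use 'head' or 'tail'")
    if n_samples > region_len:
        raise ValueError(
            f"Requested {n_samples} samples but the {region} region has "
            f"only {region_len}"
        )
    start = lo + int(rng.integers(0, region_len - n_samples + 1))
    return Waveform(noise.samples[start : start + n_samples], noise.fs)


def make_ssn(
    reference_speech: list[Waveform],
    n_samples: int,
    rng: np.random.Generator | None = None,
    n_taps: int = 512,
) -> Waveform:
    """Speech-shaped noise: white noise filtered to the long-term average
    spectrum (LTAS) of a reference speech corpus.

    The LTAS is estimated by Welch's method on the concatenated corpus and an
    FIR filter is fit to its magnitude, producing stationary noise whose
    long-term spectrum matches the corpus.  Unit RMS output.
    """
    if not reference_speech:
        raise ValueError("Reference corpus is empty")
    if rng is None:
        rng = np.random.default_rng()
    fs = reference_speech[0].fs
    if any(w.fs != fs for w in reference_speech):
        raise ValueError("Reference utterances have inconsistent sampling rates")
    corpus = np.concatenate([w.samples for w in reference_speech])
    nper = min(1024, len(corpus))
    freqs, psd = welch(corpus, fs=fs, nperseg=nper)
    mag = np.sqrt(np.maximum(psd, 1e-20))
    mag /= mag.max()
    fir = firwin2(n_taps + 1, freqs / (fs / 2.0), mag)
    white = rng.standard_normal(n_samples + n_taps)
    shaped = lfilter(fir, [1.0], white)[n_taps:]
    shaped /= np.sqrt(np.mean(shaped**2))
    return Waveform(shaped, fs)
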