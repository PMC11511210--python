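"""Synthetic speech-like and noise-like fixtures.

Real corpora (phonetically balanced sentences, recorded multi-talker babble)
are external audio; this module produces download-free stand-ins with the
statistical structure the rest of the library cares about:

* utterances: a glottal pulse train with a declining, jittered f0 driven
  through per-syllable formant resonators, interleaved with unvoiced
  fricative-like bursts and amplitude-modulated at a syllabic rate
  (2-8 Hz) — harmonic, formant-shaped, non-stationary;
* babble-like noise: a sum of at least eight independent utterance streams
  (non-stationary, speech-spectrum);
* speech-shaped noise: white noise FIR-shaped to the long-term average
  spectrum of a reference utterance set (stationary);
* white noise.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .mixing import make_ssn
from .tf_core import DEFAULT_FS, Waveform

__all__ = ["SynthSpec", "synth_utterance", "synth_noise", "synth_corpus"]


@dataclass
class SynthSpec:
    """Recipe for one synthetic utterance."""

    duration: float = 1.8          # seconds
    fs: int = DEFAULT_FS
    f0: float = 120.0              # mean fundamental, Hz (male-ish)
    f0_jitter: float = 0.03        # relative random-walk step per syllable
    syllable_rate: float = 4.0     # Hz, within the 2-8 Hz syllabic band
    unvoiced_prob: float = 0.3     # probability a syllable onset is a burst
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not (60.0 <= self.f0 <= 400.0):
            raise ValueError("f0 must lie in [60, 400] Hz")
        if not (2.0 <= self.syllable_rate <= 8.0):
            raise ValueError("syllable_rate must lie in [2, 8] Hz")


# plausible (F1, F2, F3) vowel targets in Hz
_VOWELS = np.array([
    (730, 1090, 2440),   # /a/
    (270, 2290, 3010),   # /i/
    (300, 870, 2240),    # /u/
    (530, 1840, 2480),   # /e/
    (570, 840, 2410),    # /o/
    (660, 1720, 2410),   # /ae/
], dtype=float)

_FORMANT_BW = (90.0, 110.0, 170.0)  # resonator bandwidths, Hz


def _resonator(x: np.ndarray, freq: float, bw: float, fs: float) -> np.ndarray:
    r = np.exp(-np.pi * bw / fs)
    theta = 2 * np.pi * freq / fs
    a = [1.0, -2.0 * r * np.cos(theta), r * r]
    b = [1.0 - r]
    return lfilter(b, a, x)


def _voiced_segment(n: int, f0: float, formants: np.ndarray, fs: float,
                    rng: np.random.Generator) -> np.ndarray:
    # impulse train with small per-period jitter, then formant cascade
    src = np.zeros(n)
    t = 0.0
    while t < n:
        src[int(t)] = 1.0
        period = fs / (f0 * (1.0 + 0.01 * rng.standard_normal()))
        t += max(period, 2.0)
    # mild spectral tilt of a glottal source
    src = lfilter([1.0], [1.0, -0.9], src)
    y = src
    for freq, bw in zip(formants, _FORMANT_BW):
        y = _resonator(y, freq, bw, fs)
    return y


def _unvoiced_segment(n: int, formants: np.ndarray, fs: float,
                      rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal(n)
    # fricative-ish: emphasize the upper formant region
    y = _resonator(noise, min(formants[2] * 1.3, 0.45 * fs), 900.0, fs)
    return y


def synth_utterance(spec: SynthSpec | None = None) -> Waveform:
    """Generate one speech-like utterance.

    The utterance is a chain of syllables; each has a raised-cosine
    amplitude envelope (syllabic-rate modulation), a vowel nucleus with
    formants drawn from a small vowel inventory, an f0 random walk with
    overall declination, and optionally an unvoiced onset burst.  Peak
    amplitude 0.5; fixed seed gives bit-identical output.
    """
    if spec is None:
        spec = SynthSpec()
    rng = np.random.default_rng(spec.seed)
    fs = spec.fs
    n_total = int(round(spec.duration * fs))
    syl_len = int(round(fs / spec.syllable_rate))
    out = np.zeros(n_total)
    f0 = spec.f0
    pos = 0
    while pos < n_total:
        n = min(syl_len, n_total - pos)
        vowel = _VOWELS[rng.integers(len(_VOWELS))]
        vowel = vowel * (1.0 + 0.05 * rng.standard_normal(3))
        seg = np.zeros(n)
        burst_len = 0
        if rng.random() < spec.unvoiced_prob:
            burst_len = min(int(0.25 * n), n)
            seg[:burst_len] = 0.35 * _unvoiced_segment(
                burst_len, vowel, fs, rng
            )
        voiced = _voiced_segment(n - burst_len, f0, vowel, fs, rng)
        seg[burst_len:] = voiced
        # raised-cosine syllable envelope -> 2-8 Hz modulation spectrum peak
        env = 0.5 * (1.0 - np.cos(2 * np.pi * np.arange(n) / max(n - 1, 1)))
        seg *= env
        rms = np.sqrt(np.mean(seg**2))
        if rms > 0:
            seg *= (0.8 + 0.4 * rng.random()) / rms
        out[pos : pos + n] += seg
        # f0 declination with a jittered random walk, kept in a speech range
        f0 *= (1.0 - 0.01) * (1.0 + spec.f0_jitter * rng.standard_normal())
        f0 = float(np.clip(f0, 70.0, 350.0))
        pos += n
    out *= 0.5 / np.max(np.abs(out))
    return Waveform(out, fs)


def synth_corpus(n: int, seed: int = 0, duration: float = 1.8,
                 fs: int = DEFAULT_FS) -> list[Waveform]:
    """A list of ``n`` independent utterances, seeds derived from ``seed``."""
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(n)
    out = []
    for i, cs in enumerate(child):
        child_seed = int(cs.generate_state(1)[0] % (2**31))
        out.append(synth_utterance(SynthSpec(duration=duration, fs=fs,
                                             f0=90.0 + 40.0 * (i % 4),
                                             seed=child_seed)))
    return out


def synth_noise(
    kind: str,
    duration: float,
    seed: int = 0,
    reference: list[Waveform] | None = None,
    fs: int = DEFAULT_FS,
) -> Waveform:
    """Generate noise of a given kind at unit RMS.

    ``babble_like``
        Sum of 8 independent synthetic utterance streams, each long enough
        to cover the requested duration (non-stationary).
    ``ssn_like``
        Speech-shaped noise matched to the long-term spectrum of
        ``reference`` (stationary); a reference utterance list is required.
    ``white``
        Flat-spectrum Gaussian noise.
    """
    n_samples = int(round(duration * fs))
    rng = np.random.default_rng(seed)
    if kind == "white":
        x = rng.standard_normal(n_samples)
    elif kind == "babble_like":
        n_talkers = 8
        acc = np.zeros(n_samples)
        for k in range(n_talkers):
            talker = np.zeros(0)
            while len(talker) < n_samples:
                u = synth_utterance(SynthSpec(
                    duration=min(duration, 2.0), fs=fs,
                    f0=85.0 + 30.0 * (k % 5),
                    seed=int(rng.integers(2**31)),
                ))
                talker = np.concatenate([talker, u.samples])
            acc += talker[:n_samples]
        x = acc
    elif kind == "ssn_like":
        if not reference:
            raise ValueError("ssn_like noise requires a reference utterance list")
        return make_ssn(reference, n_samples, rng)
    else:
        raise ValueError(f"Unknown noise kind {kind!r}")
    x = x / np.sqrt(np.mean(x**2))
    return Waveform(x, fs)
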