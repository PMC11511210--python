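"""Eight-channel noise vocoder simulating cochlear-implant hearing.

Signal path (per channel): pre-emphasis shelf (+3 dB/octave above 2 kHz)
-> Butterworth band-pass -> full-wave rectification -> 120 Hz low-pass
(the temporal envelope) -> envelope modulates a band-limited white-noise
carrier -> channels are summed and RMS-normalized to the input level.

The eight analysis bands follow standard CI-simulation practice: center
frequencies 366, 526, 757, 1089, 1566, 2252, 3241, 4662 Hz with band edges
at the geometric means of neighboring centers.  Fine spectral structure is
discarded; only per-band envelopes survive, which is what an implant
delivers to the electrode array.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import bilinear, butter, lfilter, sosfilt

from .tf_core import Waveform

__all__ = ["VocoderConfig", "band_edges", "channel_envelopes", "vocode"]

DEFAULT_CENTERS = (366.0, 526.0, 757.0, 1089.0, 1566.0, 2252.0, 3241.0, 4662.0)


@dataclass
class VocoderConfig:
    """Parameters of the noise vocoder.

    ``preemph_slope_db_oct`` is approximated by a first-order analog shelf
    (a true half-order 3 dB/octave slope has no rational realization); the
    shelf corner sits at ``preemph_cutoff`` and the boost saturates two
    octaves above it.  Filter orders default to common Shannon-style
    vocoder practice: 4th-order band-pass, 2nd-order envelope low-pass.
    """

    n_channels: int = 8
    center_freqs: tuple = DEFAULT_CENTERS
    preemph_cutoff: float = 2000.0
    preemph_slope_db_oct: float = 3.0
    env_lpf_cutoff: float = 120.0
    bpf_order: int = 4
    lpf_order: int = 2
    carrier_seed: int = 0

    def __post_init__(self) -> None:
        cf = np.asarray(self.center_freqs, dtype=np.float64)
        if len(cf) != self.n_channels:
            raise ValueError(
                f"{self.n_channels} channels but {len(cf)} center frequencies"
            )
        if np.any(np.diff(cf) <= 0):
            raise ValueError("Center frequencies must be strictly increasing")
        self.center_freqs = tuple(cf)


def band_edges(cfg: VocoderConfig) -> list[tuple[float, float]]:
    """(lo, hi) edges per channel: geometric means of neighboring centers,
    with the outer edges half a geometric step beyond the end centers."""
    cf = np.asarray(cfg.center_freqs)
    if len(cf) < 2:
        raise ValueError("Need at least 2 channels to derive band edges")
    inner = np.sqrt(cf[:-1] * cf[1:])
    lo0 = cf[0] * np.sqrt(cf[0] / cf[1])
    hiN = cf[-1] * np.sqrt(cf[-1] / cf[-2])
    edges = np.concatenate([[lo0], inner, [hiN]])
    return [(float(edges[i]), float(edges[i + 1])) for i in range(len(cf))]


def _preemph_filter(cfg: VocoderConfig, fs: float):
    # first-order shelf H(s) = (1 + s/wz) / (1 + s/wp); total boost fixed to
    # slope * 2 octaves, so 3 dB/oct -> +6 dB -> wp/wz = 10^(6/20) ~ 2
    wz = 2 * np.pi * cfg.preemph_cutoff
    wp = wz * 10.0 ** (2.0 * cfg.preemph_slope_db_oct / 20.0)
    b, a = bilinear([1.0 / wz, 1.0], [1.0 / wp, 1.0], fs)
    return b, a


def _band_filters(cfg: VocoderConfig, fs: float):
    nyq = fs / 2.0
    soss = []
    for lo, hi in band_edges(cfg):
        if hi >= nyq:
            raise ValueError(
                f"Band edge {hi:.0f} Hz requires fs > {2 * hi:.0f} Hz (fs={fs})"
            )
        soss.append(
            butter(cfg.bpf_order, [lo / nyq, hi / nyq], btype="bandpass",
                   output="sos")
        )
    return soss


def channel_envelopes(x: Waveform, cfg: VocoderConfig | None = None) -> np.ndarray:
    """Per-channel temporal envelopes, shape (n_channels, len(x)).

    Pre-emphasis, band-pass, full-wave rectification and the 120 Hz
    low-pass — i.e. the vocoder analysis path before carrier modulation.
    Envelopes are non-negative (tiny filter undershoots are floored at 0).
    """
    if cfg is None:
        cfg = VocoderConfig()
    b, a = _preemph_filter(cfg, x.fs)
    pre = lfilter(b, a, x.samples)
    lp = butter(cfg.lpf_order, cfg.env_lpf_cutoff / (x.fs / 2.0),
                btype="lowpass", output="sos")
    envs = np.empty((cfg.n_channels, len(x)))
    for i, sos in enumerate(_band_filters(cfg, x.fs)):
        band = sosfilt(sos, pre)
        envs[i] = sosfilt(lp, np.abs(band))
    return np.maximum(envs, 0.0)


def vocode(x: Waveform, cfg: VocoderConfig | None = None) -> Waveform:
    """Noise-vocode ``x``: envelopes remodulate band-limited noise carriers.

    Output has the same length and RMS as the input (silent input stays
    silent).  The carrier noise is drawn from ``cfg.carrier_seed``, so a
    fixed config gives bit-identical output.
    """
    if cfg is None:
        cfg = VocoderConfig()
    envs = channel_envelopes(x, cfg)
    rng = np.random.default_rng(cfg.carrier_seed)
    out = np.zeros(len(x))
    for i, sos in enumerate(_band_filters(cfg, x.fs)):
        carrier = sosfilt(sos, rng.standard_normal(len(x)))
        out += envs[i] * carrier
    rms_in = x.rms()
    rms_out = float(np.sqrt(np.mean(out**2)))
    if rms_in > 0 and rms_out > 0:
        out *= rms_in / rms_out
    return Waveform(out, x.fs)
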