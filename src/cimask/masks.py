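"""Time-frequency masks for supervised speech enhancement.

Seven oracle masks are computed from aligned clean/noise/noisy spectrograms:

========  =====================================  ==============  ==========
mask      definition                             range           phase used
========  =====================================  ==============  ==========
IBM       1[local SNR > LC], LC = mix SNR - 5    {0, 1}          no
IRM       |S|^2 / (|S|^2 + |N|^2)                [0, 1]          no
FFTM      |S| / |Y| (optionally clipped)         [0, inf)        no
PSM       Re(S / Y) = |S|/|Y| cos(th_S - th_Y)   (-inf, inf)     yes
cIRM      S / Y (complex ratio)                  complex         yes
QM        5-level staircase over local SNR       {0,.25,.5,.75,1}  no
PSM+      PSM in [0,2]; IRM where PSM<0; cap 2   [0, 2]          yes
========  =====================================  ==============  ==========

The QM quantizes the Wiener gain function xi/(1+xi) with local criteria
LC1..LC4 = mixture SNR - {8, 6, 4, 2} dB; boundary ties resolve upward
(half-open bands [LCk, LCk+1), top level for SNR >= LC4), giving a monotone
total partition of the local-SNR axis.  The PSM+ hybrid keeps phase-aware
gains where they are non-negative, falls back to the IRM where the PSM goes
negative (those units still carry magnitude information), and clips at 2.

Degenerate bins: where |Y| = 0 the ratio masks (FFTM, PSM, cIRM) are set to
0; local SNR is clamped to +/-100 dB where the clean or noise bin is zero,
which makes the SNR-threshold masks (IBM, QM) and the IRM well defined.
Silence carries no speech evidence, so a zero gain is the conservative call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tf_core import Spectrogram

__all__ = [
    "RealMask",
    "ComplexMask",
    "local_snr",
    "ibm",
    "irm",
    "fftm",
    "psm",
    "cirm",
    "qm",
    "psm_plus",
    "quantize_local_snr",
    "apply_mask",
    "apply_complex_mask",
    "mask_histogram",
    "QM_LEVELS",
    "QM_LC_OFFSETS",
    "SNR_CLAMP_DB",
    "MASK_RANGES",
]

SNR_CLAMP_DB = 100.0
QM_LEVELS = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
#: local criteria relative to the mixture SNR, in dB
QM_LC_OFFSETS = np.array([-8.0, -6.0, -4.0, -2.0])

#: declared value range per mask kind (training-target convention:
#: FFTM clipped at 1.5, PSM+ at 2; oracle FFTM/PSM are unbounded)
MASK_RANGES: dict[str, tuple[float, float]] = {
    "ibm": (0.0, 1.0),
    "irm": (0.0, 1.0),
    "fftm": (0.0, 1.5),
    "psm": (-np.inf, np.inf),
    "qm": (0.0, 1.0),
    "psmplus": (0.0, 2.0),
}


@dataclass
class RealMask:
    """A real-valued T-F gain array with a declared kind and value range."""

    values: np.ndarray
    kind: str
    declared_range: tuple[float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)

    @property
    def shape(self):
        return self.values.shape


@dataclass
class ComplexMask:
    """Real/imaginary parts of the complex ideal ratio mask."""

    real_part: np.ndarray
    imag_part: np.ndarray

    def __post_init__(self) -> None:
        self.real_part = np.asarray(self.real_part, dtype=np.float64)
        self.imag_part = np.asarray(self.imag_part, dtype=np.float64)
        if self.real_part.shape != self.imag_part.shape:
            raise ValueError("Real and imaginary parts differ in shape")

    @property
    def shape(self):
        return self.real_part.shape


def _aligned(*specs: Spectrogram) -> None:
    shapes = {s.values.shape for s in specs}
    if len(shapes) != 1:
        raise ValueError(f"Spectrogram shapes differ: {sorted(shapes)}")


def local_snr(S: Spectrogram, N: Spectrogram) -> np.ndarray:
    """Per-unit SNR in dB: 10 log10(|S|^2 / |N|^2), clamped to +/-100 dB."""
    _aligned(S, N)
    es = np.abs(S.values) ** 2
    en = np.abs(N.values) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = 10.0 * np.log10(es / en)
    snr = np.where((es == 0) & (en == 0), 0.0, snr)
    return np.clip(np.nan_to_num(snr, nan=0.0, posinf=SNR_CLAMP_DB,
                                 neginf=-SNR_CLAMP_DB),
                   -SNR_CLAMP_DB, SNR_CLAMP_DB)


def ibm(S: Spectrogram, N: Spectrogram, mixture_snr_db: float,
        lc_offset_db: float = -5.0) -> RealMask:
    """Ideal binary mask: 1 where local SNR strictly exceeds the local
    criterion LC = mixture SNR + ``lc_offset_db`` (default 5 dB below)."""
    lc = mixture_snr_db + lc_offset_db
    values = (local_snr(S, N) > lc).astype(np.float64)
    return RealMask(values, "ibm", MASK_RANGES["ibm"])


def irm(S: Spectrogram, N: Spectrogram) -> RealMask:
    """Ideal ratio mask |S|^2 / (|S|^2 + |N|^2); 0 where both energies are 0.

    Identical to the Wiener gain xi/(1+xi) evaluated at the local SNR
    power ratio xi = |S|^2/|N|^2.
    """
    _aligned(S, N)
    es = np.abs(S.values) ** 2
    en = np.abs(N.values) ** 2
    denom = es + en
    values = np.divide(es, denom, out=np.zeros_like(es), where=denom > 0)
    return RealMask(values, "irm", MASK_RANGES["irm"])


def fftm(S: Spectrogram, Y: Spectrogram, clip: float | None = 1.5) -> RealMask:
    """Spectral magnitude mask |S| / |Y|.

    ``clip`` caps the values (1.5 is the training-target convention);
    ``clip=None`` gives the unbounded oracle mask.  |Y| = 0 bins map to 0.
    """
    _aligned(S, Y)
    ms = np.abs(S.values)
    my = np.abs(Y.values)
    values = np.divide(ms, my, out=np.zeros_like(ms), where=my > 0)
    hi = np.inf if clip is None else float(clip)
    if clip is not None:
        values = np.minimum(values, hi)
    return RealMask(values, "fftm", (0.0, hi))


def psm(S: Spectrogram, Y: Spectrogram) -> RealMask:
    """Phase-sensitive mask Re(S/Y) = (|S|/|Y|) cos(th_S - th_Y).

    Analytically equal to the optimal ratio mask
    (|S|^2 + Re(S N*)) / (|S|^2 + |N|^2 + 2 Re(S N*)); unbounded both ways.
    """
    _aligned(S, Y)
    py = np.abs(Y.values) ** 2
    values = np.divide(
        (S.values * np.conj(Y.values)).real, py,
        out=np.zeros(py.shape), where=py > 0,
    )
    return RealMask(values, "psm", MASK_RANGES["psm"])


def cirm(S: Spectrogram, Y: Spectrogram) -> ComplexMask:
    """Complex ideal ratio mask M = S / Y, as real/imaginary parts:

    M_r = (Y_r S_r + Y_i S_i) / (Y_r^2 + Y_i^2)
    M_i = (Y_r S_i - Y_i S_r) / (Y_r^2 + Y_i^2)

    M_r is identical to the PSM.  |Y| = 0 bins map to 0 + 0j; everywhere
    else applying the mask by complex multiplication recovers S exactly.
    """
    _aligned(S, Y)
    yr, yi = Y.values.real, Y.values.imag
    sr, si = S.values.real, S.values.imag
    py = yr**2 + yi**2
    mr = np.divide(yr * sr + yi * si, py, out=np.zeros_like(py), where=py > 0)
    mi = np.divide(yr * si - yi * sr, py, out=np.zeros_like(py), where=py > 0)
    return ComplexMask(mr, mi)


def quantize_local_snr(grid_db: np.ndarray, mixture_snr_db: float) -> np.ndarray:
    """The QM staircase applied to a local-SNR grid in dB.

    Gain is 0 below LC1, then 0.25 / 0.5 / 0.75 on the half-open bands
    [LC1,LC2) / [LC2,LC3) / [LC3,LC4), and 1 at or above LC4, with
    LC1..LC4 = mixture SNR - {8, 6, 4, 2} dB.  Boundary ties resolve to
    the upper band, so the staircase is a monotone total partition.
    """
    lcs = mixture_snr_db + QM_LC_OFFSETS
    idx = np.searchsorted(lcs, np.asarray(grid_db), side="right")
    return QM_LEVELS[idx]


def qm(S: Spectrogram, N: Spectrogram, mixture_snr_db: float) -> RealMask:
    """Quantized mask: five-level staircase over the local SNR — a monotone
    quantized approximation to the Wiener gain function.

    See :func:`quantize_local_snr` for the band layout.
    """
    values = quantize_local_snr(local_snr(S, N), mixture_snr_db)
    return RealMask(values, "qm", MASK_RANGES["qm"])


def psm_plus(S: Spectrogram, Y: Spectrogram, N: Spectrogram,
             clip: float = 2.0) -> RealMask:
    """Hybrid phase-sensitive mask: PSM where it lies in [0, ``clip``],
    the unit's IRM where the PSM is negative, and ``clip`` above it."""
    p = psm(S, Y).values
    r = irm(S, N).values
    values = np.where(p < 0, r, np.minimum(p, clip))
    return RealMask(values, "psmplus", (0.0, clip))


def apply_mask(M: RealMask, Y: Spectrogram) -> Spectrogram:
    """Estimated speech spectrum S_hat = M * |Y| * exp(j th_Y).

    The noisy phase is reused; only the magnitude is re-weighted.
    """
    if M.shape != Y.values.shape:
        raise ValueError(f"Mask shape {M.shape} != spectrogram {Y.values.shape}")
    mag = np.abs(Y.values)
    phase = np.exp(1j * np.angle(Y.values))
    return Y.copy_with(M.values * mag * phase)


def apply_complex_mask(M: ComplexMask, Y: Spectrogram) -> Spectrogram:
    """S_hat = (M_r + j M_i) * Y, elementwise complex multiplication."""
    if M.shape != Y.values.shape:
        raise ValueError(f"Mask shape {M.shape} != spectrogram {Y.values.shape}")
    return Y.copy_with((M.real_part + 1j * M.imag_part) * Y.values)


def mask_histogram(values: np.ndarray,
                   levels: np.ndarray | None = None,
                   nbins: int = 50) -> dict:
    """Value-distribution summary of a mask.

    For quantized masks pass ``levels`` to get exact per-level fractions;
    otherwise values are binned over their observed range.  Returns a dict
    with ``counts``, ``fractions`` and either ``levels`` or ``edges``.
    """
    v = np.asarray(values).ravel()
    if v.size == 0:
        raise ValueError("Empty mask")
    if levels is not None:
        levels = np.asarray(levels, dtype=np.float64)
        counts = np.array([(np.isclose(v, lv)).sum() for lv in levels])
        if counts.sum() != v.size:
            raise ValueError("Mask contains values outside the given levels")
        return {"levels": levels, "counts": counts,
                "fractions": counts / v.size}
    counts, edges = np.histogram(v, bins=nbins)
    return {"edges": edges, "counts": counts, "fractions": counts / v.size}
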