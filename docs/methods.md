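# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, the numerical policies, and what the
synthetic fixtures do and do not establish.

## Signal analysis

All processing runs at a nominal 16 kHz on mono float64 waveforms. The STFT
uses 20 ms frames (320 samples) at 50% overlap with a periodic Hann window,
which satisfies constant overlap-add, so the overlap-add inverse divides by
the summed window and reconstructs interior samples to machine precision.
Spectra are one-sided (`fft_len/2 + 1` bins). Two analysis resolutions are
used: oracle masks are computed on 1024-point FFTs of the 20 ms frames
(zero-padded), learned masks on 320-point FFTs (161 bins), matching the
estimator's output dimensionality. Frames are counted as
`floor((n - frame_len)/hop) + 1` with no boundary padding; signals shorter
than one frame are rejected rather than padded.

## Mixing

Noisy mixtures are built by truncating a noise recording to the utterance
length and scaling the noise so the global energy ratio hits the requested
SNR exactly; the clean signal is never touched, so it stays valid as the
metric reference, and the exact scaled noise is returned for oracle-mask
construction. Training mixtures draw random contiguous cuts from the first
two minutes of a noise recording, test mixtures from the last two minutes
(whole recording when shorter), so train and test never share noise
samples. Speech-shaped noise is white noise filtered by a 512-tap FIR fit
(via `firwin2`) to the Welch long-term average spectrum of a reference
utterance set; "long-term speech envelope" admits a temporal-envelope
reading, but the long-term-spectrum reading is the one consistent with the
standard definition of SSN (stationary noise matching the corpus
spectrum), and is what we implement.

## Masks

Definitions and ranges are in the README table. Policies that the formulas
leave open:

- **Local SNR** is the energy ratio per T-F unit,
  `10·log10(|S|²/|N|²)`, clamped to ±100 dB where a bin of S or N is zero
  (0 dB where both are zero). The clamp makes the threshold masks (IBM,
  QM) and the IRM total functions.
- **Division-by-zero bins** (|Y| = 0) in FFTM, PSM and cIRM map to gain 0:
  silence carries no speech evidence.
- **QM tie-breaks**: the printed band conditions are inconsistent as
  written; we use half-open bands `[LCk, LCk+1)` with the top level at
  `SNR ≥ LC4`, which is the unique monotone total partition consistent
  with the staircase picture. A value exactly at a criterion takes the
  upper level. The staircase approximates the Wiener gain ξ/(1+ξ); at its
  reference operating point (mixture SNR 5 dB, criteria at −3,−1,1,3 dB)
  the sup-gap to the Wiener gain over ±30 dB is 0.334.
- **Clipping**: oracle evaluation uses unclipped ratios; the
  training-target pathway clips FFTM at 1.5 and PSM+ at 2. No log or tanh
  compression of unbounded masks is applied anywhere.
- **PSM ≡ ORM and cIRM-real ≡ PSM** hold analytically and are enforced in
  tests to 1e-10. Near |Y| = 0 the ORM closed form cancels
  catastrophically in double precision, so the cross-check evaluates the
  ORM side in extended precision; this is a property of the algebraic
  rearrangement, not of the mask.

Real masks are applied as `M·|Y|·e^{jθ_Y}` (noisy phase reused); the cIRM
is applied by complex multiplication and reconstructs S exactly wherever
Y ≠ 0 — hence the oracle-cIRM STOI of 1.000 ± 0.000 that
`scripts/acceptance.py` reproduces.

## Mask estimation

Features are 24-band log-mel energies per frame (HTK mel scale, triangular
filters over the 161-bin spectrum), concatenated with 2-frame regression
deltas (48 dims) and smoothed along time by an order-2 ARMA filter
`y[t] = (y[t-2]+y[t-1]+x[t]+x[t+1]+x[t+2])/5`. The estimator is a
feedforward MLP: sigmoid hidden layers; sigmoid output when the target
range lies in [0, 1] (IBM, IRM, QM), linear otherwise (FFTM, PSM+); MSE
loss; AdaGrad per-parameter scaling with classical momentum stepping from
0.5 to 0.9 after epoch 5; no dropout or pretraining. Mask frames are
spliced into 5-frame context windows on the output side (each example
predicts 5 consecutive frames; overlapping predictions are averaged at
inference and clipped to the target range); input-side splicing is
available via `MlpConfig.splice`. Estimated versions of hard masks are
soft by construction.

Full-scale defaults (`MlpConfig()`: 3×1024 units, base rate 0.0015, batch
256, 20 epochs) describe the reference configuration for corpus-scale
training. The desk-scale experiments in the test suite use 3×128 units,
batch 64, base rate 0.015, 30 epochs, and 3 independent noise cuts per
(utterance, noise, SNR) training condition: with only tens of utterances,
AdaGrad's accumulated-gradient schedule otherwise yields too small a total
step budget, and single noise cuts overfit to noise instances. These are
capacity/optimization choices scaled to the corpus, exposed as ordinary
config parameters.

## Vocoder

The 8-channel noise vocoder follows common CI-simulation practice:
pre-emphasis, per-channel Butterworth band-pass (4th order), full-wave
rectification, 120 Hz 2nd-order Butterworth low-pass (the envelope),
envelope × band-limited white-noise carrier, sum, RMS renormalization.
Channel centers are 366–4662 Hz; band edges sit at geometric means of
neighboring centers, outer edges half a geometric step beyond. The +3
dB/octave pre-emphasis above 2 kHz is approximated by a first-order shelf
whose boost saturates at +6 dB two octaves above the corner (a true
half-order slope has no rational realization). Filter orders and full-wave
rectification are package choices (the underlying description leaves them
open) and are exposed in `VocoderConfig`. Carriers are drawn from
`carrier_seed`, so a fixed config vocodes bit-identically — and clean and
enhanced signals vocoded with the same config share carriers, which is
what envelope-correlation metrics assume.

## Metrics

**STOI** follows the published short-time objective intelligibility
procedure: resample to 10 kHz; remove frames more than 40 dB below the
loudest clean frame (same frames from both signals); 256-sample Hann
frames zero-padded to 512-point FFTs; 15 one-third-octave bands from
150 Hz; per-band, per-384 ms-segment normalization, clipping at −15 dB
signal-to-distortion, and correlation; average over bands and segments.
Validated by algorithmic properties (identity = 1 to 1e-6, monotone
degradation with SNR, [0, 1] bounds) — no external reference
implementation is bundled.

**NCM** extracts the vocoder's 8 band envelopes from both signals,
decimates them to 25 Hz (the slow-modulation band that
speech-transmission-index measures correlate; full-rate correlation is
available via `env_fs=None` but punishes enhancement artifacts that carry
no intelligibility information), drops two edge samples of filter
transient, and maps each band's envelope correlation r through the
apparent-SNR chain `10·log10(r²/(1−r²))`, clipped to ±15 dB, to a
transmission index `(aSNR+15)/30`; the score is the weighted band average
(uniform weights by default). Zero-variance bands are skipped with a
warning.

**PESQ** is represented only by the wideband MOS output mapping
`0.999 + 4/(1 + e^{−1.3669·raw + 3.8224})`; the raw score must come from a
reference P.862 implementation supplied by the caller, and pipeline tables
omit PESQ when none is configured.

## Similarity battery

Amplitude histograms of vocoded signals are binned by Scott's rule
(h = 3.49·σ·n^(−1/3)) on the clean reference and the same edges are reused
for mixture/estimate (comparability requires one grid; out-of-grid values
clip into the outer bins). Distances follow Cha's taxonomy in eight
families; each is also reported as a similarity s = 1 − d, and the family
aggregate is the arithmetic mean of member similarities — except Shannon's
Entropy, reported as the raw KL divergence (lower = more similar), with
0·ln 0 terms dropped and the Q side floored at 1e-12. Two measures are
normalized so that every measure attains similarity exactly 1 at identity:
Motyka (classical peak 1/2; rescaled to [0, 1]) and the inner product
(divided by max(Σp², Σq²)). Unbounded distances (Wave Hedges, Taneja,
Bhattacharyya) can push s = 1 − d below 0 on high-dimensional pdfs; the
aggregate is then dominated by them, which is why the correlation and KLD
columns are the more interpretable summaries on fine grids. The Matusita
distance is computed as the square root of the squared-chord distance so
the self-distance is exactly 0.

## Synthetic fixtures

Utterances are syllable chains: a jittered impulse train (f0 random walk
with declination, 70–350 Hz) through a cascade of three formant resonators
with per-syllable vowel targets, optional fricative-like onset bursts, and
raised-cosine syllable envelopes at 2–8 Hz — yielding harmonic structure,
formants, and syllabic-rate modulation, the features the masks, vocoder
and metrics key on. Babble-like noise sums eight independent utterance
streams; SSN-like noise is spectrum-matched stationary noise; white noise
is flat. Defaults used by the experiment suite: 1.5 s utterances, 20 s
noise recordings, 10 train / 5 test utterances, training SNRs {−5, 0} dB,
test SNRs {−5, 0, 5} dB — sized so a full estimation experiment (five mask
types, two noises, training included) completes in a few minutes on one
CPU.

What passing on these fixtures shows: the processing chains are correct
(exact identities, metric behavior, improvement directions estimated >
mixture and oracle ≥ estimated). What it does not show: absolute scores
comparable to real speech corpora — synthetic utterances are cleaner and
more self-similar than recorded sentences, so learned-mask scores here
overstate within-corpus generalization and say nothing about
across-speaker generalization. Corpus-dependent quantities (score tables
on recorded sentences, mask-value histogram percentages) require the real
audio and are intentionally not asserted.

## Known limitations

- Single male-like synthetic voice model; no across-speaker evaluation.
- The cIRM is oracle-only (unbounded; not estimated), as intended.
- No reverberation or multi-channel mixing; no gammatone front-end.
- NCM band-importance weights default to uniform; ANSI-style weights can
  be passed but no calibrated set ships with the package.
- Runtime profiling of mask construction is hardware-dependent and out of
  scope.
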