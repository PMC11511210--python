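"""Mel features and multilayer-perceptron mask estimation.

The estimator learns a mapping from noisy-mixture acoustic features to
oracle T-F masks.  Features are 24-band log-mel energies per 20 ms frame
(50% overlap), concatenated with delta features and smoothed along time by
an auto-regressive moving-average (ARMA) filter.  The network is a plain
feedforward MLP — sigmoid hidden layers, mean-squared-error loss, AdaGrad
per-parameter learning-rate scaling with classical momentum that steps from
0.5 to 0.9 after epoch 5.  The output activation is a sigmoid when the
target mask range lies in [0, 1] and linear otherwise (FFTM, PSM+).

Mask frames can be spliced into a 5-frame context window on the output
side (each training example predicts the masks of 5 consecutive frames;
overlapping predictions are averaged at inference) or on the input side
(feature context); output splicing is the default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .masks import RealMask
from .tf_core import StftParams, Waveform, stft

__all__ = [
    "MlpConfig",
    "MaskModel",
    "mel_filterbank",
    "extract_features",
    "train",
    "predict_mask",
]

N_MEL = 24
_LOG_FLOOR = 1e-10


# ------------------------------------------------------------- features ----


def mel_filterbank(n_mels: int, n_bins: int, fs: int) -> np.ndarray:
    """Triangular mel filterbank, shape (n_mels, n_bins), HTK mel scale."""
    def hz_to_mel(f):
        return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)

    def mel_to_hz(m):
        return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)

    nyq = fs / 2.0
    mel_pts = np.linspace(0.0, hz_to_mel(nyq), n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    bin_freqs = np.linspace(0.0, nyq, n_bins)
    fb = np.zeros((n_mels, n_bins))
    for i in range(n_mels):
        lo, cen, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (bin_freqs - lo) / (cen - lo)
        down = (hi - bin_freqs) / (hi - cen)
        fb[i] = np.maximum(0.0, np.minimum(up, down))
    return fb


def _delta(x: np.ndarray, width: int = 2) -> np.ndarray:
    """Regression delta features along axis 0 (frames), edge-padded."""
    denom = 2.0 * sum(n * n for n in range(1, width + 1))
    padded = np.pad(x, ((width, width), (0, 0)), mode="edge")
    out = np.zeros_like(x)
    for n in range(1, width + 1):
        out += n * (padded[width + n : len(x) + width + n]
                    - padded[width - n : len(x) + width - n])
    return out / denom


def _arma_smooth(x: np.ndarray, order: int = 2) -> np.ndarray:
    """ARMA smoothing along frames:
    y[t] = (y[t-1] + .. + y[t-m] + x[t] + .. + x[t+m]) / (2m + 1)."""
    m = order
    T = len(x)
    y = x.copy()
    for t in range(m, T - m):
        y[t] = (y[t - m : t].sum(axis=0) + x[t : t + m + 1].sum(axis=0)) / (
            2 * m + 1
        )
    return y


def extract_features(mix: Waveform, params: StftParams | None = None,
                     arma_order: int = 2) -> np.ndarray:
    """Log-mel + delta features of a mixture, shape (frames, 48).

    Framing matches the mask STFT (20 ms, 50% overlap at 16 kHz) so the
    feature rows align one-to-one with mask frames.
    """
    if params is None:
        params = StftParams(frame_len=320, fft_len=320)
    spec = stft(mix, params)
    fb = mel_filterbank(N_MEL, params.n_bins, mix.fs)
    power = np.abs(spec.values.T) ** 2          # (frames, bins)
    logmel = np.log(fb @ power.T + _LOG_FLOOR).T
    feats = np.hstack([logmel, _delta(logmel)])
    return _arma_smooth(feats, order=arma_order)


# ------------------------------------------------------------------ MLP ----


@dataclass
class MlpConfig:
    """MLP hyperparameters (full-scale defaults; shrink for quick runs)."""

    hidden_layers: int = 3
    hidden_units: int = 1024
    lr_scale: float = 0.0015         # AdaGrad base learning rate
    epochs: int = 20
    momentum_initial: float = 0.5
    momentum_final: float = 0.9
    momentum_switch_epoch: int = 5   # momentum_final from this epoch on
    batch_size: int = 256
    context_frames: int = 5
    splice: str = "output"           # 'output', 'input' or 'none'
    seed: int = 0

    def __post_init__(self) -> None:
        if self.momentum_switch_epoch >= self.epochs:
            raise ValueError("momentum switch epoch must precede total epochs")
        if self.splice not in ("output", "input", "none"):
            raise ValueError(f"Unknown splice mode {self.splice!r}")
        if self.context_frames % 2 != 1:
            raise ValueError("context_frames must be odd")
        for name in ("hidden_layers", "hidden_units", "lr_scale", "epochs",
                     "batch_size", "context_frames"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class MaskModel:
    """A trained mask estimator: weights, config and feature statistics."""

    weights: list
    biases: list
    config: MlpConfig
    mask_kind: str
    declared_range: tuple
    n_bins: int
    feat_mean: np.ndarray
    feat_std: np.ndarray
    output_activation: str
    loss_trace: list = field(default_factory=list)

    def save(self, path) -> None:
        arrays = {f"W{i}": w for i, w in enumerate(self.weights)}
        arrays.update({f"b{i}": b for i, b in enumerate(self.biases)})
        arrays["feat_mean"] = self.feat_mean
        arrays["feat_std"] = self.feat_std
        meta = {
            "config": asdict(self.config),
            "mask_kind": self.mask_kind,
            "declared_range": list(self.declared_range),
            "n_bins": self.n_bins,
            "output_activation": self.output_activation,
            "loss_trace": self.loss_trace,
            "n_layers": len(self.weights),
        }
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "MaskModel":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        n = meta["n_layers"]
        return cls(
            weights=[data[f"W{i}"] for i in range(n)],
            biases=[data[f"b{i}"] for i in range(n)],
            config=MlpConfig(**meta["config"]),
            mask_kind=meta["mask_kind"],
            declared_range=tuple(meta["declared_range"]),
            n_bins=meta["n_bins"],
            feat_mean=data["feat_mean"],
            feat_std=data["feat_std"],
            output_activation=meta["output_activation"],
            loss_trace=meta["loss_trace"],
        )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))


def _splice_rows(x: np.ndarray, context: int) -> np.ndarray:
    """Concatenate each row with its +/-(context//2) neighbors (edge-padded)."""
    half = context // 2
    padded = np.pad(x, ((half, half), (0, 0)), mode="edge")
    return np.hstack([padded[i : i + len(x)] for i in range(context)])


def _unsplice_rows(y: np.ndarray, context: int, dim: int) -> np.ndarray:
    """Average the overlapping context copies back to one row per frame."""
    half = context // 2
    T = len(y)
    acc = np.zeros((T, dim))
    cnt = np.zeros((T, 1))
    for c in range(context):
        offset = c - half  # column block c predicts frame t + offset
        blk = y[:, c * dim : (c + 1) * dim]
        lo, hi = max(0, offset), min(T, T + offset)
        acc[lo:hi] += blk[lo - offset : hi - offset]
        cnt[lo:hi] += 1.0
    return acc / cnt


def _forward(model_w, model_b, x, out_act):
    a = x
    activations = [a]
    for i, (W, b) in enumerate(zip(model_w, model_b)):
        z = a @ W + b
        last = i == len(model_w) - 1
        a = z if (last and out_act == "linear") else _sigmoid(z)
        activations.append(a)
    return activations


def train(
    features: list[np.ndarray],
    targets: list[np.ndarray],
    cfg: MlpConfig | None = None,
    mask_kind: str = "irm",
    declared_range: tuple = (0.0, 1.0),
) -> MaskModel:
    """Train an MLP mapping mixture features to oracle mask frames.

    ``features`` and ``targets`` are per-utterance arrays with matching
    frame counts; targets are mask values (frames x bins).  The output
    activation is chosen from ``declared_range``: sigmoid for targets
    within [0, 1], linear otherwise.  Training is deterministic under
    ``cfg.seed`` and records the per-epoch MSE in ``loss_trace``.
    """
    if cfg is None:
        cfg = MlpConfig()
    if len(features) != len(targets) or not features:
        raise ValueError("Need equally many non-empty feature/target lists")
    for f, t in zip(features, targets):
        if len(f) != len(t):
            raise ValueError("Feature/target frame counts differ")
        if not np.all(np.isfinite(t)):
            raise ValueError("Targets contain non-finite values")

    lo, hi = declared_range
    out_act = "sigmoid" if (lo >= 0.0 and hi <= 1.0) else "linear"
    X = np.vstack(features)
    Yt = np.vstack(targets)
    if out_act == "sigmoid" and (Yt.min() < -1e-9 or Yt.max() > 1.0 + 1e-9):
        raise ValueError(
            "Sigmoid output selected for range [0,1] but targets fall "
            f"outside it ({Yt.min():.3g}..{Yt.max():.3g})"
        )
    n_bins = Yt.shape[1]
    if cfg.splice == "output":
        Yt = _splice_rows(Yt, cfg.context_frames)
    elif cfg.splice == "input":
        X = _splice_rows(X, cfg.context_frames)

    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    X = (X - mean) / std

    rng = np.random.default_rng(cfg.seed)
    dims = [X.shape[1]] + [cfg.hidden_units] * cfg.hidden_layers + [Yt.shape[1]]
    Ws = [rng.standard_normal((dims[i], dims[i + 1])) * np.sqrt(1.0 / dims[i])
          for i in range(len(dims) - 1)]
    bs = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]
    accW = [np.zeros_like(W) for W in Ws]
    accb = [np.zeros_like(b) for b in bs]
    velW = [np.zeros_like(W) for W in Ws]
    velb = [np.zeros_like(b) for b in bs]

    n = len(X)
    loss_trace = []
    for epoch in range(cfg.epochs):
        mom = (cfg.momentum_initial if epoch < cfg.momentum_switch_epoch
               else cfg.momentum_final)
        order = rng.permutation(n)
        sq_err = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = X[idx], Yt[idx]
            acts = _forward(Ws, bs, xb, out_act)
            out = acts[-1]
            err = out - yb
            sq_err += float(np.sum(err**2))
            delta = 2.0 * err / (err.size / len(xb))  # d(MSE)/d(out) per sample
            if out_act == "sigmoid":
                delta = delta * out * (1.0 - out)
            for layer in range(len(Ws) - 1, -1, -1):
                a_prev = acts[layer]
                gW = a_prev.T @ delta / len(xb)
                gb = delta.mean(axis=0)
                accW[layer] += gW**2
                accb[layer] += gb**2
                stepW = cfg.lr_scale * gW / (np.sqrt(accW[layer]) + 1e-8)
                stepb = cfg.lr_scale * gb / (np.sqrt(accb[layer]) + 1e-8)
                velW[layer] = mom * velW[layer] - stepW
                velb[layer] = mom * velb[layer] - stepb
                Ws[layer] += velW[layer]
                bs[layer] += velb[layer]
                if layer > 0:
                    delta = (delta @ Ws[layer].T) * a_prev * (1.0 - a_prev)
        loss_trace.append(sq_err / (n * Yt.shape[1]))

    return MaskModel(Ws, bs, cfg, mask_kind, tuple(declared_range), n_bins,
                     mean, std, out_act, loss_trace)


def predict_mask(model: MaskModel, features: np.ndarray) -> RealMask:
    """Estimate a mask from mixture features, shape (bins, frames).

    With output splicing, overlapping context predictions are averaged per
    frame; the result is clipped to the model's declared target range.
    The estimated mask is soft even for hard targets like the IBM.
    """
    cfg = model.config
    if features.ndim != 2:
        raise ValueError("features must be (frames, dim)")
    X = features
    if cfg.splice == "input":
        X = _splice_rows(X, cfg.context_frames)
    if X.shape[1] != len(model.feat_mean):
        raise ValueError(
            f"Feature dim {X.shape[1]} does not match the trained recipe "
            f"({len(model.feat_mean)})"
        )
    X = (X - model.feat_mean) / model.feat_std
    out = _forward(model.weights, model.biases, X, model.output_activation)[-1]
    if cfg.splice == "output":
        out = _unsplice_rows(out, cfg.context_frames, model.n_bins)
    lo, hi = model.declared_range
    values = np.clip(out.T, lo, hi)
    return RealMask(values, model.mask_kind, model.declared_range)
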