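"""Experiment orchestration: oracle and estimated-mask evaluations.

Two experiment shapes are provided:

* :func:`run_oracle_eval` — apply ideal (oracle) masks, computed with full
  knowledge of the clean/noise pair, to mixtures and score the resynthesized
  speech.  This upper-bounds what any estimator can achieve.
* :func:`run_estimation_eval` — train one MLP per mask kind on oracle
  targets from a training corpus, enhance unseen test mixtures with the
  estimated masks, and score intelligibility (STOI), vocoded
  intelligibility (NCM) and vocoded pdf similarity.

Both accept any list of waveforms as the corpus — the synthetic fixture
generator or user-supplied recordings — and are deterministic under a
single top-level seed from which all randomness (noise cuts, carriers,
network init) is derived.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import masks as M
from .estimator import MlpConfig, extract_features, predict_mask, train
from .metrics import ncm, stoi
from .mixing import mix_at_snr, random_cut
from .similarity import pdf_histogram, similarity_suite
from .tf_core import StftParams, Waveform, istft, stft
from .vocoder import VocoderConfig, vocode

__all__ = [
    "run_oracle_eval",
    "run_estimation_eval",
    "oracle_mask",
    "enhance_with_mask",
    "ORACLE_MASKS",
    "ESTIMABLE_MASKS",
]

ORACLE_MASKS = ("ibm", "irm", "fftm", "psm", "qm", "psmplus", "cirm")
#: the cIRM is oracle-only (unbounded); all others can be learned
ESTIMABLE_MASKS = ("ibm", "irm", "fftm", "qm", "psmplus")


def oracle_mask(kind: str, S, N, Y, snr_db: float,
                training_target: bool = False):
    """Compute an oracle mask of the given kind from aligned spectrograms.

    ``training_target=True`` applies the training-target value conventions
    (FFTM clipped at 1.5); oracle evaluation leaves ratios unclipped.
    """
    if kind == "ibm":
        return M.ibm(S, N, snr_db)
    if kind == "irm":
        return M.irm(S, N)
    if kind == "fftm":
        return M.fftm(S, Y, clip=1.5 if training_target else None)
    if kind == "psm":
        return M.psm(S, Y)
    if kind == "qm":
        return M.qm(S, N, snr_db)
    if kind == "psmplus":
        return M.psm_plus(S, Y, N)
    if kind == "cirm":
        return M.cirm(S, Y)
    raise ValueError(f"Unknown mask kind {kind!r}")


def enhance_with_mask(mask, Y) -> Waveform:
    """Apply a real or complex mask to the noisy spectrogram and resynthesize."""
    if isinstance(mask, M.ComplexMask):
        return istft(M.apply_complex_mask(mask, Y))
    return istft(M.apply_mask(mask, Y))


def _summary_rows(scores: dict, metric: str) -> pd.DataFrame:
    rows = []
    for (mask_kind, noise, snr), vals in sorted(scores.items()):
        vals = np.asarray(vals, dtype=float)
        rows.append({
            "mask": mask_kind, "noise": noise, "snr_db": snr, "metric": metric,
            "mean": float(vals.mean()), "median": float(np.median(vals)),
            "std": float(vals.std(ddof=0)), "n": len(vals),
        })
    df = pd.DataFrame(rows)
    return _flag_best_worst(df)


def _flag_best_worst(df: pd.DataFrame) -> pd.DataFrame:
    """Mark the best/worst mask per (noise, SNR): highest mean and lowest
    std is best; when mean and std disagree, the mean wins and a tie flag
    is set.  The mixture baseline is excluded from the ranking."""
    df = df.copy()
    df["best"] = False
    df["worst"] = False
    df["rank_tie"] = False
    for (_, _), grp in df.groupby(["noise", "snr_db"]):
        cand = grp[grp["mask"] != "mix"]
        if cand.empty:
            continue
        best_mean = cand["mean"].idxmax()
        worst_mean = cand["mean"].idxmin()
        df.loc[best_mean, "best"] = True
        df.loc[worst_mean, "worst"] = True
        if cand.loc[best_mean, "std"] != cand["std"].min():
            df.loc[best_mean, "rank_tie"] = True
    return df


def run_oracle_eval(
    corpus: list[Waveform],
    noises: dict[str, Waveform],
    snr_dbs=(-5.0,),
    mask_kinds=ORACLE_MASKS,
    fft_len: int = 1024,
    seed: int = 0,
    noise_region: str = "head",
) -> pd.DataFrame:
    """Score oracle-mask enhancement for every (mask, noise, SNR) condition.

    Each utterance is mixed with a random cut of each noise at each SNR;
    oracle masks are built from the exact clean/noise pair on a
    high-resolution STFT (default FFT length 1024 over 20 ms frames),
    applied, resynthesized and scored with STOI against the clean
    waveform.  A "mix" baseline row (unprocessed mixture) is included.
    Returns a tidy table of mean/median/std per condition with best/worst
    flags.
    """
    if not corpus:
        raise ValueError("Empty corpus")
    for kind in mask_kinds:
        if kind not in ORACLE_MASKS:
            raise ValueError(f"Unknown mask kind {kind!r}")
    rng = np.random.default_rng(seed)
    params = StftParams(frame_len=320, fft_len=fft_len)
    scores: dict = {}
    for noise_name, noise in noises.items():
        for snr in snr_dbs:
            for utt in corpus:
                cut = random_cut(noise, len(utt), region=noise_region, rng=rng)
                mixture, scaled_noise = mix_at_snr(utt, cut, snr)
                S = stft(utt, params)
                N = stft(scaled_noise, params)
                Y = stft(mixture, params)
                scores.setdefault(("mix", noise_name, snr), []).append(
                    stoi(utt, mixture).value
                )
                for kind in mask_kinds:
                    mask = oracle_mask(kind, S, N, Y, snr)
                    est = enhance_with_mask(mask, Y)
                    scores.setdefault((kind, noise_name, snr), []).append(
                        stoi(utt, est).value
                    )
    return _summary_rows(scores, "STOI")


def _train_one(kind: str, train_corpus, noises, train_snrs, cfg: MlpConfig,
               params: StftParams, rng, cuts_per_condition: int) -> "tuple":
    feats, targs = [], []
    for utt in train_corpus:
        for noise in noises.values():
            for snr in train_snrs:
                for _ in range(cuts_per_condition):
                    cut = random_cut(noise, len(utt), region="head", rng=rng)
                    mixture, scaled_noise = mix_at_snr(utt, cut, snr)
                    S = stft(utt, params)
                    N = stft(scaled_noise, params)
                    Y = stft(mixture, params)
                    mask = oracle_mask(kind, S, N, Y, snr,
                                       training_target=True)
                    feats.append(extract_features(mixture, params))
                    targs.append(mask.values.T)
    rng_seed = int(rng.integers(2**31))
    cfg_k = MlpConfig(**{**cfg.__dict__, "seed": rng_seed})
    lo, hi = M.MASK_RANGES[kind]
    return train(feats, targs, cfg_k, mask_kind=kind, declared_range=(lo, hi))


def run_estimation_eval(
    train_corpus: list[Waveform],
    test_corpus: list[Waveform],
    noises: dict[str, Waveform],
    train_snrs=(-5.0, 0.0),
    test_snrs=(-5.0, 0.0, 5.0),
    mask_kinds=ESTIMABLE_MASKS,
    mlp_config: MlpConfig | None = None,
    seed: int = 0,
    include_oracle: bool = True,
    vocoder_config: VocoderConfig | None = None,
    cuts_per_condition: int = 1,
) -> dict[str, pd.DataFrame]:
    """Train per-mask MLPs and evaluate enhancement on unseen mixtures.

    Training mixtures use random noise cuts from the head of each noise
    recording at ``train_snrs``; test mixtures use cuts from the tail at
    ``test_snrs`` (so train and test never share noise samples).
    ``cuts_per_condition`` draws several independent noise cuts per
    (utterance, noise, SNR) training condition — useful on small corpora,
    where noise-instance diversity limits generalization.  Returns a dict
    of tidy tables: ``"stoi"`` on wideband signals, ``"ncm"`` and
    ``"similarity"`` on vocoded signals, each with mixture baseline rows
    and (optionally) oracle rows named ``oracle:<mask>``, plus the trained
    ``"models"``.

    Raises if an utterance appears in both corpora.
    """
    for a in train_corpus:
        for b in test_corpus:
            if len(a) == len(b) and np.array_equal(a.samples, b.samples):
                raise ValueError("Train and test corpora overlap")
    if mlp_config is None:
        mlp_config = MlpConfig()
    if vocoder_config is None:
        vocoder_config = VocoderConfig()
    for kind in mask_kinds:
        if kind not in ESTIMABLE_MASKS:
            raise ValueError(f"Mask kind {kind!r} cannot be estimated")

    rng = np.random.default_rng(seed)
    params = StftParams(frame_len=320, fft_len=320)
    models = {
        kind: _train_one(kind, train_corpus, noises, train_snrs,
                         mlp_config, params, rng, cuts_per_condition)
        for kind in mask_kinds
    }

    stoi_scores: dict = {}
    ncm_scores: dict = {}
    sim_scores: dict = {}
    for noise_name, noise in noises.items():
        for snr in test_snrs:
            for utt in test_corpus:
                cut = random_cut(noise, len(utt), region="tail", rng=rng)
                mixture, scaled_noise = mix_at_snr(utt, cut, snr)
                S = stft(utt, params)
                N = stft(scaled_noise, params)
                Y = stft(mixture, params)
                feats = extract_features(mixture, params)

                clean_voc = vocode(utt, vocoder_config)
                ref_pdf = pdf_histogram(clean_voc)

                def score(name, est: Waveform):
                    key = (name, noise_name, snr)
                    stoi_scores.setdefault(key, []).append(
                        stoi(utt, est).value)
                    est_voc = vocode(est, vocoder_config)
                    ncm_scores.setdefault(key, []).append(
                        ncm(clean_voc, est_voc, vocoder_config).value)
                    rep = similarity_suite(
                        ref_pdf, pdf_histogram(est_voc, edges=ref_pdf.edges))
                    sims = [v for f, v in rep.families.items()
                            if f != "shannons_entropy"]
                    sim_scores.setdefault(key, []).append({
                        "similarity": float(np.mean(sims)),
                        "correlation": rep.correlation,
                        "kld": rep.families["shannons_entropy"],
                        **{f"family_{f}": v for f, v in rep.families.items()},
                    })

                score("mix", mixture)
                for kind in mask_kinds:
                    est_mask = predict_mask(models[kind], feats)
                    score(kind, enhance_with_mask(est_mask, Y))
                    if include_oracle:
                        omask = oracle_mask(kind, S, N, Y, snr,
                                            training_target=True)
                        score(f"oracle:{kind}", enhance_with_mask(omask, Y))

    sim_rows = []
    for (mask_kind, noise_name, snr), recs in sorted(sim_scores.items()):
        agg = {k: float(np.mean([r[k] for r in recs])) for k in recs[0]}
        sim_rows.append({"mask": mask_kind, "noise": noise_name,
                         "snr_db": snr, "n": len(recs), **agg})
    return {
        "stoi": _summary_rows(stoi_scores, "STOI"),
        "ncm": _summary_rows(ncm_scores, "NCM"),
        "similarity": pd.DataFrame(sim_rows),
        "models": models,
    }
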