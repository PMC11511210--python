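"""Histogram pdfs and a battery of pdf similarity / divergence measures.

Amplitude histograms of (vocoded) signals are normalized to probability mass
functions on a shared bin grid (Scott's rule on the reference signal) and
compared with the distance measures of Cha's taxonomy, grouped in eight
families:

* Lp Minkowski: Euclidean, Chebyshev
* L1: Sorensen, Gower, Soergel
* Intersection: Intersection, Wave Hedges, Czekanowski, Motyka, Ruzicka,
  Tanimoto
* Inner Product: Inner Product, Cosine, Kumar-Hassebrook, Dice
* Fidelity: Fidelity, Bhattacharyya, Matusita, Squared Chord
* Squared L2: Squared Euclidean
* Combinations: Taneja, Average(L1, Linf)
* Shannon's Entropy: Kullback-Leibler divergence

Every distance d is converted to a similarity s = 1 - d, so self-similarity
is exactly 1 for every measure (and the KL divergence, reported raw since
lower means more similar, is exactly 0).  Two measures are normalized to
make that hold: the classical Motyka similarity sum(min)/sum(p+q) peaks at
1/2 and is doubled here, and the raw inner product sum(p*q) peaks at
sum(p^2) and is divided by max(sum(p^2), sum(q^2)).  The classical values
are recoverable from the reported ones (halve / rescale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .tf_core import Waveform

__all__ = [
    "Pdf",
    "SimilarityReport",
    "pdf_histogram",
    "scott_bin_width",
    "similarity_suite",
    "kld",
    "pdf_correlation",
    "FAMILIES",
]

_EPS = 1e-12

FAMILIES: dict[str, tuple[str, ...]] = {
    "lp_minkowski": ("euclidean", "chebyshev"),
    "l1": ("sorensen", "gower", "soergel"),
    "intersection": ("intersection", "wave_hedges", "czekanowski",
                     "motyka", "ruzicka", "tanimoto"),
    "inner_product": ("inner_product", "cosine", "kumar_hassebrook", "dice"),
    "fidelity": ("fidelity", "bhattacharyya", "matusita", "squared_chord"),
    "squared_l2": ("squared_euclidean",),
    "combinations": ("taneja", "average"),
    "shannons_entropy": ("kld",),
}


@dataclass
class Pdf:
    """A normalized histogram: bin edges plus probability mass per bin."""

    edges: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.float64)
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if len(self.probs) != len(self.edges) - 1:
            raise ValueError("len(probs) must be len(edges) - 1")
        if np.any(self.probs < 0):
            raise ValueError("Probabilities must be non-negative")
        if abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"Probabilities sum to {self.probs.sum()}, not 1")

    @property
    def nbins(self) -> int:
        return len(self.probs)


@dataclass
class SimilarityReport:
    """Per-measure similarities/distances, per-family aggregates and the
    Pearson correlation between the two pdfs."""

    measures: dict = field(default_factory=dict)   # name -> {distance, similarity}
    families: dict = field(default_factory=dict)   # family -> aggregate value
    correlation: float = 0.0

    @property
    def kld(self) -> float:
        return self.measures["kld"]["distance"]


def scott_bin_width(x: np.ndarray) -> float:
    """Scott's rule: h = 3.49 sigma n^(-1/3)."""
    x = np.asarray(x)
    return 3.49 * float(np.std(x)) * len(x) ** (-1.0 / 3.0)


def pdf_histogram(x: Waveform | np.ndarray, edges: np.ndarray | None = None) -> Pdf:
    """Amplitude histogram of a signal, normalized to probability mass.

    Without ``edges`` the bin width follows Scott's rule on this signal;
    pass the reference pdf's edges to place a second signal on the same
    grid (required by :func:`similarity_suite`).  Values outside supplied
    edges are counted into the outermost bins so the mass still sums to 1.
    """
    samples = x.samples if isinstance(x, Waveform) else np.asarray(x, float)
    if samples.size == 0:
        raise ValueError("Empty signal")
    if edges is None:
        h = scott_bin_width(samples)
        lo, hi = float(samples.min()), float(samples.max())
        if h <= 0 or hi <= lo:
            warnings.warn("Zero-variance signal; falling back to a single bin")
            edges = np.array([lo - 0.5, lo + 0.5])
        else:
            nbins = int(np.ceil((hi - lo) / h))
            edges = lo + np.arange(nbins + 1) * h
    else:
        edges = np.asarray(edges, dtype=np.float64)
        samples = np.clip(samples, edges[0], edges[-1])
    counts, _ = np.histogram(samples, bins=edges)
    return Pdf(edges, counts / counts.sum())


def _check_edges(P: Pdf, Q: Pdf) -> None:
    if len(P.edges) != len(Q.edges) or not np.array_equal(P.edges, Q.edges):
        raise ValueError(
            "Pdfs were built on different bin grids; rebuild the second pdf "
            "with the first one's edges"
        )


def kld(P: Pdf, Q: Pdf) -> float:
    """Kullback-Leibler divergence sum(P ln(P/Q)) in nats.

    Bins with P = 0 contribute 0 (avoiding 0 ln 0); Q is floored at 1e-12
    where P > 0, so the divergence is finite.  Non-negative by Gibbs'
    inequality; 0 iff P = Q.
    """
    _check_edges(P, Q)
    p, q = P.probs, np.maximum(Q.probs, _EPS)
    nz = P.probs > 0
    return float(np.sum(p[nz] * np.log(p[nz] / q[nz])))


def pdf_correlation(P: Pdf, Q: Pdf) -> float:
    """Pearson correlation between the two probability vectors."""
    _check_edges(P, Q)
    p, q = P.probs, Q.probs
    sp, sq = np.std(p), np.std(q)
    if sp == 0.0 or sq == 0.0:
        warnings.warn("Constant pdf vector; correlation undefined, reporting 0")
        return 0.0
    return float(np.corrcoef(p, q)[0, 1])


def _measure_distances(p: np.ndarray, q: np.ndarray) -> dict[str, float]:
    """All distances of the battery on two aligned probability vectors."""
    absdiff = np.abs(p - q)
    mn, mx = np.minimum(p, q), np.maximum(p, q)
    sum_pq = p.sum() + q.sum()          # = 2 for proper pdfs
    pp, qq, pq = np.sum(p * p), np.sum(q * q), np.sum(p * q)
    sqrt_pq = np.sqrt(p * q)

    d: dict[str, float] = {}
    d["euclidean"] = np.sqrt(np.sum(absdiff**2))
    d["chebyshev"] = np.max(absdiff)
    d["sorensen"] = np.sum(absdiff) / sum_pq
    d["gower"] = np.sum(absdiff) / len(p)
    d["soergel"] = np.sum(absdiff) / np.sum(mx) if np.sum(mx) > 0 else 0.0
    d["intersection"] = 1.0 - np.sum(mn)
    wh = np.divide(absdiff, mx, out=np.zeros_like(mx), where=mx > 0)
    d["wave_hedges"] = np.sum(wh)
    d["czekanowski"] = np.sum(absdiff) / sum_pq
    # classical Motyka distance is sum(max)/sum(p+q), in [1/2, 1];
    # normalized here to [0, 1] so identity gives distance 0
    d["motyka"] = 2.0 * np.sum(mx) / sum_pq - 1.0
    smx = np.sum(mx)
    d["ruzicka"] = 1.0 - (np.sum(mn) / smx if smx > 0 else 1.0)
    d["tanimoto"] = (smx - np.sum(mn)) / smx if smx > 0 else 0.0
    # raw inner product peaks at sum(p^2) != 1; normalized by the larger
    # self-product so identity gives similarity 1
    d["inner_product"] = 1.0 - pq / max(pp, qq)
    d["cosine"] = 1.0 - pq / max(np.sqrt(pp * qq), _EPS)
    d["kumar_hassebrook"] = 1.0 - pq / max(pp + qq - pq, _EPS)
    d["dice"] = 1.0 - 2.0 * pq / max(pp + qq, _EPS)
    fid = np.sum(sqrt_pq)
    d["fidelity"] = 1.0 - fid
    d["bhattacharyya"] = -np.log(max(fid, _EPS))
    d["squared_chord"] = np.sum((np.sqrt(p) - np.sqrt(q)) ** 2)
    # sqrt of the squared chord, not sqrt(2 - 2 fid): the former is exactly
    # zero at identity, the latter loses half the digits to cancellation
    d["matusita"] = np.sqrt(d["squared_chord"])
    d["squared_euclidean"] = np.sum(absdiff**2)
    m = (p + q) / 2.0
    nz = m > 0
    d["taneja"] = float(np.sum(
        m[nz] * np.log(m[nz] / np.maximum(sqrt_pq[nz], _EPS))
    ))
    d["average"] = (np.sum(absdiff) + np.max(absdiff)) / 2.0
    return {k: float(v) for k, v in d.items()}


def similarity_suite(P: Pdf, Q: Pdf,
                     aggregate: str = "mean") -> SimilarityReport:
    """Run the full measure battery on two pdfs sharing a bin grid.

    Every distance-based measure is reported both as a distance and as the
    similarity s = 1 - d.  Family aggregates (default: arithmetic mean of
    the member similarities) follow the table layout of the battery, except
    Shannon's Entropy which is reported as the raw KL divergence (lower is
    more similar).  A Pearson correlation between the pdf vectors is
    attached as well.
    """
    _check_edges(P, Q)
    if aggregate != "mean":
        raise ValueError(f"Unknown aggregate {aggregate!r}")
    dists = _measure_distances(P.probs, Q.probs)
    dists["kld"] = kld(P, Q)
    measures = {
        name: {"distance": dv, "similarity": 1.0 - dv}
        for name, dv in dists.items()
    }
    measures["kld"]["similarity"] = np.nan  # divergence reported raw
    families = {}
    for fam, members in FAMILIES.items():
        if fam == "shannons_entropy":
            families[fam] = measures["kld"]["distance"]
        else:
            families[fam] = float(np.mean(
                [measures[m]["similarity"] for m in members]
            ))
    return SimilarityReport(measures, families, pdf_correlation(P, Q))
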