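import numpy as np
import pytest

from cimask.similarity import (
    FAMILIES,
    Pdf,
    kld,
    pdf_correlation,
    pdf_histogram,
    scott_bin_width,
    similarity_suite,
)
from cimask.tf_core import Waveform


def _pdf(probs, edges=None):
    probs = np.asarray(probs, dtype=float)
    if edges is None:
        edges = np.arange(len(probs) + 1, dtype=float)
    return Pdf(edges, probs)


class TestPdfHistogram:
    def test_probabilities_sum_to_one(self, rng):
        p = pdf_histogram(Waveform(rng.standard_normal(5000) * 0.1))
        assert p.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_scott_rule_width(self, rng):
        x = rng.standard_normal(1000)
        h = scott_bin_width(x)
        assert h == pytest.approx(3.49 * np.std(x) * 1000 ** (-1 / 3))
        assert h == pytest.approx(0.349 * np.std(x), rel=1e-3)

    def test_supplied_edges_reused_verbatim(self, rng):
        a = pdf_histogram(rng.standard_normal(1000))
        b = pdf_histogram(rng.standard_normal(1000) * 2, edges=a.edges)
        np.testing.assert_array_equal(a.edges, b.edges)

    def test_zero_variance_falls_back_to_single_bin(self):
        with pytest.warns(UserWarning, match="single bin"):
            p = pdf_histogram(np.full(100, 0.7))
        assert p.nbins == 1 and p.probs[0] == 1.0

    def test_empty_signal_raises(self):
        with pytest.raises(ValueError, match="[Ee]mpty"):
            pdf_histogram(np.zeros(0))


class TestSimilaritySuite:
    def test_self_similarity_is_one_for_every_measure(self, rng):
        p = pdf_histogram(rng.standard_normal(2000))
        rep = similarity_suite(p, p)
        for name, entry in rep.measures.items():
            if name == "kld":
                assert entry["distance"] == pytest.approx(0.0, abs=1e-12)
            else:
                assert entry["similarity"] == pytest.approx(1.0, abs=1e-12)

    def test_similarity_is_one_minus_distance(self, rng):
        p = pdf_histogram(rng.standard_normal(2000))
        q = pdf_histogram(rng.standard_normal(2000) * 1.5, edges=p.edges)
        rep = similarity_suite(p, q)
        for name, entry in rep.measures.items():
            if name != "kld":
                assert entry["similarity"] == 1.0 - entry["distance"]

    def test_all_families_reported(self, rng):
        p = pdf_histogram(rng.standard_normal(2000))
        rep = similarity_suite(p, p)
        assert set(rep.families) == set(FAMILIES)

    def test_disjoint_supports(self):
        p = _pdf([1.0, 0.0, 0.0])
        q = _pdf([0.0, 0.0, 1.0])
        rep = similarity_suite(p, q)
        assert rep.measures["intersection"]["similarity"] == 0.0
        assert rep.measures["fidelity"]["similarity"] == 0.0

    def test_two_bin_euclidean_hand_example(self):
        p = _pdf([0.5, 0.5])
        q = _pdf([0.9, 0.1])
        rep = similarity_suite(p, q)
        d = np.sqrt(0.4**2 + 0.4**2)  # ~0.5657
        assert rep.measures["euclidean"]["distance"] == pytest.approx(
            d, abs=1e-12)
        assert rep.measures["euclidean"]["similarity"] == pytest.approx(
            1 - d, abs=1e-12)
        assert rep.measures["chebyshev"]["distance"] == pytest.approx(
            0.4, abs=1e-12)
        assert rep.measures["squared_euclidean"]["distance"] == pytest.approx(
            0.32, abs=1e-12)

    def test_mismatched_edges_raise(self, rng):
        p = pdf_histogram(rng.standard_normal(100))
        q = pdf_histogram(rng.standard_normal(100))
        if len(p.edges) == len(q.edges) and np.array_equal(p.edges, q.edges):
            pytest.skip("grids coincided by chance")
        with pytest.raises(ValueError, match="grid"):
            similarity_suite(p, q)


class TestKld:
    def test_self_divergence_zero(self, rng):
        p = pdf_histogram(rng.standard_normal(500))
        assert kld(p, p) == 0.0

    def test_closed_form_ln2(self):
        assert kld(_pdf([1.0, 0.0]), _pdf([0.5, 0.5])) == pytest.approx(
            np.log(2), abs=1e-12)

    def test_nonnegative_on_random_pairs(self, rng):
        edges = np.arange(9.0)
        for _ in range(2000):
            p = Pdf(edges, rng.dirichlet(np.ones(8)))
            q = Pdf(edges, rng.dirichlet(np.ones(8)))
            assert kld(p, q) >= 0.0

    def test_zero_p_bins_contribute_nothing(self):
        assert kld(_pdf([0.0, 1.0]), _pdf([0.5, 0.5])) == pytest.approx(
            np.log(2), abs=1e-12)


class TestPdfCorrelation:
    def test_identity_correlation_one(self, rng):
        p = pdf_histogram(rng.standard_normal(500))
        assert pdf_correlation(p, p) == pytest.approx(1.0)

    def test_reversed_pdf_negative_on_skewed_grid(self):
        p = _pdf([0.6, 0.3, 0.08, 0.02])
        q = _pdf(list(reversed([0.6, 0.3, 0.08, 0.02])))
        assert pdf_correlation(p, q) < 0.0

    def test_constant_vector_warns_and_returns_zero(self):
        p = _pdf([0.25, 0.25, 0.25, 0.25])
        q = _pdf([0.7, 0.1, 0.1, 0.1])
        with pytest.warns(UserWarning, match="[Cc]onstant"):
            assert pdf_correlation(p, q) == 0.0

    def test_invariant_under_affine_rescaling(self):
        # Pearson is scale/offset invariant; mimic by comparing with an
        # affinely related mass vector (renormalized off-grid comparison)
        p = _pdf([0.5, 0.3, 0.2])
        q = _pdf([0.4, 0.35, 0.25])
        r1 = pdf_correlation(p, q)
        affine = np.array([0.4, 0.35, 0.25]) * 2 + 0.1
        r2 = pdf_correlation(p, Pdf(p.edges, affine / affine.sum()))
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestMonotoneWithSnr:
    def test_similarity_rises_and_kld_falls_with_snr(self, utterance, babble):
        from cimask.mixing import mix_at_snr
        from cimask.vocoder import vocode

        ref = vocode(utterance)
        p = pdf_histogram(ref)
        sims, klds = [], []
        for snr in (-5.0, 5.0, 30.0):
            mixture, _ = mix_at_snr(utterance, babble, snr)
            q = pdf_histogram(vocode(mixture), edges=p.edges)
            rep = similarity_suite(p, q)
            sims.append(rep.families["fidelity"])
            klds.append(rep.families["shannons_entropy"])
        assert sims[0] < sims[-1]
        assert klds[0] > klds[-1]
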