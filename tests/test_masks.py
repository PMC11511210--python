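import numpy as np
import pytest

from cimask import masks as M
from cimask.tf_core import Spectrogram, StftParams, istft, stft
from conftest import random_spectrogram_pair


def _spec(values):
    """Tiny spectrogram from literal rows (rows duplicated to >= 2 bins)."""
    values = np.atleast_2d(np.asarray(values, dtype=complex))
    if values.shape[0] == 1:
        values = np.vstack([values, values])
    n_fft = (values.shape[0] - 1) * 2
    p = StftParams(frame_len=n_fft, fft_len=n_fft)
    return Spectrogram(values, p)


def _pair_from_mags(mag_s, mag_n):
    """Aligned clean/noise spectrograms with prescribed magnitudes."""
    S = np.zeros((3, len(mag_s)), dtype=complex)
    N = np.zeros((3, len(mag_n)), dtype=complex)
    S[:] = np.asarray(mag_s, dtype=float)
    N[:] = np.asarray(mag_n, dtype=float)
    p = StftParams(4, 2, 4)
    return Spectrogram(S, p), Spectrogram(N, p)


class TestLocalSnr:
    @pytest.mark.parametrize("ms,mn,expected", [
        (1.0, 1.0, 0.0),
        (np.sqrt(10.0), 1.0, 10.0),
        (1.0, 0.0, 100.0),
        (0.0, 1.0, -100.0),
        (0.0, 0.0, 0.0),
    ])
    def test_pointwise_values(self, ms, mn, expected):
        S, N = _pair_from_mags([ms], [mn])
        assert M.local_snr(S, N)[0, 0] == pytest.approx(expected, abs=1e-9)

    def test_shape_mismatch_raises(self, rng):
        S, _ = random_spectrogram_pair(rng, n_frames=5)
        N, _ = random_spectrogram_pair(rng, n_frames=6)
        with pytest.raises(ValueError, match="shape"):
            M.local_snr(S, N)


class TestIbm:
    def test_local_criterion_is_5db_below_mixture_snr(self):
        # mixture SNR 5 -> LC 0; local SNR 3 dB is speech-dominant
        S, N = _pair_from_mags([10 ** (3 / 20), 1.0], [1.0, 1.0])
        out = M.ibm(S, N, 5.0).values
        assert out[0, 0] == 1.0 and out[0, 1] == 0.0

    def test_tie_is_noise_dominant(self):
        # strict inequality: local SNR == LC gives 0
        S, N = _pair_from_mags([1.0], [1.0])
        assert M.ibm(S, N, 5.0).values[0, 0] == 0.0

    def test_zero_noise_gives_all_ones(self):
        S, N = _pair_from_mags([1.0, 2.0], [0.0, 0.0])
        assert np.all(M.ibm(S, N, 0.0).values == 1.0)


class TestIrm:
    def test_closed_form_three_four(self):
        S, N = _pair_from_mags([3.0], [4.0])
        assert M.irm(S, N).values[0, 0] == pytest.approx(9.0 / 25.0)

    def test_degenerate_bins(self):
        S, N = _pair_from_mags([1.0, 0.0, 0.0], [0.0, 1.0, 0.0])
        out = M.irm(S, N).values[0]
        np.testing.assert_allclose(out, [1.0, 0.0, 0.0])

    def test_equals_wiener_gain_of_local_snr(self, rng):
        S, Y = random_spectrogram_pair(rng)
        xi = 10.0 ** (M.local_snr(S, Y) / 10.0)
        np.testing.assert_allclose(
            M.irm(S, Y).values, xi / (1.0 + xi), atol=1e-10
        )


class TestFftm:
    def test_clipping_at_1p5(self):
        S, Y = _pair_from_mags([2.0], [1.0])
        assert M.fftm(S, Y).values[0, 0] == 1.5
        assert M.fftm(S, Y, clip=None).values[0, 0] == 2.0

    def test_identity_when_clean_equals_noisy(self, rng):
        S, _ = random_spectrogram_pair(rng)
        np.testing.assert_allclose(M.fftm(S, S).values, 1.0)


class TestPsm:
    def test_identity(self, rng):
        S, _ = random_spectrogram_pair(rng)
        np.testing.assert_allclose(M.psm(S, S).values, 1.0, atol=1e-12)

    def test_quadrature_phase_gives_zero(self):
        S = _spec([[5.0j, 5.0j, 5.0j]])
        Y = _spec([[2.0, 2.0, 2.0]])
        np.testing.assert_allclose(M.psm(S, Y).values, 0.0, atol=1e-12)

    def test_worked_example_matches_orm(self):
        # S = 1, N = j  =>  Y = 1 + j; both routes give 1/2
        S = _spec([[1.0 + 0.0j]])
        Y = _spec([[1.0 + 1.0j]])
        psm_val = M.psm(S, Y).values[0, 0]
        assert psm_val == pytest.approx(0.5, abs=1e-12)
        # optimal-ratio-mask closed form (|S|^2 + Re(S N*)) / (|S|^2+|N|^2+2Re(S N*))
        s, n = 1.0 + 0.0j, 1.0j
        orm = (abs(s) ** 2 + (s * np.conj(n)).real) / (
            abs(s) ** 2 + abs(n) ** 2 + 2 * (s * np.conj(n)).real
        )
        assert psm_val == pytest.approx(orm, abs=1e-12)

    def test_equals_orm_on_random_spectra(self, rng):
        S, Y = random_spectrogram_pair(rng)
        N = Y.copy_with(Y.values - S.values)
        s, n = S.values, N.values
        re_sn = (s * np.conj(n)).real
        orm = (np.abs(s) ** 2 + re_sn) / (
            np.abs(s) ** 2 + np.abs(n) ** 2 + 2 * re_sn
        )
        assert np.max(np.abs(M.psm(S, Y).values - orm)) < 1e-10


class TestCirm:
    def test_identity_mask(self, rng):
        S, _ = random_spectrogram_pair(rng)
        cm = M.cirm(S, S)
        np.testing.assert_allclose(cm.real_part, 1.0, atol=1e-12)
        np.testing.assert_allclose(cm.imag_part, 0.0, atol=1e-12)

    def test_real_part_equals_psm(self, rng):
        S, Y = random_spectrogram_pair(rng)
        assert np.max(np.abs(M.cirm(S, Y).real_part - M.psm(S, Y).values)) < 1e-10

    def test_perfect_recovery(self, rng):
        S, Y = random_spectrogram_pair(rng)
        rec = M.apply_complex_mask(M.cirm(S, Y), Y)
        np.testing.assert_allclose(rec.values, S.values, atol=1e-10)

    def test_resynthesis_is_real(self, spectrogram_triplet):
        S, N, Y = spectrogram_triplet
        rec = istft(M.apply_complex_mask(M.cirm(S, Y), Y))
        assert np.all(np.isreal(rec.samples))


class TestQm:
    def test_five_levels_at_mixture_snr_5(self):
        # LC1..LC4 = -3, -1, 1, 3 dB
        gammas = [-5.0, -2.0, 0.0, 2.0, 5.0]
        S, N = _pair_from_mags([10 ** (g / 20) for g in gammas], np.ones(5))
        np.testing.assert_allclose(
            M.qm(S, N, 5.0).values[0], [0.0, 0.25, 0.5, 0.75, 1.0]
        )

    def test_boundary_tie_goes_to_upper_level(self):
        # local SNR exactly at LC4 (mixture SNR 5 -> LC4 = 3 dB) gives 1
        assert M.quantize_local_snr(np.array([3.0]), 5.0)[0] == 1.0

    def test_staircase_tracks_wiener_gain(self):
        gam = np.linspace(-30, 30, 6001)
        S, N = _pair_from_mags(10 ** (gam / 20), np.ones_like(gam))
        q = M.qm(S, N, 5.0).values[0]
        xi = 10 ** (gam / 10)
        assert np.max(np.abs(q - xi / (1 + xi))) < 0.35
        assert np.all(np.diff(q) >= 0)  # monotone in local SNR


class TestPsmPlus:
    def test_three_branches(self):
        # negative PSM -> IRM fallback; mid-range passthrough; clip at 2
        S = _spec([[-0.3 + 0.0j, 1.2 + 0.0j, 2.5 + 0.0j]])
        Y = _spec([[1.0, 1.0, 1.0]])
        N = Y.copy_with(Y.values - S.values)
        out = M.psm_plus(S, Y, N).values[0]
        irm_val = M.irm(S, N).values[0, 0]
        assert out[0] == pytest.approx(irm_val)
        assert out[1] == pytest.approx(1.2)
        assert out[2] == 2.0

    def test_range(self, rng):
        S, Y = random_spectrogram_pair(rng)
        N = Y.copy_with(Y.values - S.values)
        out = M.psm_plus(S, Y, N).values
        assert out.min() >= 0.0 and out.max() <= 2.0


class TestRangeInvariants:
    def test_declared_ranges_hold_on_random_inputs(self, rng):
        S, Y = random_spectrogram_pair(rng, n_frames=200)
        N = Y.copy_with(Y.values - S.values)
        assert set(np.unique(M.ibm(S, N, 0.0).values)) <= {0.0, 1.0}
        assert set(np.unique(M.qm(S, N, 0.0).values)) <= {0.0, 0.25, 0.5, 0.75, 1.0}
        irm_v = M.irm(S, N).values
        assert irm_v.min() >= 0.0 and irm_v.max() <= 1.0
        fftm_v = M.fftm(S, Y, clip=1.5).values
        assert fftm_v.min() >= 0.0 and fftm_v.max() <= 1.5

    def test_ibm_monotone_in_local_snr(self):
        gam = np.linspace(-30, 30, 1001)
        S, N = _pair_from_mags(10 ** (gam / 20), np.ones_like(gam))
        out = M.ibm(S, N, 0.0).values[0]
        assert np.all(np.diff(out) >= 0)


class TestApplyMask:
    def test_all_ones_returns_noisy(self, spectrogram_triplet):
        _, _, Y = spectrogram_triplet
        ones = M.RealMask(np.ones(Y.values.shape), "irm", (0, 1))
        np.testing.assert_allclose(M.apply_mask(ones, Y).values, Y.values)

    def test_all_zeros_returns_silence(self, spectrogram_triplet):
        _, _, Y = spectrogram_triplet
        zeros = M.RealMask(np.zeros(Y.values.shape), "irm", (0, 1))
        assert np.all(M.apply_mask(zeros, Y).values == 0)

    def test_oracle_irm_improves_stoi(self, mixture_at_minus5,
                                      spectrogram_triplet):
        from cimask.metrics import stoi

        clean, mixture, _ = mixture_at_minus5
        S, N, Y = spectrogram_triplet
        enhanced = istft(M.apply_mask(M.irm(S, N), Y))
        assert stoi(clean, enhanced).value > stoi(clean, mixture).value

    def test_shape_mismatch_raises(self, spectrogram_triplet):
        _, _, Y = spectrogram_triplet
        bad = M.RealMask(np.ones((3, 3)), "irm", (0, 1))
        with pytest.raises(ValueError, match="shape"):
            M.apply_mask(bad, Y)


class TestMaskHistogram:
    def test_binary_level_fractions_sum_to_one(self, spectrogram_triplet):
        S, N, Y = spectrogram_triplet
        h = M.mask_histogram(M.ibm(S, N, -5.0).values, levels=[0.0, 1.0])
        assert h["fractions"].sum() == pytest.approx(1.0)

    def test_quantized_five_levels(self, spectrogram_triplet):
        S, N, Y = spectrogram_triplet
        h = M.mask_histogram(M.qm(S, N, -5.0).values,
                             levels=[0, 0.25, 0.5, 0.75, 1.0])
        assert len(h["fractions"]) == 5
        assert h["fractions"].sum() == pytest.approx(1.0)

    def test_binned_fractions_of_soft_mask(self, spectrogram_triplet):
        S, N, Y = spectrogram_triplet
        vals = M.fftm(S, Y, clip=None).values
        h = M.mask_histogram(vals, nbins=30)
        in_range = np.mean((vals >= 0) & (vals <= 1.5))
        assert 0.0 < in_range <= 1.0  # reported fraction is corpus-dependent

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="[Ee]mpty"):
            M.mask_histogram(np.zeros((0,)))
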