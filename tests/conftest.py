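import numpy as np
import pytest

from cimask.mixing import mix_at_snr
from cimask.synthetic import SynthSpec, synth_noise, synth_utterance
from cimask.tf_core import StftParams, Waveform, stft


@pytest.fixture(scope="session")
def utterance() -> Waveform:
    return synth_utterance(SynthSpec(duration=1.5, seed=11))


@pytest.fixture(scope="session")
def babble() -> Waveform:
    return synth_noise("babble_like", 6.0, seed=12)


@pytest.fixture(scope="session")
def mixture_at_minus5(utterance, babble):
    """(clean, mixture, scaled_noise) at -5 dB SNR."""
    mixture, scaled = mix_at_snr(utterance, babble, -5.0)
    return utterance, mixture, scaled


@pytest.fixture(scope="session")
def spectrogram_triplet(mixture_at_minus5):
    """Aligned (S, N, Y) spectrograms of a -5 dB mixture (20 ms frames)."""
    clean, mixture, scaled = mixture_at_minus5
    p = StftParams(frame_len=320, fft_len=320)
    return stft(clean, p), stft(scaled, p), stft(mixture, p)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_spectrogram_pair(rng, n_bins=33, n_frames=20):
    """Two independent complex spectrograms on a common tiny grid."""
    p = StftParams(frame_len=(n_bins - 1) * 2, fft_len=(n_bins - 1) * 2)
    from cimask.tf_core import Spectrogram

    def draw():
        v = rng.standard_normal((n_bins, n_frames)) \
            + 1j * rng.standard_normal((n_bins, n_frames))
        return Spectrogram(v, p)

    return draw(), draw()
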