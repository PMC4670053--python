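import numpy as np
import pytest

from songscan.audio_io import AudioClip, Spectrogram, compute_spectrogram
from songscan.classifier import SVMConfig, tune_hyperparameters
from songscan.detector import DetectorConfig
from songscan.synthetic import default_corpus_specs, make_training_corpus

# small reduced grid so tuning stays fast in tests
FAST_GRID = tuple(range(-3, 4))

# detector threshold used for the reference corpora (high enough to reject
# background, low enough to survive the cricket-raised noise floor)
CORPUS_DETECTOR = DetectorConfig(snr_threshold=6.0)


def tone_clip(freq=3000.0, duration=1.0, sample_rate=8000.0, amplitude=0.5, source_id="tone"):
    t = np.arange(int(duration * sample_rate)) / sample_rate
    return AudioClip(
        samples=amplitude * np.sin(2 * np.pi * freq * t),
        sample_rate=sample_rate,
        source_id=source_id,
    )


def flat_spectrogram(value=1.0, n_bins=33, n_frames=40, sample_rate=8000.0, window=64, hop=32):
    freq_axis = np.fft.rfftfreq(window, d=1.0 / sample_rate)
    assert len(freq_axis) == n_bins
    time_axis = (np.arange(n_frames) * hop + window / 2) / sample_rate
    return Spectrogram(
        magnitude=np.full((n_bins, n_frames), value),
        freq_axis=freq_axis,
        time_axis=time_axis,
        window_length=window,
        hop=hop,
        sample_rate=sample_rate,
        source_id="flat",
    )


@pytest.fixture(scope="session")
def easy_corpus():
    """Feature table, class labels and truth for the clean reference corpus."""
    specs = default_corpus_specs(n_soundscapes=10, cricket=False, seed=100)
    return make_training_corpus(specs, detector_cfg=CORPUS_DETECTOR)


@pytest.fixture(scope="session")
def easy_model_cfg(easy_corpus):
    features, classes, _ = easy_corpus
    binary = (classes > 0).astype(int)
    cfg = SVMConfig(grid_exponents=FAST_GRID)
    return tune_hyperparameters(features, binary, cfg, seed=1)


@pytest.fixture(scope="session")
def gauss_blobs():
    """Two well-separated 2-D Gaussian blobs (n=100 per class)."""
    rng = np.random.default_rng(42)
    x0 = rng.normal([-4.0, 0.0], 1.0, size=(100, 2))
    x1 = rng.normal([4.0, 0.0], 1.0, size=(100, 2))
    x = np.vstack([x0, x1])
    y = np.repeat([0, 1], 100)
    return x, y
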