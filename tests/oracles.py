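"""Independent brute-force oracles shared by unit and acceptance tests.

These deliberately use plain loops and direct definitions rather than the
package's vectorized code paths.
"""

import numpy as np

from songscan.audio_io import Spectrogram
from songscan.detector import DetectorConfig

SMALL_CFG = DetectorConfig(
    min_freq=500.0,
    max_freq=3000.0,
    min_duration=0.01,
    max_duration=1.0,
    snr_threshold=6.0,
    noise_percentile=0.5,
    noise_block=0.1,
    min_separation=0.02,
    min_occupancy=0.5,
)


def oracle_detect(spec, cfg):
    """Frame-by-frame thresholding + run merging, straight from the definition."""
    hop_s = spec.hop / spec.sample_rate
    in_band = [i for i, f in enumerate(spec.freq_axis) if cfg.min_freq <= f <= cfg.max_freq]
    n_frames = spec.magnitude.shape[1]
    block = max(1, int(round(cfg.noise_block / hop_s)))
    noise = {}
    for b in in_band:
        noise[b] = []
        for start in range(0, n_frames, block):
            stop = min(start + block, n_frames)
            level = float(np.quantile(spec.magnitude[b, start:stop], cfg.noise_percentile))
            noise[b].extend([level] * (stop - start))
    factor = 10 ** (cfg.snr_threshold / 20)
    marked = []
    for t in range(n_frames):
        sig = np.sqrt(sum(spec.magnitude[b, t] ** 2 for b in in_band))
        noi = np.sqrt(sum(noise[b][t] ** 2 for b in in_band))
        marked.append(sig > noi * factor)
    max_gap = max(1, int(np.ceil(cfg.min_separation / hop_s)))
    runs = []
    for t in range(n_frames):
        if not marked[t]:
            continue
        if runs and t - runs[-1][1] - 1 < max_gap:
            runs[-1][1] = t
        else:
            runs.append([t, t])
    out = []
    for start, end in runs:
        begin = start * hop_s
        stop = (end + 1) * hop_s
        if not cfg.min_duration <= stop - begin <= cfg.max_duration:
            continue
        occ = sum(marked[start : end + 1]) / (end - start + 1)
        if occ < cfg.min_occupancy:
            continue
        out.append((begin, stop))
    return out


def random_small_spectrogram(rng, n_bins=40, n_frames=50):
    sr = 8000.0
    window = (n_bins - 1) * 2
    hop = window // 2
    mag = rng.exponential(1.0, size=(n_bins, n_frames))
    for _ in range(rng.integers(0, 4)):
        b0 = rng.integers(0, n_bins - 5)
        t0 = rng.integers(0, n_frames - 8)
        mag[b0 : b0 + 5, t0 : t0 + rng.integers(2, 8)] += rng.uniform(5, 40)
    freq_axis = np.fft.rfftfreq(window, d=1.0 / sr)
    time_axis = (np.arange(n_frames) * hop + window / 2) / sr
    return Spectrogram(
        magnitude=mag,
        freq_axis=freq_axis,
        time_axis=time_axis,
        window_length=window,
        hop=hop,
        sample_rate=sr,
        source_id="rand",
    )


def auc_brute_force(scores, truth):
    """All-pairs concordance count; ties contribute one half."""
    scores = list(scores)
    truth = list(truth)
    pos = [s for s, t in zip(scores, truth) if t == 1]
    neg = [s for s, t in zip(scores, truth) if t == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
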