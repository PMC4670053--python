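"""Band-limited energy detector.

Flags spectrogram frames whose in-band level exceeds a per-bin background
noise estimate by an SNR threshold, merges runs of flagged frames into
candidate selections and filters them by duration and occupancy.

Noise is estimated per frequency bin as a percentile of that bin's
magnitudes over non-overlapping blocks of ``noise_block`` seconds, which is
robust to sparse song energy. The in-band level of a frame is the
root-sum-square of the band bins' magnitudes, and SNR is compared on
amplitude: a frame is flagged when

    band_level > noise_level * 10**(snr_threshold / 20)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotations import Selection
from .audio_io import AudioClip, Spectrogram, compute_spectrogram

__all__ = [
    "DetectorConfig",
    "NoiseProfile",
    "estimate_noise_profile",
    "detect_candidates",
    "tune_detector",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Parameters of the band-limited energy detector.

    Defaults encode the target species' song envelope: 1000-6100 Hz band and
    0.5-5 s duration. Remaining parameters (threshold, noise block, merge
    gap, occupancy) govern the noise model and run merging and are meant to
    be tuned per dataset.
    """

    min_freq: float = 1000.0
    max_freq: float = 6100.0
    min_duration: float = 0.5
    max_duration: float = 5.0
    snr_threshold: float = 10.0
    noise_percentile: float = 0.5
    noise_block: float = 10.0
    min_separation: float = 0.1
    min_occupancy: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.min_freq < self.max_freq:
            raise ValueError(
                f"need 0 < min_freq < max_freq, got ({self.min_freq}, {self.max_freq})"
            )
        if not 0 < self.min_duration < self.max_duration:
            raise ValueError(
                "need 0 < min_duration < max_duration, got "
                f"({self.min_duration}, {self.max_duration})"
            )
        if not 0 < self.noise_percentile < 1:
            raise ValueError(f"noise_percentile must be in (0,1), got {self.noise_percentile}")
        if self.snr_threshold <= 0:
            raise ValueError(f"snr_threshold must be > 0, got {self.snr_threshold}")
        if self.noise_block <= 0:
            raise ValueError(f"noise_block must be > 0, got {self.noise_block}")
        if self.min_separation < 0 or not 0 <= self.min_occupancy <= 1:
            raise ValueError("min_separation must be >= 0 and min_occupancy in [0,1]")


@dataclass
class NoiseProfile:
    """Per-bin background noise levels inside the analysis band.

    ``noise_level`` has shape (n_band_bins, n_frames): each bin's blockwise
    percentile estimate, broadcast over the frames of its block.
    """

    noise_level: np.ndarray
    band_indices: np.ndarray
    percentile: float
    block_frames: int = field(default=0)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.noise_level)) or np.any(self.noise_level < 0):
            raise ValueError("noise levels must be finite and non-negative")


def band_indices(spec: Spectrogram, cfg: DetectorConfig) -> np.ndarray:
    """Indices of frequency bins inside [min_freq, max_freq]."""
    if cfg.min_freq < spec.freq_axis[0] or cfg.max_freq > spec.freq_axis[-1]:
        raise ValueError(
            f"band [{cfg.min_freq}, {cfg.max_freq}] Hz outside spectrogram range "
            f"[{spec.freq_axis[0]}, {spec.freq_axis[-1]}] Hz"
        )
    idx = np.flatnonzero((spec.freq_axis >= cfg.min_freq) & (spec.freq_axis <= cfg.max_freq))
    if idx.size == 0:
        raise ValueError("analysis band contains no frequency bins")
    return idx


def estimate_noise_profile(spec: Spectrogram, cfg: DetectorConfig) -> NoiseProfile:
    """Blockwise per-bin percentile noise estimate over the analysis band."""
    idx = band_indices(spec, cfg)
    band = spec.magnitude[idx]
    n_frames = band.shape[1]
    block_frames = max(1, int(round(cfg.noise_block / spec.hop_seconds)))
    levels = np.empty_like(band)
    for start in range(0, n_frames, block_frames):
        stop = min(start + block_frames, n_frames)
        block_level = np.quantile(band[:, start:stop], cfg.noise_percentile, axis=1)
        levels[:, start:stop] = block_level[:, None]
    return NoiseProfile(
        noise_level=levels,
        band_indices=idx,
        percentile=cfg.noise_percentile,
        block_frames=block_frames,
    )


def flag_frames(spec: Spectrogram, cfg: DetectorConfig, noise: NoiseProfile | None = None):
    """Boolean mask of frames whose in-band level exceeds the SNR threshold."""
    if noise is None:
        noise = estimate_noise_profile(spec, cfg)
    band = spec.magnitude[noise.band_indices]
    factor = 10.0 ** (cfg.snr_threshold / 20.0)
    band_level = np.sqrt((band**2).sum(axis=0))
    noise_level = np.sqrt((noise.noise_level**2).sum(axis=0))
    return band_level > noise_level * factor, noise


def _merge_runs(marked: np.ndarray, max_gap_frames: int) -> list[tuple[int, int]]:
    """Maximal runs of True frames, joining runs separated by < max_gap_frames."""
    idx = np.flatnonzero(marked)
    if idx.size == 0:
        return []
    runs: list[list[int]] = [[int(idx[0]), int(idx[0])]]
    for i in idx[1:]:
        if i - runs[-1][1] - 1 < max_gap_frames:
            runs[-1][1] = int(i)
        else:
            runs.append([int(i), int(i)])
    return [(a, b) for a, b in runs]


def detect_candidates(spec: Spectrogram, cfg: DetectorConfig) -> list[Selection]:
    """Run the band-limited energy detector on a spectrogram.

    Returns selections ordered by begin time; frame extents are converted to
    seconds as ``[first_frame*hop, (last_frame+1)*hop) / sample_rate`` so
    that distinct runs never overlap in time.
    """
    marked, noise = flag_frames(spec, cfg)
    hop_s = spec.hop_seconds
    max_gap = max(1, int(np.ceil(cfg.min_separation / hop_s)))
    factor = 10.0 ** (cfg.snr_threshold / 20.0)
    band = spec.magnitude[noise.band_indices]
    band_freqs = spec.freq_axis[noise.band_indices]
    bin_width = spec.sample_rate / spec.window_length

    selections: list[Selection] = []
    for first, last in _merge_runs(marked, max_gap):
        begin = first * hop_s
        end = (last + 1) * hop_s
        duration = end - begin
        if not cfg.min_duration <= duration <= cfg.max_duration:
            continue
        occupancy = marked[first : last + 1].mean()
        if occupancy < cfg.min_occupancy:
            continue
        cells = band[:, first : last + 1] > noise.noise_level[:, first : last + 1] * factor
        occupied = np.flatnonzero(cells.any(axis=1))
        if occupied.size:
            low = float(band_freqs[occupied[0]])
            high = float(band_freqs[occupied[-1]])
            if high <= low:
                high = low + bin_width
        else:
            low, high = cfg.min_freq, cfg.max_freq
        selections.append(
            Selection(
                selection_id=len(selections) + 1,
                source_id=spec.source_id,
                begin_time=begin,
                end_time=end,
                low_freq=low,
                high_freq=high,
            )
        )
    return selections


def tune_detector(
    labeled_clips: list[tuple[AudioClip, list[Selection]]],
    grid: list[DetectorConfig],
    window_length: int = 512,
    hop: int = 256,
    window_name: str = "hann",
    overlap_threshold: float = 0.5,
) -> DetectorConfig:
    """Pick the grid config maximizing recall of the truth selections.

    Ties are broken by fewer false detections, then by grid order. Recall is
    pooled over all clips; a detection matches a truth selection when their
    temporal intersection covers >= ``overlap_threshold`` of the truth
    duration (one-to-one greedy matching).
    """
    from .evaluation import match_detections

    if not labeled_clips:
        raise ValueError("need at least one labeled clip")
    if not grid:
        raise ValueError("detector grid must not be empty")
    specs = [
        compute_spectrogram(clip, window_length, hop, window_name)
        for clip, _ in labeled_clips
    ]
    best_key = None
    best_cfg = None
    for order, cfg in enumerate(grid):
        matched = total_truth = false_pos = 0
        for spec, (_, truth) in zip(specs, labeled_clips):
            detected = detect_candidates(spec, cfg)
            score = match_detections(detected, truth, overlap_threshold)
            matched += score.n_matched
            total_truth += score.n_truth
            false_pos += score.n_detected - score.n_matched
        recall = matched / total_truth if total_truth else 0.0
        key = (-recall, false_pos, order)
        if best_key is None or key < best_key:
            best_key, best_cfg = key, cfg
    return best_cfg
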