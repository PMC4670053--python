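"""Synthetic soundscapes with known ground truth.

Every stage of the pipeline is testable without field recordings: the
generator places amplitude-modulated frequency sweeps ("songs", 0.5-5 s,
inside the 1000-6100 Hz analysis band) over broadband noise, optionally
adds out-of-band or in-band distractor sweeps and a constant narrowband
"cricket" noise overlapping the song band, and returns a ground-truth
selection table alongside the audio. Song SNR is calibrated against the
in-band RMS of the broadband noise floor.

Degradation classes mirror the annotation semantics: class 3 = clean song,
class 2 = partial overlap with another sound, class 1 = heavy overlap.
Class counts follow largest-remainder rounding of the requested mix.
Everything is driven by one integer seed; identical seeds give bit-identical
audio and truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, chirp, sosfilt
from scipy.signal.windows import tukey

from .annotations import AnnotatedSelection, Selection
from .audio_io import AudioClip

__all__ = [
    "SongTemplate",
    "Distractor",
    "SoundscapeSpec",
    "synth_song",
    "synth_soundscape",
    "make_training_corpus",
    "default_corpus_specs",
    "largest_remainder_counts",
]

SONG_BAND = (1000.0, 6100.0)
SONG_DURATION_RANGE = (0.5, 5.0)
_BAND_MARGIN = 100.0  # Hz of spillover allowed around the declared sweep band


@dataclass(frozen=True)
class SongTemplate:
    """A target song: a trilled frequency sweep inside the species band."""

    duration: float = 2.0
    freq_start: float = 2200.0
    freq_end: float = 4800.0
    trill_rate: float = 12.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = SONG_DURATION_RANGE
        if not lo <= self.duration <= hi:
            raise ValueError(f"song duration must be in [{lo}, {hi}] s, got {self.duration}")
        for f in (self.freq_start, self.freq_end):
            if not SONG_BAND[0] <= f <= SONG_BAND[1]:
                raise ValueError(f"song frequencies must lie in {SONG_BAND}, got {f}")
        if self.trill_rate < 0 or self.amplitude <= 0:
            raise ValueError("trill_rate must be >= 0 and amplitude > 0")

    @property
    def low_freq(self) -> float:
        return min(self.freq_start, self.freq_end) - _BAND_MARGIN

    @property
    def high_freq(self) -> float:
        return max(self.freq_start, self.freq_end) + _BAND_MARGIN


@dataclass(frozen=True)
class Distractor:
    """A non-target sweep; may sit anywhere in frequency (e.g. out of band)."""

    duration: float = 1.5
    freq_start: float = 7000.0
    freq_end: float = 8500.0
    trill_rate: float = 0.0
    amplitude: float = 0.2

    def __post_init__(self) -> None:
        if self.duration <= 0 or min(self.freq_start, self.freq_end) <= 0:
            raise ValueError("distractor duration and frequencies must be positive")


@dataclass(frozen=True)
class SoundscapeSpec:
    """Recipe for one synthetic soundscape."""

    duration: float = 30.0
    sample_rate: float = 44100.0
    n_target_songs: int = 10
    target_snr_db: float = 20.0
    distractors: tuple[tuple[Distractor, int], ...] = ()
    cricket_band: tuple[float, float, float] | None = None  # (center Hz, bandwidth Hz, level)
    noise_level: float = 0.01
    degradation_class_mix: tuple[float, float, float] = (0.0, 0.0, 1.0)  # classes 1, 2, 3
    seed: int = 0
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.sample_rate <= 0:
            raise ValueError("duration and sample_rate must be positive")
        if self.n_target_songs < 0 or self.noise_level < 0:
            raise ValueError("n_target_songs and noise_level must be >= 0")
        if abs(sum(self.degradation_class_mix) - 1.0) > 1e-9:
            raise ValueError(
                f"degradation_class_mix must sum to 1, got {self.degradation_class_mix}"
            )

    @property
    def resolved_source_id(self) -> str:
        return self.source_id or f"soundscape_{self.seed}"


def largest_remainder_counts(n: int, fractions: tuple[float, ...]) -> tuple[int, ...]:
    """Integer counts summing to ``n`` with largest-remainder rounding."""
    quotas = np.asarray(fractions, dtype=float) * n
    counts = np.floor(quotas).astype(int)
    remainder = n - counts.sum()
    # ties broken toward earlier entries (stable argsort on negated remainders)
    order = np.argsort(-(quotas - counts), kind="stable")
    for i in order[:remainder]:
        counts[i] += 1
    return tuple(int(c) for c in counts)


def _sweep(
    duration: float,
    freq_start: float,
    freq_end: float,
    trill_rate: float,
    amplitude: float,
    sample_rate: float,
) -> np.ndarray:
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    carrier = chirp(t, f0=freq_start, f1=freq_end, t1=duration, method="linear")
    envelope = tukey(n, alpha=0.2)
    if trill_rate > 0:
        envelope = envelope * (1.0 + 0.6 * np.sin(2 * np.pi * trill_rate * t)) / 1.6
    return amplitude * envelope * carrier


def synth_song(template: SongTemplate, sample_rate: float = 44100.0) -> AudioClip:
    """Render one target song as an audio clip."""
    samples = _sweep(
        template.duration,
        template.freq_start,
        template.freq_end,
        template.trill_rate,
        template.amplitude,
        sample_rate,
    )
    return AudioClip(samples=samples, sample_rate=sample_rate, source_id="song")


def _random_song_template(rng: np.random.Generator) -> SongTemplate:
    f_lo = rng.uniform(1500.0, 2800.0)
    f_hi = rng.uniform(3600.0, 5800.0)
    return SongTemplate(
        duration=float(rng.uniform(0.8, 3.0)),
        freq_start=float(f_lo),
        freq_end=float(f_hi),
        trill_rate=float(rng.uniform(8.0, 20.0)),
    )


def _place_all(
    rng: np.random.Generator,
    duration: float,
    event_durations: list[float],
    margin: float = 0.2,
) -> list[float]:
    """Non-overlapping begin times for all events (random gap spacing).

    The free time left after stacking the events end to end (with a margin
    between neighbours) is split into random gaps, so placement always
    succeeds when the events fit at all.
    """
    k = len(event_durations)
    if k == 0:
        return []
    free = duration - sum(event_durations) - margin * (k - 1)
    if free < 0:
        raise ValueError(
            f"events ({sum(event_durations):.1f} s + margins) do not fit in "
            f"{duration:.1f} s; reduce counts or durations"
        )
    gaps = rng.dirichlet(np.ones(k + 1)) * free
    begins = []
    cursor = 0.0
    for i, d in enumerate(event_durations):
        cursor += gaps[i] + (margin if i else 0.0)
        begins.append(cursor)
        cursor += d
    return begins


def _band_noise_rms(noise_level: float, sample_rate: float) -> float:
    """In-band RMS of white noise with sd ``noise_level``."""
    nyq = sample_rate / 2.0
    lo, hi = SONG_BAND[0], min(SONG_BAND[1], nyq)
    return noise_level * np.sqrt((hi - lo) / nyq)


def synth_soundscape(spec: SoundscapeSpec) -> tuple[AudioClip, list[AnnotatedSelection]]:
    """Render a soundscape and its ground-truth annotated selections."""
    rng = np.random.default_rng(spec.seed)
    sr = spec.sample_rate
    n = int(round(spec.duration * sr))
    samples = rng.normal(0.0, spec.noise_level, size=n) if spec.noise_level > 0 else np.zeros(n)

    if spec.cricket_band is not None:
        center, bandwidth, level = spec.cricket_band
        nyq = sr / 2.0
        lo = max(center - bandwidth / 2.0, 1.0) / nyq
        hi = min(center + bandwidth / 2.0, nyq - 1.0) / nyq
        sos = butter(4, [lo, hi], btype="bandpass", output="sos")
        cricket = sosfilt(sos, rng.normal(0.0, 1.0, size=n))
        rms = np.sqrt(np.mean(cricket**2))
        if rms > 0:
            samples += cricket * (level / rms)

    sigma_band = _band_noise_rms(spec.noise_level, sr)
    snr_gain = 10.0 ** (spec.target_snr_db / 20.0)

    class_counts = largest_remainder_counts(spec.n_target_songs, spec.degradation_class_mix)
    classes = [1] * class_counts[0] + [2] * class_counts[1] + [3] * class_counts[2]
    classes = [classes[i] for i in rng.permutation(len(classes))]

    pending: list[tuple] = [("song", _random_song_template(rng), cls) for cls in classes]
    for distractor, count in spec.distractors:
        pending.extend(("distractor", distractor, None) for _ in range(count))
    pending = [pending[i] for i in rng.permutation(len(pending))]
    begins = _place_all(rng, spec.duration, [item[1].duration for item in pending])

    events = []  # song events: (begin, template, class)
    for begin, (kind, template, cls) in zip(begins, pending):
        if kind == "song":
            events.append((begin, template, cls))
            continue
        wave = _sweep(
            template.duration,
            template.freq_start,
            template.freq_end,
            template.trill_rate,
            1.0,
            sr,
        )
        wave_rms = np.sqrt(np.mean(wave**2))
        gain = (
            template.amplitude * snr_gain * sigma_band / wave_rms
            if sigma_band > 0
            else template.amplitude
        )
        i0 = int(round(begin * sr))
        samples[i0 : i0 + len(wave)] += gain * wave

    truth: list[AnnotatedSelection] = []
    for begin, template, cls in sorted(events, key=lambda e: e[0]):
        wave = _sweep(
            template.duration, template.freq_start, template.freq_end, template.trill_rate, 1.0, sr
        )
        wave_rms = np.sqrt(np.mean(wave**2))
        nominal = snr_gain * sigma_band / wave_rms if sigma_band > 0 else template.amplitude
        # degradation: lower-quality classes are fainter and increasingly
        # buried under a non-trilled overlapping sweep, so the detected box
        # reflects the interfering sound more than the song
        song_gain = {1: 0.25, 2: 0.7, 3: 1.0}[cls] * nominal
        i0 = int(round(begin * sr))
        samples[i0 : i0 + len(wave)] += song_gain * wave

        if cls in (1, 2):
            heavy = cls == 1
            cover = 0.95 if heavy else 0.3
            o_dur = max(0.05, cover * template.duration)
            o_begin = begin + (0.025 if heavy else 0.6) * template.duration
            o_f0 = float(rng.uniform(1200.0, 5500.0))
            o_f1 = float(np.clip(o_f0 + rng.uniform(-800.0, 800.0), 1100.0, 6000.0))
            overlay = _sweep(o_dur, o_f0, o_f1, 0.0, 1.0, sr)
            o_rms = np.sqrt(np.mean(overlay**2))
            o_level = rng.uniform(0.9, 1.8) if heavy else rng.uniform(0.5, 0.9)
            o_gain = o_level * nominal * wave_rms / o_rms
            j0 = int(round(o_begin * sr))
            j1 = min(j0 + len(overlay), n)
            samples[j0:j1] += o_gain * overlay[: j1 - j0]

        truth.append(
            AnnotatedSelection(
                selection=Selection(
                    selection_id=len(truth) + 1,
                    source_id=spec.resolved_source_id,
                    begin_time=begin,
                    end_time=begin + template.duration,
                    low_freq=max(template.low_freq, 0.0),
                    high_freq=min(template.high_freq, sr / 2.0),
                ),
                class_label=cls,
            )
        )

    peak = np.abs(samples).max()
    if peak > 0.95:
        samples *= 0.95 / peak
    clip = AudioClip(samples=samples, sample_rate=sr, source_id=spec.resolved_source_id)
    return clip, truth


DEFAULT_CLASS_MIX = (0.50, 0.34, 0.16)
CRICKET_BAND_DEFAULT = (3500.0, 500.0, 0.04)


def default_corpus_specs(
    n_soundscapes: int = 30,
    cricket: bool = False,
    seed: int = 100,
    duration: float = 75.0,
    sample_rate: float = 22050.0,
    n_target_songs: int = 12,
    target_snr_db: float = 20.0,
    class_mix: tuple[float, float, float] = DEFAULT_CLASS_MIX,
) -> list[SoundscapeSpec]:
    """Reference corpus recipe used by the tests and example workflows.

    Each soundscape carries trilled target songs plus eight non-trilled
    in-band sweep distractors of varying bandwidth, duration and amplitude —
    non-target sounds a detector will pick up but a classifier should
    reject. ``cricket=True`` adds the constant narrowband confound
    overlapping the song band.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_soundscapes):
        distractors = []
        for _ in range(8):
            center = rng.uniform(2000.0, 5000.0)
            bandwidth = rng.uniform(400.0, 2200.0)
            distractors.append(
                (
                    Distractor(
                        duration=float(rng.uniform(0.6, 2.4)),
                        freq_start=float(max(1100.0, center - bandwidth / 2)),
                        freq_end=float(min(6000.0, center + bandwidth / 2)),
                        trill_rate=0.0,
                        amplitude=float(rng.uniform(0.5, 1.6)),
                    ),
                    1,
                )
            )
        specs.append(
            SoundscapeSpec(
                duration=duration,
                sample_rate=sample_rate,
                n_target_songs=n_target_songs,
                target_snr_db=target_snr_db,
                distractors=tuple(distractors),
                cricket_band=CRICKET_BAND_DEFAULT if cricket else None,
                noise_level=0.01,
                degradation_class_mix=class_mix,
                seed=seed + 1 + i,
            )
        )
    return specs


def make_training_corpus(
    specs: list[SoundscapeSpec],
    detector_cfg=None,
    window_length: int = 512,
    hop: int = 256,
    window_name: str = "hann",
    overlap_threshold: float = 0.5,
):
    """Detect, measure and auto-label candidates across soundscapes.

    Candidates whose temporal overlap covers >= ``overlap_threshold`` of a
    truth song inherit that song's class; all others get class 0. Returns
    ``(feature_table, class_labels, truth)`` where ``feature_table`` has key
    columns plus the full feature schema, ``class_labels`` is an int array
    aligned with the table rows, and ``truth`` maps source_id to its
    ground-truth annotated selections.
    """
    import pandas as pd

    from .audio_io import compute_spectrogram
    from .detector import DetectorConfig, detect_candidates
    from .measurements import measure_all

    detector_cfg = detector_cfg or DetectorConfig()
    frames = []
    labels = []
    truth_map: dict[str, list[AnnotatedSelection]] = {}
    for spec in specs:
        clip, truth = synth_soundscape(spec)
        truth_map[spec.resolved_source_id] = truth
        gram = compute_spectrogram(clip, window_length, hop, window_name)
        candidates = detect_candidates(gram, detector_cfg)
        table = measure_all(gram, candidates)
        kept_ids = set(table["selection_id"])
        for cand in candidates:
            if cand.selection_id not in kept_ids:
                continue
            cls = 0
            best = overlap_threshold
            for t in truth:
                frac = t.selection.overlap_seconds(cand) / t.selection.duration
                if frac >= best:
                    cls, best = t.class_label, frac
            labels.append(cls)
        frames.append(table)
    features = pd.concat(frames, ignore_index=True) if frames else None
    if features is None:
        raise ValueError("corpus is empty")
    return features, np.asarray(labels, dtype=int), truth_map
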