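"""JSON run configuration with package defaults.

Precedence: command-line flag > config file > built-in default. The
built-in defaults encode the published workflow: 1000-6100 Hz / 0.5-5 s
detector band, 70/30 holdout repeated 1000 times, learning-curve fractions
0.9 ... 0.1, and a decade hyperparameter grid over 10^-10 ... 10^10.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

from .classifier import SVMConfig
from .detector import DetectorConfig
from .evaluation import DEFAULT_FRACTIONS
from .synthetic import Distractor, SoundscapeSpec

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Resolved configuration for a pipeline run."""

    detector: DetectorConfig = field(default_factory=DetectorConfig)
    svm: SVMConfig = field(default_factory=SVMConfig)
    window_length: int = 512
    hop: int = 256
    window_name: str = "hann"
    train_fraction: float = 0.7
    n_reps: int = 1000
    learning_curve_reps: int = 100
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS
    seed: int = 0
    soundscape: SoundscapeSpec = field(default_factory=SoundscapeSpec)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build(cls, overrides: dict, **extra):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(overrides) - fields
    if unknown:
        raise ValueError(f"unknown {cls.__name__} option(s): {sorted(unknown)}")
    return cls(**{**overrides, **extra})


def _soundscape_from(overrides: dict) -> SoundscapeSpec:
    overrides = dict(overrides)
    if "distractors" in overrides:
        overrides["distractors"] = tuple(
            (_build(Distractor, dict(d)), int(count)) for d, count in overrides["distractors"]
        )
    if "cricket_band" in overrides and overrides["cricket_band"] is not None:
        overrides["cricket_band"] = tuple(overrides["cricket_band"])
    if "degradation_class_mix" in overrides:
        overrides["degradation_class_mix"] = tuple(overrides["degradation_class_mix"])
    return _build(SoundscapeSpec, overrides)


def load_config(path: str | None = None, seed: int | None = None) -> RunConfig:
    """Load a JSON config file (or defaults) into a :class:`RunConfig`."""
    raw: dict = {}
    if path is not None:
        with open(path, encoding="utf-8") as handle:
            raw = json.load(handle)
    spectrogram = raw.get("spectrogram", {})
    evaluation = raw.get("evaluation", {})
    svm_raw = dict(raw.get("svm", {}))
    if "grid_exponents" in svm_raw:
        svm_raw["grid_exponents"] = tuple(int(k) for k in svm_raw["grid_exponents"])
    cfg = RunConfig(
        detector=_build(DetectorConfig, raw.get("detector", {})),
        svm=_build(SVMConfig, svm_raw),
        window_length=int(spectrogram.get("window_length", 512)),
        hop=int(spectrogram.get("hop", 256)),
        window_name=str(spectrogram.get("window_name", "hann")),
        train_fraction=float(evaluation.get("train_fraction", 0.7)),
        n_reps=int(evaluation.get("n_reps", 1000)),
        learning_curve_reps=int(evaluation.get("learning_curve_reps", 100)),
        fractions=tuple(evaluation.get("fractions", DEFAULT_FRACTIONS)),
        seed=int(evaluation.get("seed", 0)),
        soundscape=_soundscape_from(raw.get("soundscape", {})),
    )
    if seed is not None:
        cfg.seed = seed
        cfg.soundscape = dataclasses.replace(cfg.soundscape, seed=seed)
    return cfg
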