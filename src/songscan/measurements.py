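"""Per-selection acoustic feature measurement.

Features are computed on the magnitude submatrix clipped to the selection's
time x frequency box. Distributions (entropy, percentiles) use squared
magnitude (energy) normalized to sum to one; dB powers are referenced to the
whole spectrogram's maximum magnitude, so every feature except ``energy`` is
invariant to uniform amplitude scaling of the clip.

The feature schema is the 16-column list in :data:`FEATURE_NAMES`; it is a
configurable default (``measure_all(..., features=...)`` restricts it), the
downstream classifier is agnostic to the exact list.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .annotations import AnnotatedSelection, Selection
from .audio_io import Spectrogram

__all__ = ["FEATURE_NAMES", "measure_selection", "measure_all"]

logger = logging.getLogger(__name__)

FEATURE_NAMES = (
    "duration",
    "bandwidth",
    "low_freq",
    "high_freq",
    "peak_freq",
    "center_freq",
    "freq_5pct",
    "freq_95pct",
    "peak_time_rel",
    "time_5pct",
    "time_95pct",
    "aggregate_entropy",
    "average_entropy",
    "peak_power_db",
    "avg_power_db",
    "energy",
)

_EPS = np.finfo(np.float64).tiny


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


def _energy_percentile(axis_values: np.ndarray, energy: np.ndarray, q: float) -> float:
    cum = np.cumsum(energy)
    cum /= cum[-1]
    return float(axis_values[int(np.searchsorted(cum, q))])


def measure_selection(spec: Spectrogram, sel: Selection) -> dict[str, float]:
    """Measure the acoustic features of one selection box.

    Rows are bins with frequency in [low_freq, high_freq]; columns are
    frames whose center time lies in [begin_time, end_time]. Raises
    ``ValueError`` if the box does not intersect the spectrogram.
    """
    rows = np.flatnonzero((spec.freq_axis >= sel.low_freq) & (spec.freq_axis <= sel.high_freq))
    cols = np.flatnonzero((spec.time_axis >= sel.begin_time) & (spec.time_axis <= sel.end_time))
    if rows.size == 0 or cols.size == 0:
        raise ValueError(
            f"selection {sel.selection_id} ({sel.begin_time:.3f}-{sel.end_time:.3f} s, "
            f"{sel.low_freq:.0f}-{sel.high_freq:.0f} Hz) does not intersect the spectrogram"
        )
    sub = spec.magnitude[np.ix_(rows, cols)]
    energy = sub**2
    total = energy.sum()
    freqs = spec.freq_axis[rows]
    times = spec.time_axis[cols]
    duration = sel.duration
    ref = spec.magnitude.max()

    if total > 0:
        e_freq = energy.sum(axis=1)
        e_time = energy.sum(axis=0)
        peak_freq = float(freqs[int(np.argmax(e_freq))])
        center_freq = _energy_percentile(freqs, e_freq, 0.5)
        freq_5 = _energy_percentile(freqs, e_freq, 0.05)
        freq_95 = _energy_percentile(freqs, e_freq, 0.95)
        peak_time = float(times[int(np.argmax(e_time))])
        time_5 = _energy_percentile(times, e_time, 0.05)
        time_95 = _energy_percentile(times, e_time, 0.95)
        aggregate_entropy = _entropy_bits(e_freq / total)
        frame_entropies = [
            _entropy_bits(energy[:, j] / e_time[j]) for j in range(len(times)) if e_time[j] > 0
        ]
        average_entropy = float(np.mean(frame_entropies)) if frame_entropies else 0.0
        peak_power_db = 20.0 * np.log10(sub.max() / ref) if ref > 0 else -np.inf
        rms = np.sqrt(energy.mean())
        avg_power_db = 20.0 * np.log10(max(rms, _EPS) / ref) if ref > 0 else -np.inf
    else:
        # silent box: no energy distribution to summarize
        peak_freq = center_freq = freq_5 = freq_95 = float(freqs[0])
        peak_time = time_5 = time_95 = float(times[0])
        aggregate_entropy = average_entropy = 0.0
        peak_power_db = avg_power_db = -np.inf

    peak_time_rel = float(np.clip((peak_time - sel.begin_time) / duration, 0.0, 1.0))
    return {
        "duration": duration,
        "bandwidth": sel.high_freq - sel.low_freq,
        "low_freq": sel.low_freq,
        "high_freq": sel.high_freq,
        "peak_freq": peak_freq,
        "center_freq": center_freq,
        "freq_5pct": freq_5,
        "freq_95pct": freq_95,
        "peak_time_rel": peak_time_rel,
        "time_5pct": time_5,
        "time_95pct": time_95,
        "aggregate_entropy": aggregate_entropy,
        "average_entropy": average_entropy,
        "peak_power_db": float(peak_power_db),
        "avg_power_db": float(avg_power_db),
        "energy": float(total),
    }


def measure_all(
    specs: Spectrogram | dict[str, Spectrogram],
    selections: list[Selection] | list[AnnotatedSelection],
    features: tuple[str, ...] = FEATURE_NAMES,
) -> pd.DataFrame:
    """Measure a batch of selections into a feature table.

    ``specs`` is one spectrogram (all selections share it) or a mapping
    ``source_id -> Spectrogram``. The result has one row per measurable
    selection with key columns ``source_id``, ``selection_id`` first; rows
    with any non-finite feature (or an empty box intersection) are excluded
    and their count logged.
    """
    unknown = [f for f in features if f not in FEATURE_NAMES]
    if unknown:
        raise ValueError(f"unknown feature(s) {unknown}")
    rows = []
    n_dropped = 0
    for record in selections:
        sel = record.selection if isinstance(record, AnnotatedSelection) else record
        spec = specs if isinstance(specs, Spectrogram) else specs[sel.source_id]
        try:
            measured = measure_selection(spec, sel)
        except ValueError:
            n_dropped += 1
            continue
        values = [measured[f] for f in features]
        if not np.all(np.isfinite(values)):
            n_dropped += 1
            continue
        rows.append([sel.source_id, sel.selection_id, *values])
    if n_dropped:
        logger.warning("excluded %d selection(s) with non-measurable features", n_dropped)
    return pd.DataFrame(rows, columns=["source_id", "selection_id", *features])
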