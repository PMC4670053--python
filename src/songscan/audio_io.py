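"""Audio reading/writing and spectrogram computation.

All audio is handled as mono float arrays in [-1, 1]; the pipeline runs at
the native sample rate of the input (no resampling). Spectrograms follow an
explicit left-aligned frame convention: frame ``t`` covers samples
``[t*hop, t*hop + window_length)``, and the time axis stores frame centers.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.io import wavfile
from scipy.signal import get_window

from .errors import AudioFormatError

__all__ = [
    "AudioClip",
    "Spectrogram",
    "read_audio",
    "write_audio",
    "compute_spectrogram",
]

# aliases accepted on top of scipy's window names
_WINDOW_ALIASES = {"rectangular": "boxcar", "rect": "boxcar", "rectangle": "boxcar"}

_INT_SCALES = {
    np.dtype(np.int16): 2.0**15,
    np.dtype(np.int32): 2.0**31,
}


@dataclass
class AudioClip:
    """A mono sampled waveform.

    Parameters
    ----------
    samples : ndarray
        Dimensionless amplitudes in [-1, 1].
    sample_rate : float
        Sampling rate in Hz, > 0.
    source_id : str
        Identifier of the originating recording.
    """

    samples: np.ndarray
    sample_rate: float
    source_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise AudioFormatError("AudioClip samples must be one-dimensional")
        if self.sample_rate <= 0:
            raise AudioFormatError(f"sample_rate must be > 0, got {self.sample_rate}")
        if not np.all(np.isfinite(self.samples)):
            raise AudioFormatError("AudioClip samples must be finite")

    @property
    def duration(self) -> float:
        """Clip length in seconds."""
        return len(self.samples) / self.sample_rate


@dataclass
class Spectrogram:
    """Time-frequency magnitude grid.

    ``magnitude`` has shape (n_freq_bins, n_frames) with
    ``n_freq_bins == window_length // 2 + 1``. ``freq_axis`` is Hz per bin
    (ascending), ``time_axis`` holds frame-center times in seconds.
    """

    magnitude: np.ndarray
    freq_axis: np.ndarray
    time_axis: np.ndarray
    window_length: int
    hop: int
    window_name: str = "hann"
    sample_rate: float = field(default=0.0)
    source_id: str = ""

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=np.float64)
        self.freq_axis = np.asarray(self.freq_axis, dtype=np.float64)
        self.time_axis = np.asarray(self.time_axis, dtype=np.float64)
        if self.magnitude.ndim != 2:
            raise ValueError("magnitude must be 2-D (n_freq_bins, n_frames)")
        if self.magnitude.shape != (len(self.freq_axis), len(self.time_axis)):
            raise ValueError("magnitude shape does not match axis lengths")
        if not np.all(np.isfinite(self.magnitude)) or np.any(self.magnitude < 0):
            raise ValueError("magnitude must be finite and non-negative")
        if len(self.freq_axis) > 1 and not np.all(np.diff(self.freq_axis) > 0):
            raise ValueError("freq_axis must be strictly increasing")
        if len(self.time_axis) > 1 and not np.all(np.diff(self.time_axis) > 0):
            raise ValueError("time_axis must be strictly increasing")

    @property
    def n_freq_bins(self) -> int:
        return self.magnitude.shape[0]

    @property
    def n_frames(self) -> int:
        return self.magnitude.shape[1]

    @property
    def hop_seconds(self) -> float:
        return self.hop / self.sample_rate

    def frame_start_time(self, frame: int) -> float:
        """Time (s) of the first sample covered by ``frame``."""
        return frame * self.hop / self.sample_rate


def read_audio(path: str | os.PathLike) -> AudioClip:
    """Read a PCM WAV file as a mono, [-1, 1]-normalized :class:`AudioClip`.

    Multi-channel input is averaged to mono. Integer encodings are scaled by
    their full-scale value; float encodings are passed through.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # wavfile raises assorted ValueError subclasses
        raise AudioFormatError(f"cannot read WAV file {path!r}: {exc}") from exc
    if data.size == 0:
        raise AudioFormatError(f"WAV file {path!r} contains no samples")
    samples = data.astype(np.float64)
    if data.dtype in _INT_SCALES:
        samples /= _INT_SCALES[data.dtype]
    elif data.dtype == np.uint8:
        samples = (samples - 128.0) / 128.0
    elif not np.issubdtype(data.dtype, np.floating):
        raise AudioFormatError(f"unsupported WAV encoding {data.dtype} in {path!r}")
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    source_id = os.path.splitext(os.path.basename(path))[0]
    return AudioClip(samples=samples, sample_rate=float(rate), source_id=source_id)


def write_audio(clip: AudioClip, path: str | os.PathLike, bit_depth: int = 16) -> None:
    """Write a clip as PCM WAV (16- or 24-bit equivalent int32)."""
    samples = np.clip(clip.samples, -1.0, 1.0)
    if bit_depth == 16:
        data = np.clip(np.round(samples * 2**15), -(2**15), 2**15 - 1).astype(np.int16)
    elif bit_depth == 24:
        # stored as int32 with full-scale 2**31; low byte zero, i.e. 24 effective bits
        data = np.clip(np.round(samples * 2**23), -(2**23), 2**23 - 1).astype(np.int32) << 8
    else:
        raise AudioFormatError(f"unsupported bit depth {bit_depth}")
    wavfile.write(os.fspath(path), int(clip.sample_rate), data)


def compute_spectrogram(
    clip: AudioClip,
    window_length: int = 512,
    hop: int = 256,
    window_name: str = "hann",
) -> Spectrogram:
    """Magnitude short-time Fourier transform of ``clip``.

    Frame ``t`` covers samples ``[t*hop, t*hop + window_length)``; no padding
    is applied, so every frame is fully backed by data and the last frame
    center lies strictly inside the clip.
    """
    if window_length < 16:
        raise ValueError(f"window_length must be >= 16, got {window_length}")
    if hop < 1:
        raise ValueError(f"hop must be >= 1, got {hop}")
    n = len(clip.samples)
    if n < window_length:
        raise ValueError(
            f"clip has {n} samples, shorter than one window ({window_length})"
        )
    window = get_window(_WINDOW_ALIASES.get(window_name, window_name), window_length, fftbins=True)
    frames = sliding_window_view(clip.samples, window_length)[::hop]
    magnitude = np.abs(np.fft.rfft(frames * window, axis=1)).T
    freq_axis = np.fft.rfftfreq(window_length, d=1.0 / clip.sample_rate)
    starts = np.arange(frames.shape[0]) * hop
    time_axis = (starts + window_length / 2.0) / clip.sample_rate
    return Spectrogram(
        magnitude=magnitude,
        freq_axis=freq_axis,
        time_axis=time_axis,
        window_length=window_length,
        hop=hop,
        window_name=window_name,
        sample_rate=clip.sample_rate,
        source_id=clip.source_id,
    )
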