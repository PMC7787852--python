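"""WAV I/O and time-domain preprocessing.

This module provides the shared front end of the pipeline: reading a
recording into the canonical 16 kHz mono form, pre-emphasis (first-order
high-pass), short-time framing, Hamming windowing and the per-frame power
spectrum.  All three cepstral feature extractors and the event detector
are built on these primitives.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from os import PathLike

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

from .errors import FormatError, InputSizeError, ParameterError

logger = logging.getLogger(__name__)

#: Canonical sample rate of the pipeline (Hz).  Recordings at any other
#: rate are resampled on read.
TARGET_RATE = 16_000


@dataclass(frozen=True)
class AudioSignal:
    """A sampled waveform.

    Parameters
    ----------
    samples
        1-D float array of amplitudes, nominally in ``[-1, 1]``.
    sample_rate
        Sampling frequency in Hz.
    """

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples)
        if samples.ndim != 1:
            raise ParameterError("AudioSignal samples must be 1-D")
        if not np.issubdtype(samples.dtype, np.floating):
            samples = samples.astype(np.float64)
        object.__setattr__(self, "samples", samples)
        if self.sample_rate <= 0:
            raise ParameterError("sample_rate must be positive")

    @property
    def duration_s(self) -> float:
        """Duration in seconds."""
        return len(self.samples) / self.sample_rate

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class FrameParams:
    """Short-time analysis parameters.

    The defaults — 0.03 s frames with a 0.01 s shift — give exactly 298
    frames on a 3 s clip at 16 kHz, which is the row count of every
    feature matrix fed to the classifiers.
    """

    frame_len_s: float = 0.03
    shift_s: float = 0.01
    preemph_alpha: float = 0.97
    n_fft: int = 512

    def __post_init__(self) -> None:
        if not 0 < self.shift_s <= self.frame_len_s:
            raise ParameterError("require 0 < shift_s <= frame_len_s")
        if not 0.0 <= self.preemph_alpha <= 1.0:
            raise ParameterError("preemph_alpha must be in [0, 1]")
        if self.n_fft < 1:
            raise ParameterError("n_fft must be positive")

    def frame_len(self, sample_rate: int) -> int:
        """Frame length in samples."""
        return int(round(self.frame_len_s * sample_rate))

    def shift(self, sample_rate: int) -> int:
        """Frame shift (hop) in samples."""
        return int(round(self.shift_s * sample_rate))


@dataclass(frozen=True)
class FrameMatrix:
    """A stack of short-time frames cut from one signal."""

    frames: np.ndarray  # (n_frames, frame_len)
    params: FrameParams
    sample_rate: int = TARGET_RATE
    windowed: bool = field(default=False, compare=False)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_len(self) -> int:
        return self.frames.shape[1]

    def frame_start_s(self, index: np.ndarray | int) -> np.ndarray | float:
        """Start time (s) of frame ``index`` in the source signal."""
        return np.asarray(index) * self.params.shift(self.sample_rate) / self.sample_rate


def n_frames_for(n_samples: int, frame_len: int, shift: int) -> int:
    """Number of complete frames: ``floor((n - frame_len)/shift) + 1``.

    The trailing remainder that does not fill a whole frame is dropped;
    this is the convention that yields 298 frames from 48 000 samples at
    the default 480/160 framing.
    """
    if n_samples < frame_len:
        return 0
    return (n_samples - frame_len) // shift + 1


def read_wav(path: str | PathLike) -> AudioSignal:
    """Read a PCM/float WAV file into canonical 16 kHz mono form.

    Integer samples are scaled to ``[-1, 1]``; multichannel audio is
    averaged down to mono; any sample rate other than 16 kHz is
    resampled with band-limited polyphase interpolation (and logged).
    """
    try:
        rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # wavfile raises bare ValueError on bad RIFF
        raise FormatError(f"could not read WAV file {path!r}: {exc}") from exc
    if data.size == 0:
        raise FormatError(f"WAV file {path!r} contains no samples")
    if data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif np.issubdtype(data.dtype, np.integer):
        samples = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        samples = data.astype(np.float64)
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    if rate != TARGET_RATE:
        g = math.gcd(int(rate), TARGET_RATE)
        samples = resample_poly(samples, TARGET_RATE // g, int(rate) // g)
        logger.info("resampled %r from %d Hz to %d Hz", path, rate, TARGET_RATE)
    return AudioSignal(samples=samples, sample_rate=TARGET_RATE)


def write_wav(path: str | PathLike, signal: AudioSignal) -> None:
    """Write a signal as 16-bit PCM WAV."""
    clipped = np.clip(signal.samples, -1.0, 1.0)
    wavfile.write(path, signal.sample_rate, (clipped * 32767.0).astype(np.int16))


def preemphasize(signal: AudioSignal, alpha: float | None = None) -> AudioSignal:
    """First-order high-pass filter ``y[n] = x[n] - alpha * x[n-1]``.

    ``y[0] = x[0]``.  Boosts high-frequency content before spectral
    analysis.  ``alpha=0`` is the identity.
    """
    if alpha is None:
        alpha = FrameParams().preemph_alpha
    if not 0.0 <= alpha <= 1.0:
        raise ParameterError(f"preemphasis alpha must be in [0, 1], got {alpha}")
    x = signal.samples
    y = np.empty_like(x, dtype=np.float64)
    y[0] = x[0]
    y[1:] = x[1:] - alpha * x[:-1]
    return AudioSignal(samples=y, sample_rate=signal.sample_rate)


def deemphasize(signal: AudioSignal, alpha: float) -> AudioSignal:
    """Inverse of :func:`preemphasize` (the running recursion)."""
    y = signal.samples
    x = np.empty_like(y, dtype=np.float64)
    acc = 0.0
    for n in range(len(y)):  # sequential recursion; used only in tests
        acc = y[n] + alpha * acc
        x[n] = acc
    return AudioSignal(samples=x, sample_rate=signal.sample_rate)


def frame_signal(signal: AudioSignal, params: FrameParams | None = None) -> FrameMatrix:
    """Cut a signal into overlapping short-time frames.

    Raises :class:`InputSizeError` if the signal is shorter than one
    frame.  The incomplete trailing frame, if any, is dropped.
    """
    params = params or FrameParams()
    flen = params.frame_len(signal.sample_rate)
    shift = params.shift(signal.sample_rate)
    n = n_frames_for(len(signal.samples), flen, shift)
    if n < 1:
        raise InputSizeError(
            f"signal of {len(signal.samples)} samples is shorter than one "
            f"frame of {flen} samples"
        )
    idx = shift * np.arange(n)[:, None] + np.arange(flen)[None, :]
    frames = signal.samples[idx]
    return FrameMatrix(frames=frames, params=params, sample_rate=signal.sample_rate)


def apply_hamming(frames: FrameMatrix) -> FrameMatrix:
    """Multiply each frame by the Hamming window
    ``w[n] = 0.54 - 0.46 cos(2 pi n / (N - 1))``."""
    window = np.hamming(frames.frame_len)
    return FrameMatrix(
        frames=frames.frames * window[None, :],
        params=frames.params,
        sample_rate=frames.sample_rate,
        windowed=True,
    )


def power_spectrum(frames: FrameMatrix, n_fft: int | None = None) -> np.ndarray:
    """Per-frame squared-magnitude DFT, ``|X_a(k)|^2``.

    Frames are zero-padded to ``n_fft`` points and only the
    non-redundant half (``n_fft // 2 + 1`` bins) is returned.
    """
    if n_fft is None:
        n_fft = frames.params.n_fft
    if n_fft < frames.frame_len:
        raise ParameterError(
            f"n_fft={n_fft} is smaller than the frame length {frames.frame_len}"
        )
    spectrum = np.fft.rfft(frames.frames, n=n_fft, axis=1)
    return np.abs(spectrum) ** 2


def preprocess(
    signal: AudioSignal, params: FrameParams | None = None
) -> FrameMatrix:
    """Pre-emphasis -> framing -> Hamming window, in that order."""
    params = params or FrameParams()
    emphasized = preemphasize(signal, params.preemph_alpha)
    return apply_hamming(frame_signal(emphasized, params))
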