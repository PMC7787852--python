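"""Snore-episode segmentation by dual-threshold endpoint detection.

Long recordings are reduced to fixed 3 s clips.  Candidate regions are
frames whose short-time energy exceeds a high threshold relative to the
noise floor (the 10th percentile of frame energies); each candidate is
extended outward while energy stays above a low threshold or the
zero-crossing rate stays high, nearby regions are merged, and short
blips are discarded.  Each surviving event becomes one 3 s clip centred
on its peak-energy frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from os import PathLike

import numpy as np

from .errors import InputSizeError, ParameterError
from .signal import AudioSignal, FrameMatrix, FrameParams, frame_signal

#: Fixed clip duration in seconds; every classifier input is this long.
CLIP_LEN_S = 3.0


@dataclass(frozen=True)
class SegmentationParams:
    """Thresholds of the dual-threshold detector.

    ``energy_high`` / ``energy_low`` are multiples of the noise floor;
    ``zcr_threshold`` is crossings per frame *above the median frame
    ZCR* (default framing: 480 samples).  The baseline is adaptive
    because broadband background noise already crosses zero hundreds of
    times per frame; an absolute threshold would extend every candidate
    region into its neighbours.
    """

    energy_high: float = 8.0
    energy_low: float = 2.0
    zcr_threshold: float = 40.0
    min_event_s: float = 0.3
    merge_gap_s: float = 0.2
    clip_len_s: float = CLIP_LEN_S
    noise_percentile: float = 10.0
    frame_params: FrameParams = FrameParams()

    def __post_init__(self) -> None:
        if not self.energy_high >= self.energy_low > 0:
            raise ParameterError("require energy_high >= energy_low > 0")
        if self.min_event_s <= 0:
            raise ParameterError("min_event_s must be positive")
        if self.clip_len_s != CLIP_LEN_S:
            raise ParameterError(f"clip_len_s is fixed at {CLIP_LEN_S} s")


@dataclass(frozen=True)
class Event:
    """A detected (or planted) acoustic event, in seconds."""

    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not 0 <= self.start_s < self.end_s:
            raise ParameterError("require 0 <= start_s < end_s")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def center_s(self) -> float:
        return 0.5 * (self.start_s + self.end_s)

    def overlap_s(self, other: "Event") -> float:
        """Length of the overlap with another event (0 if disjoint)."""
        return max(0.0, min(self.end_s, other.end_s) - max(self.start_s, other.start_s))


@dataclass(frozen=True)
class Annotation:
    """An event with a class label (``normal`` / ``abnormal``)."""

    event: Event
    label: str


@dataclass(frozen=True)
class SnoreClip:
    """An exactly-3 s audio clip, optionally labelled."""

    audio: AudioSignal
    label: str | None = None
    source_event: Event | None = None
    kind: str | None = None

    def __post_init__(self) -> None:
        expected = int(round(CLIP_LEN_S * self.audio.sample_rate))
        if len(self.audio) != expected:
            raise ParameterError(
                f"clip must be exactly {expected} samples, got {len(self.audio)}"
            )


def short_time_energy(frames: FrameMatrix) -> np.ndarray:
    """Mean squared amplitude per frame."""
    return np.mean(frames.frames**2, axis=1)


def zero_crossing_rate(frames: FrameMatrix) -> np.ndarray:
    """Sign changes between consecutive samples per frame (zeros count
    as positive)."""
    signs = np.where(frames.frames >= 0, 1, -1)
    return np.count_nonzero(np.diff(signs, axis=1), axis=1)


def _framewise_energy_zcr(
    signal: AudioSignal, fp: FrameParams, chunk: int = 20_000
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame energy and ZCR computed in chunks over a strided view,
    so hour-long recordings never materialise the full frame matrix."""
    flen = fp.frame_len(signal.sample_rate)
    shift = fp.shift(signal.sample_rate)
    view = np.lib.stride_tricks.sliding_window_view(signal.samples, flen)[::shift]
    n = view.shape[0]
    energy = np.empty(n)
    zcr = np.empty(n, dtype=np.int64)
    for start in range(0, n, chunk):
        block = view[start: start + chunk]
        energy[start: start + chunk] = np.mean(
            np.square(block, dtype=np.float64), axis=1
        )
        signs = np.where(block >= 0, 1, -1)
        zcr[start: start + chunk] = np.count_nonzero(np.diff(signs, axis=1), axis=1)
    return energy, zcr


def detect_events(
    signal: AudioSignal, params: SegmentationParams | None = None
) -> list[Event]:
    """Locate acoustic events with the dual-threshold detector.

    Deterministic; returns non-overlapping events sorted by start time.
    An empty list is a valid result for quiet input.
    """
    params = params or SegmentationParams()
    fp = params.frame_params
    if len(signal) < fp.frame_len(signal.sample_rate):
        raise InputSizeError("recording is shorter than one analysis frame")
    energy, zcr = _framewise_energy_zcr(signal, fp)
    floor = np.percentile(energy, params.noise_percentile)
    zcr_baseline = np.median(zcr)
    high = energy > params.energy_high * floor
    low = (energy > params.energy_low * floor) | (
        zcr > zcr_baseline + params.zcr_threshold
    )

    shift = fp.shift(signal.sample_rate)
    flen = fp.frame_len(signal.sample_rate)
    n = len(energy)

    # runs of the high mask
    regions: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if not high[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and high[j + 1]:
            j += 1
        # extend outward on the low mask
        lo, hi = i, j
        while lo - 1 >= 0 and low[lo - 1]:
            lo -= 1
        while hi + 1 < n and low[hi + 1]:
            hi += 1
        regions.append((lo, hi))
        i = hi + 1

    # merge regions whose gap is below merge_gap_s
    max_gap_frames = int(round(params.merge_gap_s * signal.sample_rate / shift))
    merged: list[tuple[int, int]] = []
    for lo, hi in regions:
        if merged and lo - merged[-1][1] - 1 <= max_gap_frames:
            merged[-1] = (merged[-1][0], hi)
        else:
            merged.append((lo, hi))

    events = []
    for lo, hi in merged:
        start_s = lo * shift / signal.sample_rate
        end_s = min((hi * shift + flen) / signal.sample_rate, signal.duration_s)
        if end_s - start_s >= params.min_event_s:
            events.append(Event(start_s=start_s, end_s=end_s))
    return events


def extract_clips(
    signal: AudioSignal,
    events: list[Event],
    params: SegmentationParams | None = None,
) -> list[SnoreClip]:
    """Cut one 3 s clip per event, centred on its peak-energy frame.

    Windows near the recording edges are shifted inward so every clip
    keeps real recording context (never zero padding).
    """
    params = params or SegmentationParams()
    sr = signal.sample_rate
    clip_len = int(round(params.clip_len_s * sr))
    if len(signal) < clip_len:
        raise InputSizeError("recording shorter than one clip length")
    fp = params.frame_params
    shift = fp.shift(sr)
    flen = fp.frame_len(sr)
    clips = []
    for event in events:
        if event.end_s > signal.duration_s + 1e-9:
            raise ParameterError(f"event {event} exceeds the recording bounds")
        seg = signal.samples[int(event.start_s * sr): int(event.end_s * sr)]
        if len(seg) >= flen:
            seg_frames = frame_signal(AudioSignal(seg, sr), fp)
            peak = int(np.argmax(short_time_energy(seg_frames)))
            center = int(event.start_s * sr) + peak * shift + flen // 2
        else:
            center = int(event.center_s * sr)
        start = int(np.clip(center - clip_len // 2, 0, len(signal) - clip_len))
        clips.append(
            SnoreClip(
                audio=AudioSignal(signal.samples[start: start + clip_len], sr),
                source_event=event,
            )
        )
    return clips


def write_annotations(
    path: str | PathLike, annotations: list[Annotation]
) -> None:
    """Write events as a tab-separated file: start_s, end_s, label."""
    with open(path, "w") as fh:
        fh.write("start_s\tend_s\tlabel\n")
        for ann in annotations:
            fh.write(f"{ann.event.start_s:.4f}\t{ann.event.end_s:.4f}\t{ann.label}\n")


def read_annotations(path: str | PathLike) -> list[Annotation]:
    """Read the tab-separated annotation format back."""
    annotations = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("start_s"):
            raise ParameterError(f"{path!r} is not an annotation file")
        for line in fh:
            if not line.strip():
                continue
            start, end, label = line.rstrip("\n").split("\t")
            annotations.append(
                Annotation(event=Event(float(start), float(end)), label=label)
            )
    return annotations
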