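"""Evaluation metrics and the screening arithmetic.

Classifier quality is summarised by accuracy, precision,
sensitivity (recall), specificity and F1 computed from a confusion
matrix.  Screening converts the count of abnormal-labelled snores (AB)
in a recording of SH hours of sleep into an apnea-hypopnea index

    AHI = (AB / 2) / SH

— the divisor 2 reflects the assumption that each apnea event
contributes exactly two abnormal snores (one faint snore during the
event, one gasp after it) — and then grades severity:

    AHI <= 5   normal (0)       15 < AHI <= 30  moderate (2)
    5 < AHI <= 15  slight (1)   AHI > 30        serious (3)

Note on specificity: the conventional definition TN / (TN + FP) is
used; implementations that divide by (TP + FP) are a known transcription
error and are deliberately not reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .errors import ParameterError
from .features import FeatureConfig, extract
from .segmentation import (
    Annotation,
    Event,
    SegmentationParams,
    SnoreClip,
    detect_events,
    extract_clips,
)
from .signal import AudioSignal, FrameParams

#: Abnormal snores counted per apnea event (faint + gasp).
SNORES_PER_EVENT = 2

SEVERITY_NAMES = ("normal", "slight", "moderate", "serious")


@dataclass(frozen=True)
class ConfusionCounts:
    """TP / FN / TN / FP counts of a binary classifier."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ParameterError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @classmethod
    def from_predictions(
        cls, y_true: Sequence[int], y_pred: Sequence[int], positive: int = 1
    ) -> "ConfusionCounts":
        t = np.asarray(y_true) == positive
        p = np.asarray(y_pred) == positive
        return cls(
            tp=int(np.sum(t & p)),
            fn=int(np.sum(t & ~p)),
            tn=int(np.sum(~t & ~p)),
            fp=int(np.sum(~t & p)),
        )


@dataclass(frozen=True)
class MetricSet:
    """The five summary metrics; a metric with a zero denominator is
    ``None`` (undefined) rather than silently 0."""

    accuracy: float | None
    precision: float | None
    sensitivity: float | None
    specificity: float | None
    f1: float | None

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f1": self.f1,
        }


def compute_metrics(counts: ConfusionCounts) -> MetricSet:
    """Accuracy, precision, sensitivity, specificity and F1 from counts."""
    if counts.total == 0:
        raise ParameterError("cannot compute metrics from all-zero counts")

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    accuracy = (counts.tp + counts.tn) / counts.total
    precision = ratio(counts.tp, counts.tp + counts.fp)
    sensitivity = ratio(counts.tp, counts.tp + counts.fn)
    specificity = ratio(counts.tn, counts.tn + counts.fp)
    if precision is None or sensitivity is None:
        f1 = None
    elif precision + sensitivity == 0:
        f1 = 0.0
    else:
        f1 = 2.0 * precision * sensitivity / (precision + sensitivity)
    return MetricSet(
        accuracy=accuracy,
        precision=precision,
        sensitivity=sensitivity,
        specificity=specificity,
        f1=f1,
    )


def compute_ahi(
    ab_count: int, sleep_hours: float, snores_per_event: int = SNORES_PER_EVENT
) -> float:
    """AHI = (AB / snores_per_event) / SH, in events per hour."""
    if sleep_hours <= 0:
        raise ParameterError("sleep_hours must be positive")
    if ab_count < 0:
        raise ParameterError("ab_count must be nonnegative")
    return (ab_count / snores_per_event) / sleep_hours


def grade_severity(ahi: float) -> tuple[int, str]:
    """Map an AHI to ``(degree, name)`` with the thresholds above."""
    if ahi < 0:
        raise ParameterError("ahi must be nonnegative")
    if ahi <= 5:
        degree = 0
    elif ahi <= 15:
        degree = 1
    elif ahi <= 30:
        degree = 2
    else:
        degree = 3
    return degree, SEVERITY_NAMES[degree]


class AhiDiscrepancy(NamedTuple):
    """Scaled and plain differences between a reference and an estimate."""

    scaled: float  # |ref - est| / 4
    absolute: float


def ahi_discrepancy(ahi_ref: float, ahi_est: float) -> AhiDiscrepancy:
    """Quarter-scaled absolute AHI difference, ``|ref - est| / 4``.

    The scale factor 4 is an empirical reporting convention; the plain
    absolute difference is returned alongside and should be preferred
    for new analyses.
    """
    if ahi_ref < 0 or ahi_est < 0:
        raise ParameterError("AHI values must be nonnegative")
    diff = abs(ahi_ref - ahi_est)
    return AhiDiscrepancy(scaled=diff / 4.0, absolute=diff)


@dataclass(frozen=True)
class ClipDecision:
    """Per-clip audit record of a screening run."""

    event: Event
    label: int
    probability: float


@dataclass(frozen=True)
class ScreeningReport:
    """Outcome of screening one recording."""

    ab_count: int
    sleep_hours: float
    ahi: float
    degree: int
    degree_name: str
    decisions: list[ClipDecision] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "ab_count": self.ab_count,
            "sleep_hours": self.sleep_hours,
            "ahi": self.ahi,
            "degree": self.degree,
            "degree_name": self.degree_name,
            "n_clips": len(self.decisions),
        }

    def to_text(self) -> str:
        lines = [
            "snorescreen report",
            f"  clips classified : {len(self.decisions)}",
            f"  abnormal snores  : {self.ab_count}",
            f"  sleep hours      : {self.sleep_hours:.2f}",
            f"  AHI              : {self.ahi:.2f} events/hour",
            f"  severity         : {self.degree} ({self.degree_name})",
        ]
        return "\n".join(lines)

    def annotations(self) -> list[Annotation]:
        return [
            Annotation(event=d.event, label="abnormal" if d.label == 1 else "normal")
            for d in self.decisions
        ]


def screen_recording(
    audio: AudioSignal,
    model,
    feature_kind: str = "mfcc",
    sleep_hours: float | None = None,
    seg_params: SegmentationParams | None = None,
    frame_params: FrameParams | None = None,
    feature_config: FeatureConfig | None = None,
) -> ScreeningReport:
    """Run the full screening chain on one recording.

    Detect events, cut 3 s clips, extract features, classify each clip,
    count abnormal snores, convert to AHI and grade severity.  ``model``
    is either a :class:`~snorescreen.models.TrainedModel` or any object
    with a ``predict_clip(clip) -> (label, probability)`` method (used
    by oracle classifiers in validation).
    """
    from .models import TrainedModel, predict_proba  # deferred; avoids a cycle

    if sleep_hours is None:
        sleep_hours = audio.duration_s / 3600.0
    if isinstance(model, TrainedModel) and model.feature_kind not in (
        None, feature_kind,
    ):
        raise ParameterError(
            f"model was trained on {model.feature_kind!r} features, "
            f"but {feature_kind!r} was requested"
        )
    events = detect_events(audio, seg_params)
    clips = extract_clips(audio, events, seg_params) if events else []
    decisions: list[ClipDecision] = []
    if clips and hasattr(model, "predict_clip"):
        for clip in clips:
            label, prob = model.predict_clip(clip)
            decisions.append(
                ClipDecision(event=clip.source_event, label=int(label),
                             probability=float(prob))
            )
    elif clips:
        mats = [
            extract(clip.audio, feature_kind, frame_params, feature_config)
            for clip in clips
        ]
        probs = predict_proba(model, mats)
        for clip, p in zip(clips, probs):
            decisions.append(
                ClipDecision(
                    event=clip.source_event,
                    label=int(np.argmax(p)),
                    probability=float(p[1]),
                )
            )
    ab = sum(d.label == 1 for d in decisions)
    ahi = compute_ahi(ab, sleep_hours)
    degree, name = grade_severity(ahi)
    return ScreeningReport(
        ab_count=ab,
        sleep_hours=sleep_hours,
        ahi=ahi,
        degree=degree,
        degree_name=name,
        decisions=decisions,
    )
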