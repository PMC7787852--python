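"""Synthetic snore audio: labelled 3 s clips and whole overnight sessions.

No public snore corpus with apnea annotations exists, so every pipeline
stage is exercised on generated audio that mimics the phenomenology of
obstructive sleep apnea recordings:

* **normal snores** — periodic harmonic bursts (fundamental 90-140 Hz,
  moderate amplitude) riding on low-level background noise;
* **faint in-apnea snores** — the same harmonic structure at much lower
  amplitude and slightly lower pitch, as heard while the airway is
  obstructed;
* **post-apnea gasps** — loud, broadband, irregular bursts as breathing
  resumes.

A session is background noise with normal snores at a steady rate,
interrupted by apnea events of about 10 s: a quiet interval containing
one faint snore, followed immediately by one gasp.  Each event thus
contributes exactly two abnormal snores, matching the screening rule
AHI = (AB / 2) / SH.  All generation is a pure function of its seed.

The acoustic parameter distributions are stylised, not physiological:
classes are separable but overlapping (pitch ranges overlap; faint
snores differ from normal ones mainly through their signal-to-noise
ratio), so a classifier has real work to do.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ParameterError
from .segmentation import Annotation, Event, SnoreClip
from .signal import TARGET_RATE, AudioSignal

CLIP_KINDS = ("normal", "abnormal_faint", "abnormal_gasp")

#: Background noise RMS in clips and sessions (recording-room hiss).
#: Clips share the session value so that directly generated clips match
#: clips cut out of sessions by endpoint detection.
DEFAULT_NOISE_RMS = 0.003
DEFAULT_SESSION_NOISE = DEFAULT_NOISE_RMS
#: Minimum gap between apnea events in a session (s).
MIN_EVENT_GAP_S = 30.0


@dataclass(frozen=True)
class SnoreAcoustics:
    """Acoustic description of one snore burst train."""

    f0: float = 110.0  # fundamental (Hz)
    n_harmonics: int = 14
    spectral_tilt: float = -12.0  # dB per octave of harmonic roll-off
    amplitude: float = 0.5  # peak envelope level in (0, 1]
    burst_rate: float = 0.4  # snore cycles per second (breathing rate)
    duration_s: float = 3.0

    def __post_init__(self) -> None:
        if not 40.0 <= self.f0 <= 400.0:
            raise ParameterError("f0 must be in [40, 400] Hz")
        if not 0.0 < self.amplitude <= 1.0:
            raise ParameterError("amplitude must be in (0, 1]")
        if self.duration_s <= 0:
            raise ParameterError("duration_s must be positive")


@dataclass(frozen=True)
class SessionSpec:
    """Specification of one synthetic overnight session."""

    hours: float = 1.0
    events_per_hour: float = 20.0
    noise_level: float = DEFAULT_SESSION_NOISE
    seed: int = 0
    normal_snore_rate: float = 4.0  # snores per minute outside events

    def __post_init__(self) -> None:
        if self.hours <= 0:
            raise ParameterError("hours must be positive")
        if self.events_per_hour < 0:
            raise ParameterError("events_per_hour must be nonnegative")


def _harmonic_burst_train(
    rng: np.random.Generator,
    acoustics: SnoreAcoustics,
    sample_rate: int,
    jitter: float = 0.0,
    single_burst: bool = False,
) -> np.ndarray:
    """A harmonic series gated by a raised-cosine breathing envelope.

    ``jitter`` adds per-harmonic random frequency wobble (used for the
    irregular gasp timbre).  With ``single_burst`` the envelope is one
    lobe spanning the whole duration (used for snores planted into
    sessions, so each planted snore is one contiguous acoustic event).
    """
    n = int(round(acoustics.duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    wave = np.zeros(n)
    for k in range(1, acoustics.n_harmonics + 1):
        level = 10.0 ** (acoustics.spectral_tilt * np.log2(k) / 20.0)
        fk = k * acoustics.f0
        if fk >= sample_rate / 2:
            break
        if jitter > 0:
            fk *= 1.0 + jitter * rng.uniform(-1.0, 1.0)
        phase = rng.uniform(0, 2 * np.pi)
        wave += level * np.sin(2 * np.pi * fk * t + phase)
    if single_burst:
        env = np.sin(np.pi * t / acoustics.duration_s) ** 2
    else:
        env_phase = rng.uniform(0, 2 * np.pi)
        env = (
            np.maximum(0.0, np.sin(np.pi * acoustics.burst_rate * t + env_phase)) ** 2
        )
    wave *= env
    peak = np.max(np.abs(wave))
    if peak > 0:
        wave *= acoustics.amplitude / peak
    return wave


def _gasp_burst(
    rng: np.random.Generator, acoustics: SnoreAcoustics, sample_rate: int
) -> np.ndarray:
    """A broadband inhalation burst plus irregular harmonics."""
    n = int(round(acoustics.duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    noise = rng.standard_normal(n)
    # centre the burst with a sharp attack / slow decay envelope
    onset = acoustics.duration_s * rng.uniform(0.2, 0.4)
    width = acoustics.duration_s * 0.25
    env = np.exp(-0.5 * ((t - onset) / width) ** 2)
    env[t < onset] = np.exp(-0.5 * ((t[t < onset] - onset) / (width / 4)) ** 2)
    burst = noise * env
    harm = _harmonic_burst_train(
        rng, replace(acoustics, amplitude=1.0, burst_rate=1.2), sample_rate,
        jitter=0.05, single_burst=True,
    )
    wave = 0.6 * burst / max(np.max(np.abs(burst)), 1e-12) + 0.4 * harm
    peak = np.max(np.abs(wave))
    if peak > 0:
        wave *= acoustics.amplitude / peak
    return wave


def _clip_kind_acoustics(kind: str, rng: np.random.Generator) -> SnoreAcoustics:
    if kind == "normal":
        return SnoreAcoustics(
            f0=rng.uniform(90.0, 140.0), amplitude=rng.uniform(0.4, 0.7),
            duration_s=rng.uniform(1.2, 2.2),
        )
    if kind == "abnormal_faint":
        return SnoreAcoustics(
            f0=rng.uniform(60.0, 100.0), amplitude=rng.uniform(0.05, 0.15),
            duration_s=rng.uniform(1.2, 1.8),
        )
    if kind == "abnormal_gasp":
        return SnoreAcoustics(
            f0=rng.uniform(70.0, 120.0), amplitude=rng.uniform(0.8, 1.0),
            duration_s=rng.uniform(1.0, 1.5),
        )
    raise ParameterError(f"kind must be one of {CLIP_KINDS}, got {kind!r}")


def gen_snore_clip(
    kind: str,
    acoustics: SnoreAcoustics | None = None,
    seed: int = 0,
    sample_rate: int = TARGET_RATE,
    noise_rms: float = DEFAULT_NOISE_RMS,
    clip_len_s: float = 3.0,
) -> SnoreClip:
    """Generate one labelled 3 s clip; deterministic for a fixed seed.

    The clip mimics what endpoint detection cuts from a long recording:
    one snore burst of 1-2 s, approximately centred in the 3 s window,
    over continuous background noise.
    """
    rng = np.random.default_rng(seed)
    if acoustics is None:
        acoustics = _clip_kind_acoustics(kind, rng)
    elif kind not in CLIP_KINDS:
        raise ParameterError(f"kind must be one of {CLIP_KINDS}, got {kind!r}")
    if kind == "abnormal_gasp":
        burst = _gasp_burst(rng, acoustics, sample_rate)
    else:
        burst = _harmonic_burst_train(rng, acoustics, sample_rate, single_burst=True)
    n = int(round(clip_len_s * sample_rate))
    wave = noise_rms * rng.standard_normal(n)
    # peak-centring leaves a small jitter in practice
    offset_s = (clip_len_s - acoustics.duration_s) / 2 + rng.uniform(-0.2, 0.2)
    offset = int(np.clip(offset_s * sample_rate, 0, n - len(burst)))
    wave[offset: offset + len(burst)] += burst
    wave = np.clip(wave, -1.0, 1.0).astype(np.float32)
    label = "normal" if kind == "normal" else "abnormal"
    return SnoreClip(
        audio=AudioSignal(samples=wave, sample_rate=sample_rate),
        label=label,
        kind=kind,
    )


def gen_clip_dataset(n_per_class: int, seed: int = 0) -> list[SnoreClip]:
    """A balanced labelled clip set.

    The abnormal class is an even mix of faint in-apnea snores and
    post-apnea gasps; per-clip seeds are derived from the master seed.
    """
    if n_per_class < 1:
        raise ParameterError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    clips = []
    for i in range(n_per_class):
        clips.append(gen_snore_clip("normal", seed=int(rng.integers(2**31))))
    for i in range(n_per_class):
        kind = "abnormal_faint" if i % 2 == 0 else "abnormal_gasp"
        clips.append(gen_snore_clip(kind, seed=int(rng.integers(2**31))))
    return clips


def _place_snippet(session: np.ndarray, start_sample: int, wave: np.ndarray) -> None:
    end = min(start_sample + len(wave), len(session))
    session[start_sample:end] += wave[: end - start_sample].astype(session.dtype)


def gen_session(
    spec: SessionSpec,
) -> tuple[AudioSignal, list[Annotation], float]:
    """Generate a whole session with planted apnea events.

    Returns ``(audio, annotations, true_ahi)`` where ``annotations``
    carries the exact time and label of every planted snore and
    ``true_ahi`` is planted apnea events divided by session hours.
    Events are Poisson-spaced with a 30 s minimum gap; each is a ~10 s
    quiet interval with one faint snore at its middle and one gasp just
    after it ends.
    """
    sr = TARGET_RATE
    duration_s = spec.hours * 3600.0
    rng = np.random.default_rng(spec.seed)
    n = int(round(duration_s * sr))
    session = (spec.noise_level * rng.standard_normal(n)).astype(np.float32)

    # --- apnea event times: exponential gaps with a hard minimum ---
    event_windows: list[tuple[float, float]] = []
    if spec.events_per_hour > 0:
        mean_gap = 3600.0 / spec.events_per_hour
        if mean_gap <= MIN_EVENT_GAP_S:
            raise ParameterError(
                f"events_per_hour={spec.events_per_hour} too dense for the "
                f"{MIN_EVENT_GAP_S:.0f} s minimum event gap"
            )
        t = MIN_EVENT_GAP_S + rng.exponential(mean_gap - MIN_EVENT_GAP_S)
        while t < duration_s - 20.0:
            event_windows.append((t, t + rng.uniform(9.0, 11.0)))
            t = event_windows[-1][1] + MIN_EVENT_GAP_S + rng.exponential(
                mean_gap - MIN_EVENT_GAP_S
            )

    annotations: list[Annotation] = []
    for start, end in event_windows:
        # faint snore at the event middle
        faint = _clip_kind_acoustics("abnormal_faint", rng)
        wave = _harmonic_burst_train(rng, faint, sr, single_burst=True)
        mid = 0.5 * (start + end) - faint.duration_s / 2
        _place_snippet(session, int(mid * sr), wave)
        annotations.append(
            Annotation(Event(mid, mid + faint.duration_s), "abnormal")
        )
        # gasp shortly after the event ends
        gasp = _clip_kind_acoustics("abnormal_gasp", rng)
        gasp_start = end + rng.uniform(0.5, 1.0)
        _place_snippet(session, int(gasp_start * sr), _gasp_burst(rng, gasp, sr))
        annotations.append(
            Annotation(Event(gasp_start, gasp_start + gasp.duration_s), "abnormal")
        )

    # --- normal snores outside events (with a 3 s guard band) ---
    def in_event(t0: float, t1: float) -> bool:
        return any(
            t1 > s - 3.0 and t0 < e + 3.0 for s, e in event_windows
        )

    if spec.normal_snore_rate > 0:
        mean_gap = 60.0 / spec.normal_snore_rate
        t = rng.exponential(mean_gap)
        last_end = -np.inf
        while t < duration_s - 3.0:
            acoustics = _clip_kind_acoustics("normal", rng)
            dur = acoustics.duration_s
            if not in_event(t, t + dur) and t - last_end > 1.0:
                _place_snippet(
                    session,
                    int(t * sr),
                    _harmonic_burst_train(rng, acoustics, sr, single_burst=True),
                )
                annotations.append(Annotation(Event(t, t + dur), "normal"))
                last_end = t + dur
            t += rng.exponential(mean_gap)

    annotations.sort(key=lambda a: a.event.start_s)
    np.clip(session, -1.0, 1.0, out=session)
    true_ahi = len(event_windows) / spec.hours
    return AudioSignal(samples=session, sample_rate=sr), annotations, true_ahi


class OracleClassifier:
    """A clip classifier that reads planted ground-truth labels.

    Used to validate the screening bookkeeping (event detection, clip
    extraction, AHI arithmetic) independently of any trained model: a
    clip is labelled by the planted annotation that best overlaps its
    source event.  Synthetic-validation aid only.
    """

    def __init__(self, annotations: list[Annotation]):
        self.annotations = annotations

    def predict_clip(self, clip: SnoreClip) -> tuple[int, float]:
        event = clip.source_event
        if event is None:
            raise ParameterError("oracle classification needs a source event")
        best, best_overlap = None, 0.0
        for ann in self.annotations:
            ov = ann.event.overlap_s(event)
            if ov > best_overlap:
                best, best_overlap = ann, ov
        if best is None:
            return 0, 0.0
        return (1, 1.0) if best.label == "abnormal" else (0, 0.0)
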