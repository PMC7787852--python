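"""Cepstral feature extraction: MFCC, LPCC and LPMFCC.

Three extractors share the preprocessing chain of :mod:`snorescreen.signal`
and each turns a 3 s clip into a 298 x 40 matrix:

* **MFCC** — per-frame power spectrum, mel-scale triangular filterbank,
  natural log, discrete cosine transform.  The mel scale
  ``mel(f) = 2595 log10(1 + f/700)`` mimics the ear's nonlinear
  frequency resolution.
* **LPCC** — an order-``p`` all-pole (linear predictive) model is fitted
  to each frame by the autocorrelation method (Levinson-Durbin), then
  converted to cepstral coefficients by the standard recursion.
* **LPMFCC** — the LPC coefficient vector itself is Fourier-transformed,
  squared, mel-filtered, logged and cosine-transformed: a mel cepstrum
  of the smoothed all-pole envelope rather than of the raw spectrum.

Coefficient indices run ``n = 1..L`` (the constant/energy term is
excluded), so MFCC coefficients are invariant to overall gain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from os import PathLike

import numpy as np

from .errors import (
    DegenerateFrameError,
    DimensionError,
    ParameterError,
)
from .signal import (
    AudioSignal,
    FrameMatrix,
    FrameParams,
    power_spectrum,
    preprocess,
)

FEATURE_KINDS = ("mfcc", "lpcc", "lpmfcc")


def hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    """Convert frequency in Hz to mel: ``2595 log10(1 + f/700)``."""
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    """Inverse of :func:`hz_to_mel`."""
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


@dataclass(frozen=True)
class FeatureConfig:
    """Knobs of the three extractors.

    ``n_mel_filters`` (M) and ``n_coeffs`` (L) are both 40 so that every
    extractor returns 298 x 40 matrices on 3 s clips.  ``lpc_order`` is
    the all-pole model order p; 12 is the standard choice for 16 kHz
    audio.  ``log_floor`` keeps the logarithm finite on empty bands.
    """

    n_mel_filters: int = 40
    n_coeffs: int = 40
    lpc_order: int = 12
    log_floor: float = 1e-10
    f_min: float = 0.0
    f_max: float | None = 8000.0

    def __post_init__(self) -> None:
        if self.n_mel_filters < 1:
            raise ParameterError("n_mel_filters must be >= 1")
        if self.n_coeffs < 1:
            raise ParameterError("n_coeffs must be >= 1")
        if self.lpc_order < 1:
            raise ParameterError("lpc_order must be >= 1")
        if self.log_floor <= 0:
            raise ParameterError("log_floor must be > 0")
        if self.n_coeffs > self.n_mel_filters:
            raise ParameterError(
                "n_coeffs must not exceed n_mel_filters for a mel-cepstral DCT"
            )


@dataclass(frozen=True)
class MelFilterbank:
    """A bank of M triangular filters on the mel scale.

    ``weights`` has shape ``(M, n_fft // 2 + 1)``; each row is a
    triangle with unit peak, centers equally spaced in mel between
    ``f_min`` and ``f_max``.
    """

    weights: np.ndarray
    centers_hz: np.ndarray
    n_fft: int
    sample_rate: int
    f_min: float
    f_max: float

    @property
    def n_filters(self) -> int:
        return self.weights.shape[0]


def build_mel_filterbank(
    config: FeatureConfig,
    sample_rate: int,
    n_fft: int,
) -> MelFilterbank:
    """Construct the triangular mel filterbank.

    Filter edges are M + 2 points equally spaced on the mel axis; filter
    m rises linearly from edge m to edge m+1 and falls to edge m+2.
    """
    f_max = config.f_max if config.f_max is not None else sample_rate / 2.0
    if config.f_min >= f_max:
        raise ParameterError("f_min must be below f_max")
    if f_max > sample_rate / 2.0 + 1e-9:
        raise ParameterError("f_max must not exceed the Nyquist frequency")
    m = config.n_mel_filters
    edges_mel = np.linspace(hz_to_mel(config.f_min), hz_to_mel(f_max), m + 2)
    edges_hz = np.asarray(mel_to_hz(edges_mel))
    n_bins = n_fft // 2 + 1
    bin_hz = np.arange(n_bins) * sample_rate / n_fft
    lower, center, upper = edges_hz[:-2], edges_hz[1:-1], edges_hz[2:]
    up = (bin_hz[None, :] - lower[:, None]) / (center - lower)[:, None]
    down = (upper[:, None] - bin_hz[None, :]) / (upper - center)[:, None]
    weights = np.clip(np.minimum(up, down), 0.0, None)
    return MelFilterbank(
        weights=weights,
        centers_hz=center,
        n_fft=n_fft,
        sample_rate=sample_rate,
        f_min=config.f_min,
        f_max=f_max,
    )


def log_mel_energies(
    power_spec: np.ndarray, fb: MelFilterbank, log_floor: float = 1e-10
) -> np.ndarray:
    """Log filterbank energies ``s(m) = ln(sum_k |Xa(k)|^2 H_m(k))``.

    Energies below ``log_floor`` are clamped to it so the log is finite.
    """
    power_spec = np.atleast_2d(power_spec)
    if power_spec.shape[1] != fb.weights.shape[1]:
        raise DimensionError(
            f"spectrum has {power_spec.shape[1]} bins but the filterbank "
            f"expects {fb.weights.shape[1]}"
        )
    energies = power_spec @ fb.weights.T
    return np.log(np.maximum(energies, log_floor))


def _dct_matrix(n_coeffs: int, n_filters: int) -> np.ndarray:
    """Cosine transform rows ``cos(pi n (m + 0.5) / M)`` for n = 1..L."""
    n = np.arange(1, n_coeffs + 1)[:, None]
    m = np.arange(n_filters)[None, :]
    return np.cos(np.pi * n * (m + 0.5) / n_filters)


@dataclass(frozen=True)
class FeatureMatrix:
    """Frames x coefficients array with its extraction provenance."""

    values: np.ndarray
    feature_kind: str
    frame_params: FrameParams

    def __post_init__(self) -> None:
        if self.feature_kind not in FEATURE_KINDS:
            raise ParameterError(f"unknown feature kind {self.feature_kind!r}")
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2:
            raise DimensionError("feature values must be 2-D (frames x coeffs)")
        if not np.all(np.isfinite(values)):
            raise DimensionError("feature values must be finite")
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def mfcc(
    signal: AudioSignal,
    frame_params: FrameParams | None = None,
    config: FeatureConfig | None = None,
) -> FeatureMatrix:
    """Mel-frequency cepstral coefficients of a clip.

    Full chain: pre-emphasis, framing, Hamming window, power spectrum,
    mel filterbank log energies, DCT rows n = 1..L.  A 3 s clip at
    16 kHz yields a 298 x 40 matrix with the defaults.
    """
    frame_params = frame_params or FrameParams()
    config = config or FeatureConfig()
    frames = preprocess(signal, frame_params)
    spec = power_spectrum(frames, frame_params.n_fft)
    fb = build_mel_filterbank(config, signal.sample_rate, frame_params.n_fft)
    s = log_mel_energies(spec, fb, config.log_floor)
    dct = _dct_matrix(config.n_coeffs, config.n_mel_filters)
    return FeatureMatrix(values=s @ dct.T, feature_kind="mfcc", frame_params=frame_params)


@dataclass(frozen=True)
class LPCModel:
    """An all-pole model ``V(z) = G / (1 - sum_k a_k z^-k)`` of one frame."""

    coeffs: np.ndarray  # a_1 .. a_p
    order: int
    gain: float
    prediction_error: float

    def __post_init__(self) -> None:
        coeffs = np.asarray(self.coeffs, dtype=np.float64)
        object.__setattr__(self, "coeffs", coeffs)
        if self.order < 1 or len(coeffs) != self.order:
            raise ParameterError("coefficient count must equal the model order")
        if self.prediction_error < 0:
            raise ParameterError("prediction_error must be nonnegative")

    def poles(self) -> np.ndarray:
        """Poles of the all-pole filter (roots of z^p - a1 z^{p-1} - ...)."""
        return np.roots(np.concatenate(([1.0], -self.coeffs)))


def lpc(frame: np.ndarray, order: int) -> LPCModel:
    """Fit an all-pole model to one frame by the autocorrelation method.

    Solves the Yule-Walker normal equations with the Levinson-Durbin
    recursion, which guarantees a minimum-phase (stable) filter.  The
    sign convention is the prediction form ``x[n] ~ sum_k a_k x[n-k]``,
    so an AR(1) process with coefficient 0.9 recovers ``a_1 ~ 0.9``.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 1:
        raise DimensionError("lpc expects a single 1-D frame")
    if order < 1:
        raise ParameterError("order must be >= 1")
    if order >= len(frame):
        raise ParameterError(
            f"order {order} must be smaller than the frame length {len(frame)}"
        )
    # autocorrelation r[0..p]
    r = np.array(
        [frame[: len(frame) - k] @ frame[k:] for k in range(order + 1)]
    )
    if r[0] <= 0.0 or not np.isfinite(r[0]):
        raise DegenerateFrameError("all-zero (or non-finite) frame has no LPC model")
    a = np.zeros(order + 1)
    err = r[0]
    for i in range(1, order + 1):
        k = (r[i] - a[1:i] @ r[1:i][::-1]) / err
        a_new = a.copy()
        a_new[i] = k
        a_new[1:i] = a[1:i] - k * a[1:i][::-1]
        a = a_new
        err *= 1.0 - k * k
        if err <= 0.0:  # numerically singular; clamp to keep the model usable
            err = np.finfo(np.float64).tiny
    return LPCModel(
        coeffs=a[1:], order=order, gain=float(np.sqrt(err)), prediction_error=float(err)
    )


def lpcc(lpc_model: LPCModel, n_coeffs: int) -> np.ndarray:
    """LPC-derived cepstral coefficients ``c(1) .. c(L)``.

    Recursion: ``c(1) = a(1)``; for ``1 < n <= p``,
    ``c(n) = a(n) + sum_{k=1}^{n-1} (1 - k/n) a_k c(n-k)``; for
    ``n > p``, ``c(n) = sum_{k=1}^{p} (1 - k/n) a_k c(n-k)``.
    """
    if n_coeffs < 1:
        raise ParameterError("n_coeffs must be >= 1")
    a = lpc_model.coeffs
    p = lpc_model.order
    c = np.zeros(n_coeffs + 1)  # c[0] unused; indices mirror the math
    for n in range(1, n_coeffs + 1):
        k = np.arange(1, min(n - 1, p) + 1)
        acc = np.sum((1.0 - k / n) * a[k - 1] * c[n - k]) if k.size else 0.0
        c[n] = acc + (a[n - 1] if n <= p else 0.0)
    return c[1:]


def _frame_lpc_rows(
    frames: FrameMatrix, order: int, fn, n_coeffs: int
) -> np.ndarray:
    """Apply an LPC-based per-frame transform, mapping degenerate
    (all-zero) frames to all-zero rows."""
    out = np.zeros((frames.n_frames, n_coeffs))
    for i, frame in enumerate(frames.frames):
        try:
            model = lpc(frame, order)
        except DegenerateFrameError:
            continue
        out[i] = fn(model)
    return out


def lpcc_features(
    signal: AudioSignal,
    frame_params: FrameParams | None = None,
    config: FeatureConfig | None = None,
) -> FeatureMatrix:
    """Per-frame LPCC matrix (same framing and shape as :func:`mfcc`)."""
    frame_params = frame_params or FrameParams()
    config = config or FeatureConfig()
    frames = preprocess(signal, frame_params)
    values = _frame_lpc_rows(
        frames,
        config.lpc_order,
        lambda model: lpcc(model, config.n_coeffs),
        config.n_coeffs,
    )
    return FeatureMatrix(values=values, feature_kind="lpcc", frame_params=frame_params)


def lpmfcc(
    signal: AudioSignal,
    frame_params: FrameParams | None = None,
    config: FeatureConfig | None = None,
) -> FeatureMatrix:
    """Mel cepstrum of the LPC coefficient spectrum.

    Per frame: the coefficient vector ``a_1..a_p`` is zero-padded to
    ``n_fft`` and Fourier-transformed; its squared magnitude is passed
    through the mel filterbank and natural log (``Za(m)``), then the
    same cosine transform as MFCC produces L coefficients.  Degenerate
    all-zero frames yield a flat zero spectrum, hence log-floor energies
    and (for n >= 1) zero coefficients.
    """
    frame_params = frame_params or FrameParams()
    config = config or FeatureConfig()
    frames = preprocess(signal, frame_params)
    fb = build_mel_filterbank(config, signal.sample_rate, frame_params.n_fft)
    dct = _dct_matrix(config.n_coeffs, config.n_mel_filters)
    floor_row = dct @ np.full(config.n_mel_filters, np.log(config.log_floor))

    def row(model: LPCModel) -> np.ndarray:
        spec = np.abs(np.fft.rfft(model.coeffs, n=frame_params.n_fft)) ** 2
        z = log_mel_energies(spec[None, :], fb, config.log_floor)[0]
        return dct @ z

    values = _frame_lpc_rows(frames, config.lpc_order, row, config.n_coeffs)
    # degenerate frames: a flat zero spectrum floors every band
    zero_rows = ~np.any(values, axis=1)
    values[zero_rows] = floor_row
    return FeatureMatrix(values=values, feature_kind="lpmfcc", frame_params=frame_params)


_EXTRACTORS = {"mfcc": mfcc, "lpcc": lpcc_features, "lpmfcc": lpmfcc}


def extract(
    signal: AudioSignal,
    feature_kind: str,
    frame_params: FrameParams | None = None,
    config: FeatureConfig | None = None,
) -> FeatureMatrix:
    """Dispatch to one of the three extractors by name."""
    try:
        fn = _EXTRACTORS[feature_kind]
    except KeyError:
        raise ParameterError(
            f"feature_kind must be one of {FEATURE_KINDS}, got {feature_kind!r}"
        ) from None
    return fn(signal, frame_params, config)


# ---------------------------------------------------------------------------
# Archive format: a .npz container with a JSON header, for moving feature
# sets between the extract / train / evaluate pipeline stages.

def save_feature_archive(
    path: str | PathLike,
    matrices: list[FeatureMatrix],
    labels: np.ndarray | list[int] | None = None,
) -> None:
    """Persist a homogeneous set of feature matrices (plus labels)."""
    if not matrices:
        raise ParameterError("cannot save an empty feature archive")
    kind = matrices[0].feature_kind
    fp = matrices[0].frame_params
    if any(m.feature_kind != kind or m.shape != matrices[0].shape for m in matrices):
        raise DimensionError("all matrices in an archive must share kind and shape")
    header = {
        "version": 1,
        "feature_kind": kind,
        "frame_params": {
            "frame_len_s": fp.frame_len_s,
            "shift_s": fp.shift_s,
            "preemph_alpha": fp.preemph_alpha,
            "n_fft": fp.n_fft,
        },
    }
    values = np.stack([m.values for m in matrices])
    arrays = {"values": values, "header": np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8)}
    if labels is not None:
        labels = np.asarray(labels, dtype=np.int64)
        if len(labels) != len(matrices):
            raise DimensionError("labels length must match the number of matrices")
        arrays["labels"] = labels
    np.savez(path, **arrays)


def load_feature_archive(
    path: str | PathLike,
) -> tuple[list[FeatureMatrix], np.ndarray | None]:
    """Inverse of :func:`save_feature_archive`."""
    with np.load(path) as data:
        header = json.loads(bytes(data["header"]).decode())
        values = data["values"]
        labels = data["labels"] if "labels" in data else None
    fp = FrameParams(**header["frame_params"])
    matrices = [
        FeatureMatrix(values=v, feature_kind=header["feature_kind"], frame_params=fp)
        for v in values
    ]
    return matrices, labels
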