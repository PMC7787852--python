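"""Shared fixtures and independently-coded oracle implementations.

The oracles here deliberately re-derive each quantity through a
different code path (direct DFT matrices, plain-Python recursions,
linear solves) so that agreement with the package is informative.
"""

import numpy as np
import pytest

import snorescreen as ss

SR = 16000


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture(scope="session")
def short_two_tone():
    """A 0.5 s two-tone test signal (sum of 250 Hz and 1200 Hz)."""
    t = np.arange(int(0.5 * SR)) / SR
    x = 0.5 * np.sin(2 * np.pi * 250 * t) + 0.3 * np.sin(2 * np.pi * 1200 * t)
    return ss.AudioSignal(samples=x, sample_rate=SR)


@pytest.fixture(scope="session")
def three_second_clip():
    return ss.gen_snore_clip("normal", seed=7)


# ---------------------------------------------------------------------------
# independent oracle implementations


def oracle_preprocess(x: np.ndarray, alpha=0.97, flen=480, shift=160):
    """Pre-emphasis + framing + Hamming, coded directly."""
    y = np.append(x[0], x[1:] - alpha * x[:-1])
    n_frames = 1 + (len(y) - flen) // shift
    w = 0.54 - 0.46 * np.cos(2 * np.pi * np.arange(flen) / (flen - 1))
    return np.stack([y[i * shift: i * shift + flen] * w for i in range(n_frames)])


def oracle_mel_filterbank(n_filters=40, n_fft=512, sr=SR, f_min=0.0, f_max=8000.0):
    """Triangular mel filterbank built point-by-point."""
    def mel(f):
        return 2595.0 * np.log10(1.0 + f / 700.0)

    def imel(m):
        return 700.0 * (10.0 ** (m / 2595.0) - 1.0)

    edges = imel(np.linspace(mel(f_min), mel(f_max), n_filters + 2))
    bins = np.arange(n_fft // 2 + 1) * sr / n_fft
    H = np.zeros((n_filters, len(bins)))
    for m in range(n_filters):
        lo, c, hi = edges[m], edges[m + 1], edges[m + 2]
        for k, f in enumerate(bins):
            if lo <= f <= c:
                H[m, k] = (f - lo) / (c - lo)
            elif c < f <= hi:
                H[m, k] = (hi - f) / (hi - c)
    return H


def oracle_mfcc(x: np.ndarray, n_filters=40, n_coeffs=40, n_fft=512, floor=1e-10):
    """MFCC via an explicit DFT matrix and explicit cosine sums."""
    frames = oracle_preprocess(x)
    k = np.arange(n_fft // 2 + 1)
    n = np.arange(frames.shape[1])
    dft = np.exp(-2j * np.pi * np.outer(k, n) / n_fft)
    P = np.abs(frames @ dft.T) ** 2
    H = oracle_mel_filterbank(n_filters, n_fft)
    E = np.log(np.maximum(P @ H.T, floor))
    C = np.zeros((len(frames), n_coeffs))
    m = np.arange(n_filters)
    for j in range(1, n_coeffs + 1):
        C[:, j - 1] = np.sum(E * np.cos(np.pi * j * (m + 0.5) / n_filters), axis=1)
    return C


def oracle_lpc(frame: np.ndarray, order: int) -> np.ndarray:
    """LPC via a dense Toeplitz solve of the normal equations."""
    from scipy.linalg import toeplitz

    r = np.array([frame[: len(frame) - k] @ frame[k:] for k in range(order + 1)])
    return np.linalg.solve(toeplitz(r[:-1]), r[1:])


def oracle_lpcc(a: np.ndarray, n_coeffs: int) -> np.ndarray:
    """Cepstral recursion in plain Python loops."""
    p = len(a)
    c = [0.0] * (n_coeffs + 1)
    for n in range(1, n_coeffs + 1):
        total = 0.0
        for k in range(1, min(n - 1, p) + 1):
            total += (1.0 - k / n) * a[k - 1] * c[n - k]
        if n <= p:
            total += a[n - 1]
        c[n] = total
    return np.array(c[1:])


def oracle_lstm_cell(x, h_prev, c_prev, W_f, W_i, W_c, W_o, b_f, b_i, b_c, b_o):
    """Scalar-loop evaluation of the LSTM gate equations."""
    import math

    H = len(h_prev)
    z = list(h_prev) + list(x)

    def mat(W, b):
        return [sum(W[i][j] * z[j] for j in range(len(z))) + b[i] for i in range(H)]

    sig = lambda v: 1.0 / (1.0 + math.exp(-v))
    f = [sig(v) for v in mat(W_f, b_f)]
    i = [sig(v) for v in mat(W_i, b_i)]
    g = [math.tanh(v) for v in mat(W_c, b_c)]
    o = [sig(v) for v in mat(W_o, b_o)]
    c = [f[j] * c_prev[j] + i[j] * g[j] for j in range(H)]
    h = [o[j] * math.tanh(c[j]) for j in range(H)]
    return np.array(h), np.array(c)


def random_stable_lpc_model(rng, order: int) -> ss.LPCModel:
    """A random minimum-phase LPC model built from reflection
    coefficients in (-0.95, 0.95) via the step-up recursion."""
    ks = rng.uniform(-0.95, 0.95, size=order)
    a = np.zeros(order + 1)
    for i, k in enumerate(ks, start=1):
        a_new = a.copy()
        a_new[i] = k
        a_new[1:i] = a[1:i] - k * a[1:i][::-1]
        a = a_new
    return ss.LPCModel(coeffs=a[1:], order=order, gain=1.0, prediction_error=1.0)
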