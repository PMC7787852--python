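"""Binary snore classifiers: 3-layer CNN, 5-layer CNN and a 298-step LSTM.

The networks are implemented directly in numpy (im2col convolution,
backpropagation through time, Adam) so the package has no deep-learning
framework dependency.  Architectures:

* ``cnn3`` — three conv blocks (20x8/64/stride 2, 10x4/64/stride 2,
  5x2/64/stride 1), each followed by a ReLU and a 2x2 max-pool, then a
  fully connected map to the two class logits.
* ``cnn5`` — the same three blocks plus two 2x2/64/stride 1 blocks.
* ``lstm`` — one recurrent layer applied to the 298 feature frames of a
  clip (one LSTM step per frame); the final hidden state feeds the
  fully connected output map.

The LSTM cell follows the standard gate equations: with
``z = [h_{t-1}, x_t]``,

    f_t = sigma(W_f z + b_f)        (forget gate)
    i_t = sigma(W_i z + b_i)        (input gate)
    C'_t = tanh(W_c z + b_c)        (candidate state)
    C_t = f_t * C_{t-1} + i_t * C'_t
    O_t = sigma(W_o z + b_o)        (output gate)
    h_t = O_t * tanh(C_t)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from os import PathLike
from typing import Sequence

import numpy as np
from scipy.special import expit

from .errors import ConfigError, DataError, DimensionError, ParameterError
from .features import FeatureMatrix

ARCHITECTURES = ("cnn3", "cnn5", "lstm")
CLASS_NAMES = ("normal", "abnormal")

#: Conv blocks as (filter_h, filter_w, n_filters, stride, pool).
CNN3_BLOCKS = ((20, 8, 64, 2, 2), (10, 4, 64, 2, 2), (5, 2, 64, 1, 2))
CNN5_BLOCKS = CNN3_BLOCKS + ((2, 2, 64, 1, 2), (2, 2, 64, 1, 2))

_GRAD_CLIP = 5.0


# ---------------------------------------------------------------------------
# configs


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``conv_blocks`` defaults to the fixed per-architecture tables above;
    supplying a different stack for ``cnn3``/``cnn5`` is a config error.
    """

    architecture: str
    conv_blocks: tuple = None  # type: ignore[assignment]
    lstm_hidden: int = 128
    n_classes: int = 2
    input_shape: tuple[int, int] = (298, 40)

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ConfigError(
                f"architecture must be one of {ARCHITECTURES}, "
                f"got {self.architecture!r}"
            )
        expected = {"cnn3": CNN3_BLOCKS, "cnn5": CNN5_BLOCKS, "lstm": ()}[
            self.architecture
        ]
        if self.conv_blocks is None:
            object.__setattr__(self, "conv_blocks", expected)
        elif tuple(map(tuple, self.conv_blocks)) != expected:
            raise ConfigError(
                f"{self.architecture} requires conv blocks {expected}, "
                f"got {self.conv_blocks}"
            )
        if self.n_classes != 2:
            raise ConfigError("the classifier is binary (n_classes must be 2)")
        if self.architecture == "lstm" and self.lstm_hidden < 1:
            raise ConfigError("lstm_hidden must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings; ``seed`` fixes init and shuffling."""

    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    validation_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ParameterError("epochs, batch_size, learning_rate must be positive")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ParameterError("validation_fraction must be in [0, 1)")


# ---------------------------------------------------------------------------
# the LSTM cell primitive


@dataclass(frozen=True)
class LSTMCellWeights:
    """Per-gate weights of one LSTM cell.

    Each matrix multiplies the concatenation ``[h_{t-1}, x_t]`` and has
    shape ``(hidden_size, hidden_size + input_size)``.
    """

    W_f: np.ndarray
    W_i: np.ndarray
    W_c: np.ndarray
    W_o: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_c: np.ndarray
    b_o: np.ndarray

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.W_f, self.W_i, self.W_c, self.W_o)}
        if len(shapes) != 1:
            raise DimensionError("all four gate matrices must share one shape")
        h = self.W_f.shape[0]
        for b in (self.b_f, self.b_i, self.b_c, self.b_o):
            if b.shape != (h,):
                raise DimensionError("bias length must equal hidden_size")

    @property
    def hidden_size(self) -> int:
        return self.W_f.shape[0]

    @property
    def input_size(self) -> int:
        return self.W_f.shape[1] - self.W_f.shape[0]


def lstm_cell_step(
    x_t: np.ndarray,
    h_prev: np.ndarray,
    c_prev: np.ndarray,
    weights: LSTMCellWeights,
) -> tuple[np.ndarray, np.ndarray]:
    """One forward step of the LSTM cell (gate equations above)."""
    if x_t.shape != (weights.input_size,):
        raise DimensionError(
            f"x_t must have length {weights.input_size}, got {x_t.shape}"
        )
    if h_prev.shape != (weights.hidden_size,) or c_prev.shape != (weights.hidden_size,):
        raise DimensionError("h_prev and c_prev must have length hidden_size")
    z = np.concatenate([h_prev, x_t])
    f = expit(weights.W_f @ z + weights.b_f)
    i = expit(weights.W_i @ z + weights.b_i)
    c_tilde = np.tanh(weights.W_c @ z + weights.b_c)
    c_t = f * c_prev + i * c_tilde
    o = expit(weights.W_o @ z + weights.b_o)
    h_t = o * np.tanh(c_t)
    return h_t, c_t


# ---------------------------------------------------------------------------
# internal layers (float32 training arithmetic)


def _softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def _ce_loss_and_dlogits(logits, y):
    probs = _softmax(logits)
    n = len(y)
    loss = -np.log(np.maximum(probs[np.arange(n), y], 1e-30)).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), y] -= 1.0
    return float(loss), dlogits / n


def _same_pad(size: int, k: int, stride: int) -> tuple[int, int, int]:
    """'same' padding: output ceil(size/stride); returns (out, before, after)."""
    out = -(-size // stride)
    total = max((out - 1) * stride + k - size, 0)
    return out, total // 2, total - total // 2


class _LSTMNetwork:
    """Packed-weight LSTM + linear head, with BPTT."""

    def __init__(self, input_size: int, hidden: int, n_classes: int, rng):
        self.input_size, self.hidden = input_size, hidden
        s = 1.0 / np.sqrt(hidden + input_size)
        self.params = {
            # gate order: f, i, c, o
            "W": rng.uniform(-s, s, (hidden + input_size, 4 * hidden)).astype(
                np.float32
            ),
            "b": np.zeros(4 * hidden, dtype=np.float32),
            "W_out": (rng.standard_normal((hidden, n_classes))
                      * np.sqrt(2.0 / hidden)).astype(np.float32),
            "b_out": np.zeros(n_classes, dtype=np.float32),
        }
        # forget-gate bias init 3.0: sigma(3) ~ 0.95 per-step retention, so
        # early-sequence evidence survives to the final-state readout even
        # before the gates are learned
        self.params["b"][:hidden] = 3.0

    def forward(self, X: np.ndarray, want_cache: bool = False):
        B, T, D = X.shape
        H = self.hidden
        W, b = self.params["W"], self.params["b"]
        h = np.zeros((B, H), dtype=np.float32)
        c = np.zeros((B, H), dtype=np.float32)
        cache = []
        for t in range(T):
            z = np.concatenate([h, X[:, t, :]], axis=1)
            a = z @ W + b
            f = expit(a[:, :H])
            i = expit(a[:, H: 2 * H])
            g = np.tanh(a[:, 2 * H: 3 * H])
            o = expit(a[:, 3 * H:])
            c_new = f * c + i * g
            h = o * np.tanh(c_new)
            if want_cache:
                cache.append((z, f, i, g, o, c, c_new))
            c = c_new
        logits = h @ self.params["W_out"] + self.params["b_out"]
        return (logits, h, cache) if want_cache else logits

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray):
        H = self.hidden
        W = self.params["W"]
        logits, h_T, cache = self.forward(X, want_cache=True)
        loss, dlogits = _ce_loss_and_dlogits(logits, y)
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        grads["W_out"] = h_T.T @ dlogits
        grads["b_out"] = dlogits.sum(axis=0)
        dh = (dlogits @ self.params["W_out"].T).astype(np.float32)
        dc = np.zeros_like(dh)
        for z, f, i, g, o, c_prev, c_t in reversed(cache):
            tc = np.tanh(c_t)
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            df = dc * c_prev
            di = dc * g
            dg = dc * i
            dc_prev = dc * f
            da = np.concatenate(
                [
                    df * f * (1.0 - f),
                    di * i * (1.0 - i),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            grads["W"] += z.T @ da
            grads["b"] += da.sum(axis=0)
            dz = da @ W.T
            dh = dz[:, :H]
            dc = dc_prev
        return loss, logits, grads


class _CNNNetwork:
    """Conv/ReLU/max-pool stack + linear head, via im2col."""

    def __init__(self, input_shape, blocks, n_classes, rng):
        self.blocks = blocks
        self.input_shape = input_shape
        self.params = {}
        h, w, ch = input_shape[0], input_shape[1], 1
        for idx, (kh, kw, nf, stride, pool) in enumerate(blocks):
            fan_in = kh * kw * ch
            self.params[f"conv{idx}_W"] = (
                rng.standard_normal((fan_in, nf)) * np.sqrt(2.0 / fan_in)
            ).astype(np.float32)
            self.params[f"conv{idx}_b"] = np.zeros(nf, dtype=np.float32)
            h = -(-h // stride)
            w = -(-w // stride)
            h = -(-h // pool)
            w = -(-w // pool)
            ch = nf
        self.flat = h * w * ch
        self.params["fc_W"] = (
            rng.standard_normal((self.flat, n_classes)) * np.sqrt(2.0 / self.flat)
        ).astype(np.float32)
        self.params["fc_b"] = np.zeros(n_classes, dtype=np.float32)

    @staticmethod
    def _conv_forward(x, Wmat, b, kh, kw, stride):
        B, H, Wd, C = x.shape
        oh, ph0, ph1 = _same_pad(H, kh, stride)
        ow, pw0, pw1 = _same_pad(Wd, kw, stride)
        xp = np.pad(x, ((0, 0), (ph0, ph1), (pw0, pw1), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
        win = win[:, ::stride, ::stride]  # (B, oh, ow, C, kh, kw)
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(B, oh, ow, kh * kw * C)
        out = cols @ Wmat + b
        return out, (cols, xp.shape, (ph0, pw0), (B, H, Wd, C))

    @staticmethod
    def _conv_backward(dout, Wmat, cache, kh, kw, stride):
        cols, xp_shape, (ph0, pw0), (B, H, Wd, C) = cache
        oh, ow = dout.shape[1:3]
        dW = cols.reshape(-1, cols.shape[-1]).T @ dout.reshape(-1, dout.shape[-1])
        db = dout.sum(axis=(0, 1, 2))
        dcols = (dout @ Wmat.T).reshape(B, oh, ow, kh, kw, C)
        dxp = np.zeros(xp_shape, dtype=np.float32)
        for i in range(kh):
            for j in range(kw):
                dxp[:, i: i + stride * oh: stride, j: j + stride * ow: stride, :] += (
                    dcols[:, :, :, i, j, :]
                )
        dx = dxp[:, ph0: ph0 + H, pw0: pw0 + Wd, :]
        return dx, dW, db

    @staticmethod
    def _pool_forward(x, pool):
        B, H, W, C = x.shape
        oh, ph0, ph1 = _same_pad(H, pool, pool)
        ow, pw0, pw1 = _same_pad(W, pool, pool)
        xp = np.pad(
            x, ((0, 0), (ph0, ph1), (pw0, pw1), (0, 0)), constant_values=-np.inf
        )
        xr = xp.reshape(B, oh, pool, ow, pool, C)
        out = xr.max(axis=(2, 4))
        mask = xr == out[:, :, None, :, None, :]
        return out, (mask, xp.shape, (ph0, pw0), (H, W))

    @staticmethod
    def _pool_backward(dout, cache, pool):
        mask, xp_shape, (ph0, pw0), (H, W) = cache
        B, oh, _, ow, _, C = mask.shape
        dxr = mask * dout[:, :, None, :, None, :]
        dxp = dxr.reshape(xp_shape)
        return dxp[:, ph0: ph0 + H, pw0: pw0 + W, :]

    def forward(self, X: np.ndarray, want_cache: bool = False):
        a = X[..., None].astype(np.float32)
        caches = []
        for idx, (kh, kw, nf, stride, pool) in enumerate(self.blocks):
            z, conv_cache = self._conv_forward(
                a, self.params[f"conv{idx}_W"], self.params[f"conv{idx}_b"],
                kh, kw, stride,
            )
            r = np.maximum(z, 0.0)
            p, pool_cache = self._pool_forward(r, pool)
            caches.append((conv_cache, z, pool_cache))
            a = p
        flat = a.reshape(len(X), -1)
        logits = flat @ self.params["fc_W"] + self.params["fc_b"]
        if want_cache:
            return logits, (caches, flat, a.shape)
        return logits

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray):
        logits, (caches, flat, last_shape) = self.forward(X, want_cache=True)
        loss, dlogits = _ce_loss_and_dlogits(logits, y)
        grads = {}
        grads["fc_W"] = flat.T @ dlogits
        grads["fc_b"] = dlogits.sum(axis=0)
        da = (dlogits @ self.params["fc_W"].T).reshape(last_shape).astype(np.float32)
        for idx in range(len(self.blocks) - 1, -1, -1):
            kh, kw, nf, stride, pool = self.blocks[idx]
            conv_cache, z, pool_cache = caches[idx]
            dr = self._pool_backward(da, pool_cache, pool)
            dz = dr * (z > 0.0)
            da, dW, db = self._conv_backward(
                dz, self.params[f"conv{idx}_W"], conv_cache, kh, kw, stride
            )
            grads[f"conv{idx}_W"] = dW
            grads[f"conv{idx}_b"] = db
        da = da[..., 0]  # drop the channel axis of the input
        return loss, logits, grads


def _build_network(config: ModelConfig, rng) -> _LSTMNetwork | _CNNNetwork:
    if config.architecture == "lstm":
        return _LSTMNetwork(
            config.input_shape[1], config.lstm_hidden, config.n_classes, rng
        )
    return _CNNNetwork(config.input_shape, config.conv_blocks, config.n_classes, rng)


# ---------------------------------------------------------------------------
# training


@dataclass
class UntrainedModel:
    """A validated architecture awaiting :func:`train`."""

    config: ModelConfig


@dataclass
class TrainedModel:
    """A fitted classifier plus its input-normalisation statistics.

    ``normalization`` (per-coefficient mean and std, fitted on the
    training split only) is stored with the model and applied
    identically at inference.
    """

    config: ModelConfig
    network: object
    norm_mean: np.ndarray
    norm_std: np.ndarray
    history: list = field(default_factory=list)
    feature_kind: str | None = None


def build_model(config: ModelConfig) -> UntrainedModel:
    """Validate a config and return an untrained model handle."""
    return UntrainedModel(config=config)


def _as_array(features) -> np.ndarray:
    if isinstance(features, np.ndarray):
        X = features
    else:
        X = np.stack(
            [f.values if isinstance(f, FeatureMatrix) else np.asarray(f)
             for f in features]
        )
    if X.ndim != 3:
        raise DimensionError("features must stack to (n, n_frames, n_coeffs)")
    return X.astype(np.float32)


def _clip_gradients(grads: dict, max_norm: float) -> None:
    total = np.sqrt(sum(float(np.sum(g.astype(np.float64) ** 2))
                        for g in grads.values()))
    if total > max_norm:
        scale = np.float32(max_norm / (total + 1e-12))
        for g in grads.values():
            g *= scale


def train(
    model: UntrainedModel,
    features: Sequence[FeatureMatrix] | np.ndarray,
    labels: Sequence[int] | np.ndarray,
    cfg: TrainConfig | None = None,
    feature_kind: str | None = None,
) -> TrainedModel:
    """Fit a classifier by minimising cross-entropy with Adam.

    Raises :class:`DataError` on a single-class or too-small training
    set.  With a fixed ``cfg.seed``, initialisation and shuffling (and
    hence the final weights) are reproducible on one platform.
    """
    cfg = cfg or TrainConfig()
    X = _as_array(features)
    y = np.asarray(labels, dtype=np.int64)
    if len(X) != len(y):
        raise DimensionError("features and labels must have equal length")
    counts = np.bincount(y, minlength=2)
    if np.count_nonzero(counts) < 2:
        raise DataError("training set must contain both classes")
    if counts.min() < 2:
        raise DataError("need at least 2 examples per class")
    if X.shape[1:] != tuple(model.config.input_shape):
        raise DimensionError(
            f"features of shape {X.shape[1:]} do not match the model input "
            f"shape {model.config.input_shape}"
        )
    if isinstance(features, Sequence) and features and isinstance(
        features[0], FeatureMatrix
    ):
        feature_kind = feature_kind or features[0].feature_kind

    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(X))
    n_val = int(round(cfg.validation_fraction * len(X)))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    if np.count_nonzero(np.bincount(y[tr_idx], minlength=2)) < 2:
        raise DataError("training split lost a class; lower validation_fraction")

    mean = X[tr_idx].mean(axis=(0, 1))
    std = X[tr_idx].std(axis=(0, 1))
    std = np.maximum(std, 1e-8)
    Xn = (X - mean) / std

    net = _build_network(model.config, rng)
    adam_m = {k: np.zeros_like(v) for k, v in net.params.items()}
    adam_v = {k: np.zeros_like(v) for k, v in net.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    history = []
    for epoch in range(cfg.epochs):
        perm = tr_idx[rng.permutation(len(tr_idx))]
        epoch_loss, epoch_correct, seen = 0.0, 0, 0
        for start in range(0, len(perm), cfg.batch_size):
            batch = perm[start: start + cfg.batch_size]
            loss, logits, grads = net.loss_and_grads(Xn[batch], y[batch])
            _clip_gradients(grads, _GRAD_CLIP)
            step += 1
            lr_t = cfg.learning_rate * np.sqrt(1 - beta2**step) / (1 - beta1**step)
            for k, g in grads.items():
                adam_m[k] = beta1 * adam_m[k] + (1 - beta1) * g
                adam_v[k] = beta2 * adam_v[k] + (1 - beta2) * g * g
                net.params[k] -= (lr_t * adam_m[k] /
                                  (np.sqrt(adam_v[k]) + eps)).astype(np.float32)
            epoch_loss += loss * len(batch)
            epoch_correct += int(np.sum(np.argmax(logits, axis=1) == y[batch]))
            seen += len(batch)
        record = {
            "epoch": epoch,
            "train_loss": epoch_loss / seen,
            "train_acc": epoch_correct / seen,
        }
        if n_val:
            val_logits = _forward_in_batches(net, Xn[val_idx], cfg.batch_size)
            val_loss, _ = _ce_loss_and_dlogits(val_logits, y[val_idx])
            record["val_loss"] = val_loss
            record["val_acc"] = float(
                np.mean(np.argmax(val_logits, axis=1) == y[val_idx])
            )
        history.append(record)
    return TrainedModel(
        config=model.config,
        network=net,
        norm_mean=mean,
        norm_std=std,
        history=history,
        feature_kind=feature_kind,
    )


def _forward_in_batches(net, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
    out = [net.forward(X[i: i + batch_size]) for i in range(0, len(X), batch_size)]
    return np.concatenate(out, axis=0)


def predict_proba(
    model: TrainedModel, features: Sequence[FeatureMatrix] | np.ndarray
) -> np.ndarray:
    """Class probabilities, shape ``(n, 2)``; column 1 is "abnormal"."""
    X = _as_array(features)
    if X.shape[1:] != tuple(model.config.input_shape):
        raise DimensionError(
            f"features of shape {X.shape[1:]} do not match the model input "
            f"shape {model.config.input_shape}"
        )
    Xn = (X - model.norm_mean) / model.norm_std
    return _softmax(_forward_in_batches(model.network, Xn))


def predict(
    model: TrainedModel, features: FeatureMatrix | np.ndarray
) -> tuple[int, float]:
    """Classify one clip: returns ``(label, p_abnormal)``.

    ``label`` is 0 (normal) or 1 (abnormal), the argmax of the class
    probabilities.
    """
    values = features.values if isinstance(features, FeatureMatrix) else features
    probs = predict_proba(model, np.asarray(values)[None, ...])
    return int(np.argmax(probs[0])), float(probs[0, 1])


# ---------------------------------------------------------------------------
# persistence


def save_model(path: str | PathLike, model: TrainedModel) -> None:
    """Write a checkpoint (config + weights + normalisation + history)."""
    meta = {
        "config": {
            "architecture": model.config.architecture,
            "lstm_hidden": model.config.lstm_hidden,
            "n_classes": model.config.n_classes,
            "input_shape": list(model.config.input_shape),
        },
        "history": model.history,
        "feature_kind": model.feature_kind,
    }
    arrays = {f"param_{k}": v for k, v in model.network.params.items()}
    arrays["norm_mean"] = model.norm_mean
    arrays["norm_std"] = model.norm_std
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path: str | PathLike) -> TrainedModel:
    """Read a checkpoint written by :func:`save_model`."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        config = ModelConfig(
            architecture=meta["config"]["architecture"],
            lstm_hidden=meta["config"]["lstm_hidden"],
            n_classes=meta["config"]["n_classes"],
            input_shape=tuple(meta["config"]["input_shape"]),
        )
        net = _build_network(config, np.random.default_rng(0))
        for k in net.params:
            net.params[k] = data[f"param_{k}"]
        return TrainedModel(
            config=config,
            network=net,
            norm_mean=data["norm_mean"],
            norm_std=data["norm_std"],
            history=meta["history"],
            feature_kind=meta["feature_kind"],
        )
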