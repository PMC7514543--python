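"""Shallow CNN with full-height 1D kernels for two-class MI decoding.

Architecture: the input image (Nv x Nt) is correlated at stride 1 with
NF kernels of shape Nv x kernel_time_width -- each kernel spans the whole
frequency/electrode axis and slides only along time -- giving NF feature
maps of length Nt - kernel_time_width + 1; ReLU; non-overlapping
max-pooling by ``pool_factor`` (trailing remainder dropped, no padding);
the pooled maps are flattened and mapped by one fully connected layer to
two logits, softmax-ed to class probabilities.  At the default geometry:
93 x 32 -> 30 maps x 30 -> 30 x 3 -> 90 features -> 2 logits.

Training is plain mini-batch gradient descent on softmax cross-entropy
with analytically derived gradients (validated against central finite
differences in the test suite).  All randomness -- weight initialization
and per-epoch batch shuffling -- is seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from wavemi.synthetic import LABELS

#: class index convention: left -> 0, right -> 1
CLASS_TO_INDEX = {label: i for i, label in enumerate(LABELS)}


@dataclass(frozen=True)
class CNNConfig:
    """Hyperparameters; defaults follow the reference architecture."""

    n_kernels: int = 30
    kernel_time_width: int = 3
    pool_factor: int = 10
    stride: int = 1
    batch_size: int = 50
    epochs: int = 300
    learning_rate: float = 0.01
    seed: int = 0
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.stride != 1:
            raise ValueError("only stride 1 is supported")
        for name in ("n_kernels", "kernel_time_width", "pool_factor",
                     "batch_size", "epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def pooled_len(self, nt: int) -> int:
        conv_len = nt - self.kernel_time_width + 1
        if conv_len < self.pool_factor:
            raise ValueError(
                f"conv output length {conv_len} is shorter than the "
                f"pool factor {self.pool_factor}"
            )
        return conv_len // self.pool_factor


@dataclass
class CNNModel:
    """Kernel, bias and fully-connected weights plus their configuration."""

    conv_w: np.ndarray  # (NF, Nv, kw)
    conv_b: np.ndarray  # (NF,)
    fc_w: np.ndarray    # (NF * pooled_len, n_classes)
    fc_b: np.ndarray    # (n_classes,)
    config: CNNConfig

    def __post_init__(self) -> None:
        nf = self.config.n_kernels
        if self.conv_w.shape[0] != nf or self.conv_b.shape != (nf,):
            raise ValueError("conv weight shapes inconsistent with config")
        if self.fc_w.shape[1] != self.config.n_classes \
                or self.fc_b.shape != (self.config.n_classes,):
            raise ValueError("fc weight shapes inconsistent with config")
        for arr in (self.conv_w, self.conv_b, self.fc_w, self.fc_b):
            if not np.all(np.isfinite(arr)):
                raise ValueError("model weights must be finite")

    @classmethod
    def initialize(cls, nv: int, nt: int, config: CNNConfig) -> "CNNModel":
        """Seeded zero-mean uniform init scaled by 1/sqrt(fan-in)."""
        rng = np.random.default_rng(config.seed)
        pooled = config.pooled_len(nt)
        conv_fan = nv * config.kernel_time_width
        fc_fan = config.n_kernels * pooled
        conv_w = rng.uniform(-1, 1, (config.n_kernels, nv,
                                     config.kernel_time_width)) / np.sqrt(conv_fan)
        fc_w = rng.uniform(-1, 1, (fc_fan, config.n_classes)) / np.sqrt(fc_fan)
        return cls(conv_w, np.zeros(config.n_kernels), fc_w,
                   np.zeros(config.n_classes), config)


def relu(a: np.ndarray) -> np.ndarray:
    """max(a, 0), elementwise."""
    return np.maximum(a, 0)


def conv_forward(img: np.ndarray, model: CNNModel) -> np.ndarray:
    """Feature maps for one image: valid correlation + bias + ReLU.

    Returns an (NF, Nt - kw + 1) array.
    """
    maps, _ = _conv_batch(np.asarray(img, dtype=float)[None], model)
    return maps[0]


def _conv_batch(x: np.ndarray, model: CNNModel) -> tuple[np.ndarray, np.ndarray]:
    """ReLU-ed feature maps and pre-activations for a (B, Nv, Nt) batch."""
    kw = model.config.kernel_time_width
    if x.ndim != 3 or x.shape[1] != model.conv_w.shape[1]:
        raise ValueError(
            f"batch shape {x.shape} does not match kernel height "
            f"{model.conv_w.shape[1]}"
        )
    windows = sliding_window_view(x, kw, axis=2)  # (B, Nv, L, kw)
    pre = np.einsum("bvlw,kvw->bkl", windows, model.conv_w, optimize=True)
    pre += model.conv_b[None, :, None]
    return relu(pre), pre


def maxpool(maps: np.ndarray, pool_factor: int) -> np.ndarray:
    """Non-overlapping max over windows of ``pool_factor``; remainder dropped."""
    length = maps.shape[-1]
    if length < pool_factor:
        raise ValueError(f"map length {length} < pool factor {pool_factor}")
    n_out = length // pool_factor
    trimmed = maps[..., : n_out * pool_factor]
    return trimmed.reshape(*maps.shape[:-1], n_out, pool_factor).max(axis=-1)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _forward_batch(x: np.ndarray, model: CNNModel) -> dict:
    """Forward pass with the intermediates backprop needs."""
    cfg = model.config
    h, pre = _conv_batch(x, model)
    b, nf, length = h.shape
    n_out = length // cfg.pool_factor
    trimmed = h[..., : n_out * cfg.pool_factor].reshape(b, nf, n_out, cfg.pool_factor)
    pooled = trimmed.max(axis=-1)
    argmax = trimmed.argmax(axis=-1)
    flat = pooled.reshape(b, -1)
    logits = flat @ model.fc_w + model.fc_b
    probs = _softmax(logits)
    return {"pre": pre, "pooled_arg": argmax, "flat": flat, "probs": probs,
            "n_out": n_out}


def forward(img: np.ndarray, model: CNNModel) -> np.ndarray:
    """Class probabilities (summing to 1) for one image or a batch."""
    x = np.asarray(img, dtype=float)
    single = x.ndim == 2
    probs = _forward_batch(x[None] if single else x, model)["probs"]
    return probs[0] if single else probs


def _loss_and_gradients(
    x: np.ndarray, y: np.ndarray, model: CNNModel
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean cross-entropy and its gradients w.r.t. all weights.

    Backprop chain: dlogits = (probs - onehot)/B; the fc layer is affine;
    pooled gradients scatter to the per-window argmax positions; ReLU
    gates on the sign of the pre-activation; the kernel gradient is the
    correlation of the input windows with the map gradient.
    """
    cfg = model.config
    cache = _forward_batch(x, model)
    b = x.shape[0]
    probs = cache["probs"]
    loss = float(-np.log(probs[np.arange(b), y] + 1e-300).mean())

    dlogits = probs.copy()
    dlogits[np.arange(b), y] -= 1.0
    dlogits /= b

    grads = {
        "fc_w": cache["flat"].T @ dlogits,
        "fc_b": dlogits.sum(axis=0),
    }

    dflat = dlogits @ model.fc_w.T
    nf, n_out, pf = cfg.n_kernels, cache["n_out"], cfg.pool_factor
    dpooled = dflat.reshape(b, nf, n_out)

    dh = np.zeros_like(cache["pre"])
    window_start = np.arange(n_out) * pf
    positions = window_start[None, None, :] + cache["pooled_arg"]  # (B, NF, n_out)
    bi, ki = np.meshgrid(np.arange(b), np.arange(nf), indexing="ij")
    dh[bi[..., None], ki[..., None], positions] = dpooled

    da = dh * (cache["pre"] > 0)
    windows = sliding_window_view(x, cfg.kernel_time_width, axis=2)
    grads["conv_w"] = np.einsum("bkl,bvlw->kvw", da, windows, optimize=True)
    grads["conv_b"] = da.sum(axis=(0, 2))
    return loss, grads


def train(
    images: np.ndarray,
    labels: np.ndarray,
    config: CNNConfig = CNNConfig(),
) -> tuple[CNNModel, np.ndarray]:
    """Train by seeded mini-batch gradient descent on cross-entropy.

    ``images`` is (n, Nv, Nt); ``labels`` holds 'left'/'right' strings or
    0/1 class indices.  Returns the final model and the per-epoch mean
    batch loss (length ``config.epochs``).
    """
    x = np.asarray(images, dtype=float)
    y = encode_labels(labels)
    if x.ndim != 3 or len(x) != len(y):
        raise ValueError("images must be (n, Nv, Nt) matching labels")
    if len(x) < 2 or len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")

    model = CNNModel.initialize(x.shape[1], x.shape[2], config)
    rng = np.random.default_rng(config.seed + 1)
    history = np.empty(config.epochs)
    lr = config.learning_rate
    for epoch in range(config.epochs):
        order = rng.permutation(len(x))
        losses = []
        for lo in range(0, len(x), config.batch_size):
            idx = order[lo:lo + config.batch_size]
            loss, grads = _loss_and_gradients(x[idx], y[idx], model)
            model.conv_w -= lr * grads["conv_w"]
            model.conv_b -= lr * grads["conv_b"]
            model.fc_w -= lr * grads["fc_w"]
            model.fc_b -= lr * grads["fc_b"]
            losses.append(loss)
        history[epoch] = np.mean(losses)
    return model, history


def predict(images: np.ndarray, model: CNNModel
            ) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels and class probabilities for a batch of images.

    Ties break toward class index 0 ('left').
    """
    x = np.asarray(images, dtype=float)
    if x.ndim == 2:
        x = x[None]
    probs = forward(x, model)
    indices = probs.argmax(axis=-1)  # argmax prefers the lower index on ties
    labels = np.array([LABELS[i] for i in indices])
    return labels, probs


def encode_labels(labels: np.ndarray) -> np.ndarray:
    """Map 'left'/'right' (or ints) to class indices 0/1."""
    labels = np.asarray(labels)
    if labels.dtype.kind in "iu":
        return labels.astype(int)
    try:
        return np.array([CLASS_TO_INDEX[l] for l in labels])
    except KeyError as err:
        raise ValueError(f"unknown label {err.args[0]!r}") from None
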