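"""Training: Adam with gradient clipping, plus masked-prediction
pretraining of the convolutional stem.

Classification uses cross-entropy, Adam at learning rate 1.5e-3, batch
size 32, up to 20 epochs, and global-norm gradient clipping at 1.0.
Pretraining wraps the conv stem as the encoder of an autoencoder whose
decoder mirrors the stem with reversed channel dimensions; contiguous time
spans of the input are zeroed (masked prediction) and the mean-squared
reconstruction error over all positions is minimised for three epochs, after
which the decoder is discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .architectures import KERNEL, Model
from .layers import Conv1d, Param, ReLU, Sequential, softmax, softmax_cross_entropy

__all__ = [
    "TrainingConfig",
    "PretrainConfig",
    "Adam",
    "train_classifier",
    "pretrain_encoder",
    "predict",
]


@dataclass
class TrainingConfig:
    learning_rate: float = 1.5e-3
    batch_size: int = 32
    max_epochs: int = 20
    grad_clip_max_norm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class PretrainConfig:
    epochs: int = 3
    mask_fraction: float = 0.15
    mask_span: int = 8
    learning_rate: float = 1.5e-3
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.mask_fraction < 1:
            raise ValueError("mask_fraction must be in [0, 1)")


class Adam:
    def __init__(self, params: list[Param], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.eps = lr, eps
        self.b1, self.b2 = betas
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def clip_global_norm(self, max_norm: float) -> None:
        total = np.sqrt(sum(float((p.grad ** 2).sum()) for p in self.params))
        if total > max_norm:
            scale = max_norm / (total + 1e-12)
            for p in self.params:
                p.grad *= scale

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _as_arrays(dataset) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(dataset, "windows"):
        return np.asarray(dataset.windows), np.asarray(dataset.labels)
    X, y = dataset
    return np.asarray(X), np.asarray(y)


def train_classifier(model: Model, train_dataset, config: TrainingConfig
                     ) -> tuple[Model, list[dict]]:
    """Mini-batch Adam training; returns the model and per-epoch history
    (loss and training accuracy)."""
    X, y = _as_arrays(train_dataset)
    if len(X) == 0:
        raise ValueError("empty training dataset")
    n_classes = model.layers[-1].b.value.size
    if y.min() < 0 or y.max() >= n_classes:
        raise ValueError(f"labels must lie in [0, {n_classes})")
    rng = np.random.default_rng(config.seed)
    model.set_rng(np.random.default_rng(config.seed + 1))
    opt = Adam(model.params(), config.learning_rate)
    history: list[dict] = []
    n = len(X)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for s in range(0, n, config.batch_size):
            idx = order[s:s + config.batch_size]
            xb = np.asarray(X[idx], dtype=np.float64)
            yb = y[idx]
            model.zero_grad()
            logits = model.forward(xb, train=True)
            loss, grad = softmax_cross_entropy(logits, yb)
            model.backward(grad)
            opt.clip_global_norm(config.grad_clip_max_norm)
            opt.step()
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == yb).sum())
        history.append({"epoch": epoch, "loss": float(np.mean(losses)),
                        "accuracy": correct / n})
    return model, history


def _mirrored_decoder(stem_convs: list[Conv1d], rng: np.random.Generator
                      ) -> Sequential:
    dims = [c.in_ch for c in stem_convs] + [stem_convs[-1].out_ch]
    # Reverse the channel ladder: e.g. encoder 3->64->64 gives 64->64->3.
    rev = dims[::-1]
    layers: list = []
    for i in range(len(rev) - 1):
        layers.append(Conv1d(rev[i], rev[i + 1], KERNEL, rng))
        if i < len(rev) - 2:
            layers.append(ReLU())
    return Sequential(layers)


def _mask_spans(X: np.ndarray, fraction: float, span: int,
                rng: np.random.Generator) -> np.ndarray:
    masked = X.copy()
    B, T, _ = X.shape
    n_spans = max(int(round(fraction * T / span)), 1) if fraction > 0 else 0
    for b in range(B):
        for _ in range(n_spans):
            s = rng.integers(0, max(T - span, 1))
            masked[b, s:s + span, :] = 0.0
    return masked


def pretrain_encoder(model: Model, train_windows, config: PretrainConfig
                     ) -> tuple[Model, list[float]]:
    """Masked-prediction pretraining of the conv stem.

    Returns the model (stem weights updated in place) and the per-epoch
    reconstruction-loss history — exactly ``config.epochs`` entries. For
    architectures without a convolutional stem (A2) this is an explicit
    no-op with a warning and an empty history.
    """
    stem = model.conv_stem
    convs = [l for l in stem if isinstance(l, Conv1d)]
    if not convs:
        warnings.warn(f"architecture {model.spec.name} has no conv stem; "
                      "pretraining skipped", stacklevel=2)
        return model, []
    X = (np.asarray(train_windows.windows) if hasattr(train_windows, "windows")
         else np.asarray(train_windows))
    rng = np.random.default_rng(config.seed)
    encoder = Sequential(stem)
    decoder = _mirrored_decoder(convs, np.random.default_rng(config.seed + 1))
    opt = Adam(encoder.params() + decoder.params(), config.learning_rate)
    history: list[float] = []
    n = len(X)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, config.batch_size):
            idx = order[s:s + config.batch_size]
            target = np.asarray(X[idx], dtype=np.float64)
            inp = _mask_spans(target, config.mask_fraction, config.mask_span, rng)
            encoder.zero_grad()
            decoder.zero_grad()
            recon = decoder.forward(encoder.forward(inp, train=True), train=True)
            diff = recon - target
            loss = float((diff ** 2).mean())
            grad = 2.0 * diff / diff.size
            encoder.backward(decoder.backward(grad))
            opt.clip_global_norm(1.0)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return model, history


def predict(model: Model, windows, batch_size: int = 256) -> np.ndarray:
    """Class-probability matrix (rows sum to 1) for a window array."""
    X = (np.asarray(windows.windows) if hasattr(windows, "windows")
         else np.asarray(windows))
    if X.ndim != 3 or X.shape[2] != model.in_channels:
        raise ValueError(
            f"expected [N x T x {model.in_channels}] input, got {X.shape}"
        )
    probs = []
    for s in range(0, len(X), batch_size):
        logits = model.forward(np.asarray(X[s:s + batch_size], dtype=np.float64),
                               train=False)
        probs.append(softmax(logits))
    return np.concatenate(probs, axis=0) if probs else np.empty((0, 6))
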