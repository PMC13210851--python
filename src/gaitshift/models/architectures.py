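"""The A1-A5 architecture zoo.

All five models map a [batch x 256 x C] window to six unnormalised class
scores. Shared conventions: 64 convolutional filters of kernel length 3
(stride 1, same padding, bias, ReLU), bidirectional LSTM with 32 hidden
units per direction and two bias vectors per direction, dropout p = 0.2,
and an affine 64 -> 6 head fed by the concatenated final hidden states of
the two LSTM directions.

  A1: Conv(C->64) -> global average pool -> dropout -> head
  A2: BiLSTM(C->32x2) -> dropout -> head
  A3: Conv(C->64) x3 -> LayerNorm (no affine) -> BiLSTM -> dropout -> head
  A4: Conv(C->64) x2 -> parameter-free 4-head self-attention ->
      LayerNorm (no affine) -> BiLSTM -> dropout -> head
  A5: Conv(C->64) x2 -> 2 x [projected 4-head self-attention +
      affine LayerNorm] -> LayerNorm (no affine) -> BiLSTM -> dropout -> head

With C = 3 these yield 1,030 / 9,862 / 50,822 / 38,470 / 72,006 trainable
parameters respectively; dropping one input channel removes exactly
1*64*3 = 192 parameters from the first convolution (or 4*32*1 + head
adjustments are absent since only the conv stem sees C).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import (
    BiLSTMLast,
    Conv1d,
    Dropout,
    GlobalAvgPool,
    LayerNorm,
    Linear,
    ReLU,
    SelfAttention,
    Sequential,
)

__all__ = [
    "ArchitectureSpec",
    "ARCHITECTURES",
    "build_model",
    "count_trainable_parameters",
    "Model",
]

ARCHITECTURES = ("A1", "A2", "A3", "A4", "A5")

N_FILTERS = 64
KERNEL = 3
LSTM_HIDDEN = 32
N_HEADS = 4


@dataclass(frozen=True)
class ArchitectureSpec:
    """Declarative description of one model variant."""

    name: str
    in_channels: int = 3
    n_classes: int = 6
    dropout_p: float = 0.2

    def __post_init__(self) -> None:
        if self.name not in ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {self.name!r}; expected one of {ARCHITECTURES}"
            )
        if self.in_channels < 1:
            raise ValueError("in_channels must be >= 1")


class Model(Sequential):
    """A built architecture: a Sequential with its spec attached."""

    def __init__(self, layers, spec: ArchitectureSpec):
        super().__init__(layers)
        self.spec = spec

    @property
    def in_channels(self) -> int:
        return self.spec.in_channels

    @property
    def conv_stem(self) -> list:
        """Leading Conv1d/ReLU pairs (the encoder pretrained by masked
        prediction); empty for A2."""
        stem = []
        for layer in self.layers:
            if isinstance(layer, (Conv1d, ReLU)):
                stem.append(layer)
            else:
                break
        return stem


def build_model(spec: ArchitectureSpec | str, seed: int = 0) -> Model:
    """Instantiate an architecture with seeded weight initialisation."""
    if isinstance(spec, str):
        spec = ArchitectureSpec(name=spec)
    rng = np.random.default_rng(seed)
    C, F, H = spec.in_channels, N_FILTERS, LSTM_HIDDEN
    layers: list = []

    def convs(n: int) -> None:
        ch = C
        for _ in range(n):
            layers.append(Conv1d(ch, F, KERNEL, rng))
            layers.append(ReLU())
            ch = F

    if spec.name == "A1":
        convs(1)
        layers += [GlobalAvgPool(), Dropout(spec.dropout_p),
                   Linear(F, spec.n_classes, rng)]
    elif spec.name == "A2":
        layers += [BiLSTMLast(C, H, rng), Dropout(spec.dropout_p),
                   Linear(2 * H, spec.n_classes, rng)]
    elif spec.name == "A3":
        convs(3)
        layers += [LayerNorm(F, affine=False), BiLSTMLast(F, H, rng),
                   Dropout(spec.dropout_p), Linear(2 * H, spec.n_classes, rng)]
    elif spec.name == "A4":
        convs(2)
        layers += [SelfAttention(F, N_HEADS, projected=False),
                   LayerNorm(F, affine=False), BiLSTMLast(F, H, rng),
                   Dropout(spec.dropout_p), Linear(2 * H, spec.n_classes, rng)]
    elif spec.name == "A5":
        convs(2)
        for _ in range(2):
            layers.append(SelfAttention(F, N_HEADS, projected=True, rng=rng))
            layers.append(LayerNorm(F, affine=True))
        layers += [LayerNorm(F, affine=False), BiLSTMLast(F, H, rng),
                   Dropout(spec.dropout_p), Linear(2 * H, spec.n_classes, rng)]
    return Model(layers, spec)


def count_trainable_parameters(model: Model | Sequential) -> int:
    """Total number of learnable scalars across all layers."""
    return int(sum(p.value.size for p in model.params()))
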