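"""The segment classifier: 1D CNN with an embedded recurrent stage.

Default architecture, following the detector this package implements:

* four convolutional groups of two same-padded conv layers each (eight conv
  layers total), kernel size 3, channel widths 32 / 64 / 128 / 256, each group
  closed by a size-2 max pool and an ELU;
* two stacked LSTM layers over the pooled time axis (1500 samples -> 93
  steps of 256 features), either the standard gated cell or the two-gate
  "paper" variant without a cell state;
* two fully connected layers ending in a single sigmoid unit.

Setting ``lstm_layers=0`` ablates the recurrent stage: the conv features are
mean-pooled over time before the fully connected head.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.special import expit as sigmoid

from .layers import (F32, Conv1d, Dense, ELU, LSTM, Layer, MaxPool1d,
                     MeanOverTime, PaperLSTM, ReLU, TakeLast)

__all__ = ["ModelSpec", "SegmentNet", "build_model", "bce_loss", "bce_loss_grad"]

DEFAULT_CONV_GROUPS = ((2, 32), (2, 64), (2, 128), (2, 256))


@dataclass(frozen=True)
class ModelSpec:
    """Declarative architecture description from which the network is built."""

    input_length: int = 1500
    conv_groups: tuple = DEFAULT_CONV_GROUPS
    kernel_size: int = 3
    pool_size: int = 2
    activation: str = "elu"
    lstm_layers: int = 2
    lstm_hidden: int = 128
    lstm_variant: str = "standard"  # "standard" | "paper"
    fc_sizes: tuple = (64, 1)
    intra_group_activation: bool = True

    def validate(self) -> None:
        if self.activation not in ("elu", "relu"):
            raise ValueError(f"activation must be 'elu' or 'relu', got {self.activation!r}")
        if self.lstm_variant not in ("standard", "paper"):
            raise ValueError(f"lstm_variant must be 'standard' or 'paper', got {self.lstm_variant!r}")
        if self.lstm_layers < 0:
            raise ValueError("lstm_layers must be >= 0")
        if len(self.fc_sizes) != 2 or self.fc_sizes[-1] != 1:
            raise ValueError("fc_sizes must be two integers ending in 1")
        min_len = self.pool_size ** len(self.conv_groups)
        if self.input_length < min_len:
            raise ValueError(
                f"input_length {self.input_length} too short for "
                f"{len(self.conv_groups)} pools of size {self.pool_size}; "
                f"minimum is {min_len}")

    @property
    def sequence_length(self) -> int:
        """Time steps entering the recurrent stage (floor division per pool)."""
        L = self.input_length
        for _ in self.conv_groups:
            L //= self.pool_size
        return L

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        if "conv_groups" in d:
            d["conv_groups"] = tuple(tuple(g) for g in d["conv_groups"])
        if "fc_sizes" in d:
            d["fc_sizes"] = tuple(d["fc_sizes"])
        return cls(**d)


class SegmentNet:
    """The assembled network: an ordered layer list with shared backprop."""

    def __init__(self, spec: ModelSpec, layers: list, seed: int):
        self.spec = spec
        self.layers = layers
        self.seed = seed

    def forward_logits(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """(B, input_length) standardized segments -> (B,) raw logits."""
        h = np.ascontiguousarray(x, dtype=F32)[:, :, None]  # (B, L, 1) channels-last
        for layer in self.layers:
            h = layer.forward(h, train=train)
        return h[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        d = np.asarray(dlogits, dtype=F32)[:, None]
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def params(self) -> list:
        return [p for layer in self.layers for p in layer.params()]

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def n_params(self) -> int:
        return sum(p.size for p in self.params())

    def get_weights(self) -> list:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights: list) -> None:
        for p, w in zip(self.params(), weights, strict=True):
            p.value[...] = w

    def save(self, path: str | Path) -> None:
        """Weights as .npz plus a JSON sidecar with spec, seed and a content hash."""
        import hashlib
        path = Path(path)
        weights = {f"p{i}": w for i, w in enumerate(self.get_weights())}
        np.savez(path.with_suffix(".npz"), **weights)
        digest = hashlib.sha256()
        for w in self.get_weights():
            digest.update(w.tobytes())
        sidecar = {"spec": self.spec.to_dict(), "seed": self.seed,
                   "weights_sha256": digest.hexdigest()}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SegmentNet":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        net = build_model(ModelSpec.from_dict(sidecar["spec"]), seed=sidecar["seed"])
        data = np.load(path.with_suffix(".npz"))
        net.set_weights([data[f"p{i}"] for i in range(len(data.files))])
        return net


def build_model(spec: ModelSpec, seed: int = 0) -> SegmentNet:
    """Deterministically construct the network described by ``spec``."""
    spec.validate()
    rng = np.random.default_rng(seed)
    act = ELU if spec.activation == "elu" else ReLU
    layers: list[Layer] = []
    in_ch = 1
    for n_convs, out_ch in spec.conv_groups:
        for j in range(n_convs):
            layers.append(Conv1d(in_ch, out_ch, spec.kernel_size, rng))
            in_ch = out_ch
            if spec.intra_group_activation and j < n_convs - 1:
                layers.append(act())
        layers.append(MaxPool1d(spec.pool_size))
        layers.append(act())
    # channels-last layout: the pooled maps (B, T, C) are already a sequence

    if spec.lstm_layers > 0:
        cell = LSTM if spec.lstm_variant == "standard" else PaperLSTM
        feat = in_ch
        for _ in range(spec.lstm_layers):
            layers.append(cell(feat, spec.lstm_hidden, rng))
            feat = spec.lstm_hidden
        layers.append(TakeLast())
        head_in = spec.lstm_hidden
    else:
        layers.append(MeanOverTime())
        head_in = in_ch

    layers.append(Dense(head_in, spec.fc_sizes[0], rng))
    layers.append(act())
    layers.append(Dense(spec.fc_sizes[0], spec.fc_sizes[1], rng))
    if isinstance(layers[0], Conv1d):
        layers[0].needs_input_grad = False  # input gradient is never consumed
    return SegmentNet(spec, layers, seed)


def bce_loss(p: np.ndarray, y: np.ndarray, eps: float = 1e-7) -> float:
    """Binary cross-entropy, natural log, probabilities clamped to [eps, 1-eps].

    L = -(1/N) sum_i [ y_i log p_i + (1 - y_i) log(1 - p_i) ]
    """
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if p.size == 0:
        raise ValueError("bce_loss requires at least one sample")
    if p.shape != y.shape:
        raise ValueError("p and y must have equal shapes")
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def bce_loss_grad(p: np.ndarray, y: np.ndarray, eps: float = 1e-7) -> np.ndarray:
    """Analytic dL/dp of :func:`bce_loss` (for gradient verification)."""
    p = np.clip(np.asarray(p, dtype=np.float64), eps, 1.0 - eps)
    y = np.asarray(y, dtype=np.float64)
    return (-(y / p) + (1.0 - y) / (1.0 - p)) / p.size


def bce_logits_loss_and_grad(logits: np.ndarray, y: np.ndarray) -> tuple:
    """Numerically stable fused sigmoid + BCE with gradient w.r.t. logits."""
    z = np.asarray(logits, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    loss = float(np.mean(np.maximum(z, 0.0) - y * z + np.log1p(np.exp(-np.abs(z)))))
    grad = (sigmoid(z) - y) / z.size
    return loss, grad
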