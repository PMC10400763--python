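"""Seeded minibatch training with Adam and early stopping."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit as sigmoid

from .network import SegmentNet, bce_logits_loss_and_grad

__all__ = ["TrainConfig", "Adam", "train", "predict_proba", "predict"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation protocol (unconstrained by the detector's description;
    defaults sized for single-CPU training of the default architecture)."""

    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 4
    early_stopping_patience: int = 2
    seed: int = 0
    device: str = "cpu"

    def validate(self) -> None:
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")
        if self.early_stopping_patience < 0:
            raise ValueError("early_stopping_patience must be >= 0")
        if self.device != "cpu":
            raise ValueError("this NumPy backend only supports device='cpu'")


class Adam:
    def __init__(self, params: list, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1; m += (1 - self.b1) * g
            v *= self.b2; v += (1 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _forward_batched(net: SegmentNet, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
    out = np.empty(len(x), dtype=np.float64)
    for i in range(0, len(x), batch_size):
        out[i:i + batch_size] = net.forward_logits(x[i:i + batch_size], train=False)
    return out


def predict_proba(net: SegmentNet, x: np.ndarray) -> np.ndarray:
    """Sigmoid probabilities for standardized segments (B, input_length)."""
    if x.shape[1] != net.spec.input_length:
        raise ValueError(
            f"segments of length {x.shape[1]} do not match model input_length "
            f"{net.spec.input_length}")
    return sigmoid(_forward_batched(net, x))


def predict(net: SegmentNet, x: np.ndarray, threshold: float = 0.5) -> tuple:
    """(probabilities, hard labels); p >= threshold maps to the positive class."""
    p = predict_proba(net, x)
    return p, (p >= threshold).astype(np.int64)


def train(net: SegmentNet, x_train: np.ndarray, y_train: np.ndarray,
          x_val: np.ndarray, y_val: np.ndarray, config: TrainConfig | None = None
          ) -> dict:
    """Minimise binary cross-entropy by seeded minibatch Adam.

    Early-stops when the validation loss has not improved for
    ``early_stopping_patience`` consecutive epochs and restores the
    best-validation weights.  Returns the history dict; the network is
    updated in place.
    """
    config = config or TrainConfig()
    config.validate()
    y_train = np.asarray(y_train)
    y_val = np.asarray(y_val)
    if len(x_train) == 0:
        raise ValueError("training set is empty")
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set must contain both classes")

    rng = np.random.default_rng(config.seed)
    opt = Adam(net.params(), lr=config.learning_rate)
    history = {"train_loss": [], "val_loss": [], "val_acc": []}
    best_loss = np.inf
    best_weights = net.get_weights()
    bad_epochs = 0

    for _epoch in range(config.max_epochs):
        order = rng.permutation(len(x_train))
        epoch_loss = 0.0
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            net.zero_grad()
            logits = net.forward_logits(x_train[idx], train=True)
            loss, dlogits = bce_logits_loss_and_grad(logits, y_train[idx])
            net.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(idx)
        history["train_loss"].append(epoch_loss / len(order))

        val_logits = _forward_batched(net, x_val)
        val_loss, _ = bce_logits_loss_and_grad(val_logits, y_val)
        val_acc = float(np.mean((val_logits >= 0.0) == (y_val == 1)))
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)

        if val_loss < best_loss - 1e-12:
            best_loss = val_loss
            best_weights = net.get_weights()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.early_stopping_patience > 0:
                break

    net.set_weights(best_weights)
    history["best_val_loss"] = best_loss
    return history
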