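"""NumPy layers with hand-written backpropagation.

Everything runs in float32 on the CPU.  Each layer caches what its backward
pass needs during ``forward`` and exposes its parameters as
:class:`ParamTensor` pairs (value, grad) for the optimizer.  Convolutions are
realised as im2col + BLAS matmul; recurrences loop over time with batched
matmuls per step.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy.special import expit as sigmoid

F32 = np.float32


class ParamTensor:
    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = value.astype(F32)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def params(self) -> list:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1d(Layer):
    """1D convolution, stride 1, length-preserving (same) padding.

    Operates channels-last: input (B, L, C_in) -> output (B, L, C_out).
    Realised as im2col (k shifted contiguous copies) + one BLAS matmul.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for same padding")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.k = kernel_size
        fan_in = in_channels * kernel_size
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, out_channels))
        self.W = ParamTensor("W", w)  # rows ordered (tap, channel)
        self.b = ParamTensor("b", np.zeros(out_channels))
        self.needs_input_grad = True
        self._col_buf = None

    def params(self):
        return [self.W, self.b]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        B, L, C = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
        shape = (B, L, self.k * C)
        if self._col_buf is None or self._col_buf.shape != shape:
            self._col_buf = np.empty(shape, dtype=F32)
        cols = self._col_buf
        for i in range(self.k):
            cols[:, :, i * C:(i + 1) * C] = xp[:, i:i + L, :]
        return cols.reshape(B * L, self.k * C)

    def forward(self, x, train=True):
        B, L, C = x.shape
        cols = self._im2col(x)
        y = cols @ self.W.value + self.b.value
        if train:
            self._cache = (cols, x.shape)
        return y.reshape(B, L, self.out_channels)

    def backward(self, dy):
        cols, (B, L, C) = self._cache
        dyf = dy.reshape(B * L, self.out_channels)
        self.W.grad += cols.T @ dyf
        self.b.grad += dyf.sum(axis=0)
        if not self.needs_input_grad:  # e.g. the first layer of the network
            return None
        dcols = (dyf @ self.W.value.T).reshape(B, L, self.k * C)
        p = self.k // 2
        dxp = np.zeros((B, L + 2 * p, C), dtype=F32)
        for i in range(self.k):
            dxp[:, i:i + L, :] += dcols[:, :, i * C:(i + 1) * C]
        return dxp[:, p:p + L, :]


class MaxPool1d(Layer):
    """Max pooling over the time axis of (B, L, C); a trailing remainder
    shorter than the pool is dropped."""

    def __init__(self, pool_size: int = 2):
        self.pool = pool_size

    def forward(self, x, train=True):
        B, L, C = x.shape
        L2 = L // self.pool
        xt = x[:, :L2 * self.pool, :].reshape(B, L2, self.pool, C)
        if self.pool == 2:  # common case without argmax/gather
            a, b = xt[:, :, 0, :], xt[:, :, 1, :]
            second = b >= a
            y = np.where(second, b, a)
            if train:
                self._cache = (second, x.shape)
            return y
        idx = xt.argmax(axis=2)
        if train:
            self._cache = (idx, x.shape)
        return np.take_along_axis(xt, idx[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dy):
        sel, (B, L, C) = self._cache
        L2 = L // self.pool
        dx = np.zeros((B, L, C), dtype=F32)
        dxt = dx[:, :L2 * self.pool, :].reshape(B, L2, self.pool, C)
        if self.pool == 2:
            second = sel
            dxt[:, :, 1, :] = np.where(second, dy, F32(0.0))
            dxt[:, :, 0, :] = np.where(second, F32(0.0), dy)
        else:
            np.put_along_axis(dxt, sel[:, :, None, :], dy[:, :, None, :], axis=2)
        return dx


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def forward(self, x, train=True):
        y = np.maximum(x, 0.0)
        y += self.alpha * np.expm1(np.minimum(x, 0.0))
        if train:
            # d/dx: 1 for x > 0, else alpha * exp(x) = y + alpha
            slope = np.where(x > 0, F32(1.0), y + F32(self.alpha))
            self._cache = slope
        return y

    def backward(self, dy):
        return dy * self._cache


class ReLU(Layer):
    def forward(self, x, train=True):
        if train:
            self._cache = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy):
        return (dy * self._cache).astype(F32)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        w = rng.normal(0.0, np.sqrt(2.0 / in_features), size=(in_features, out_features))
        self.W = ParamTensor("W", w)
        self.b = ParamTensor("b", np.zeros(out_features))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        if train:
            self._cache = x
        return x @ self.W.value + self.b.value

    def backward(self, dy):
        x = self._cache
        self.W.grad += x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


class LSTM(Layer):
    """Standard gated LSTM (input/forget/cell/output gates, cell state).

    Input (B, T, in); output the full hidden sequence (B, T, hidden).
    Forget-gate bias initialised to +1.
    """

    def __init__(self, in_features: int, hidden: int, rng: np.random.Generator):
        self.inf = in_features
        self.H = hidden
        s = np.sqrt(1.0 / hidden)
        self.Wx = ParamTensor("Wx", rng.uniform(-s, s, size=(in_features, 4 * hidden)))
        self.Wh = ParamTensor("Wh", rng.uniform(-s, s, size=(hidden, 4 * hidden)))
        b = np.zeros(4 * hidden)
        b[hidden:2 * hidden] = 1.0
        self.b = ParamTensor("b", b)

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, x, train=True):
        B, T, _ = x.shape
        H = self.H
        Z = (x.reshape(B * T, self.inf) @ self.Wx.value).reshape(B, T, 4 * H)
        I = np.empty((B, T, H), F32); Fg = np.empty((B, T, H), F32)
        G = np.empty((B, T, H), F32); O = np.empty((B, T, H), F32)
        Cs = np.empty((B, T, H), F32); TC = np.empty((B, T, H), F32)
        Hs = np.empty((B, T, H), F32)
        h = np.zeros((B, H), F32)
        c = np.zeros((B, H), F32)
        for t in range(T):
            a = Z[:, t] + h @ self.Wh.value + self.b.value
            i = sigmoid(a[:, :H]); f = sigmoid(a[:, H:2 * H])
            g = np.tanh(a[:, 2 * H:3 * H]); o = sigmoid(a[:, 3 * H:])
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            I[:, t], Fg[:, t], G[:, t], O[:, t] = i, f, g, o
            Cs[:, t], TC[:, t], Hs[:, t] = c, tc, h
        if train:
            self._cache = (x, I, Fg, G, O, Cs, TC, Hs)
        return Hs

    def backward(self, dHs):
        x, I, Fg, G, O, Cs, TC, Hs = self._cache
        B, T, H = I.shape
        dA = np.empty((B, T, 4 * H), F32)
        dh_next = np.zeros((B, H), F32)
        dc_next = np.zeros((B, H), F32)
        for t in range(T - 1, -1, -1):
            dh = dHs[:, t] + dh_next
            i, f, g, o, tc = I[:, t], Fg[:, t], G[:, t], O[:, t], TC[:, t]
            do = dh * tc
            dc = dh * o * (1 - tc * tc) + dc_next
            c_prev = Cs[:, t - 1] if t > 0 else 0.0
            di, df, dg = dc * g, dc * c_prev, dc * i
            dc_next = dc * f
            da = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
                axis=1)
            h_prev = Hs[:, t - 1] if t > 0 else np.zeros((B, H), F32)
            self.Wh.grad += h_prev.T @ da
            dh_next = da @ self.Wh.value.T
            dA[:, t] = da
        dAf = dA.reshape(B * T, 4 * H)
        self.b.grad += dAf.sum(axis=0)
        xf = x.reshape(B * T, self.inf)
        self.Wx.grad += xf.T @ dAf
        return (dAf @ self.Wx.value.T).reshape(B, T, self.inf)


class PaperLSTMStep(NamedTuple):
    """One step of the two-gate recurrence: gates, candidate and new hidden state."""
    I_t: np.ndarray
    F_t: np.ndarray
    h_tilde: np.ndarray
    h_t: np.ndarray


def paper_lstm_step(h_prev: np.ndarray, x_t: np.ndarray, W_i: np.ndarray,
                    W_f: np.ndarray, W: np.ndarray, b_i=0.0, b_f=0.0, b=0.0
                    ) -> PaperLSTMStep:
    """Evaluate the two-gate LSTM recurrence exactly as written.

    I_t  = sigmoid(W_i . [h_{t-1}, X_t])
    F_t  = sigmoid(W_f . [h_{t-1}, X_t])
    h~_t = tanh(W . [I_t * h_{t-1}, X_t])
    h_t  = (1 - F_t) * h_{t-1} + F_t * h~_t

    The update carries no separate cell state and no output gate: the forget
    gate interpolates between the previous hidden state and the candidate,
    and the input gate modulates the hidden state fed to the candidate.
    Weight matrices act on the concatenation (rows = hidden + input dims).
    """
    h_prev = np.atleast_2d(h_prev)
    x_t = np.atleast_2d(x_t)
    z = np.concatenate([h_prev, x_t], axis=1)
    if z.shape[1] != W_i.shape[0]:
        raise ValueError(
            f"weight rows ({W_i.shape[0]}) must equal hidden + input dims ({z.shape[1]})")
    I = sigmoid(z @ W_i + b_i)
    F = sigmoid(z @ W_f + b_f)
    h_tilde = np.tanh(np.concatenate([I * h_prev, x_t], axis=1) @ W + b)
    h_t = (1 - F) * h_prev + F * h_tilde
    return PaperLSTMStep(I, F, h_tilde, h_t)


class PaperLSTM(Layer):
    """Recurrent layer built from the two-gate update of :func:`paper_lstm_step`."""

    def __init__(self, in_features: int, hidden: int, rng: np.random.Generator):
        self.inf = in_features
        self.H = hidden
        s = np.sqrt(1.0 / hidden)
        shape = (hidden + in_features, hidden)
        self.Wi = ParamTensor("Wi", rng.uniform(-s, s, size=shape))
        self.Wf = ParamTensor("Wf", rng.uniform(-s, s, size=shape))
        self.Wc = ParamTensor("Wc", rng.uniform(-s, s, size=shape))
        self.bi = ParamTensor("bi", np.zeros(hidden))
        self.bf = ParamTensor("bf", np.zeros(hidden))
        self.bc = ParamTensor("bc", np.zeros(hidden))

    def params(self):
        return [self.Wi, self.Wf, self.Wc, self.bi, self.bf, self.bc]

    def forward(self, x, train=True):
        B, T, _ = x.shape
        H = self.H
        I = np.empty((B, T, H), F32); Fg = np.empty((B, T, H), F32)
        Hc = np.empty((B, T, H), F32); Hs = np.empty((B, T, H), F32)
        h = np.zeros((B, H), F32)
        for t in range(T):
            step = paper_lstm_step(h, x[:, t], self.Wi.value, self.Wf.value,
                                   self.Wc.value, self.bi.value, self.bf.value,
                                   self.bc.value)
            I[:, t], Fg[:, t], Hc[:, t] = step.I_t, step.F_t, step.h_tilde
            h = step.h_t.astype(F32)
            Hs[:, t] = h
        if train:
            self._cache = (x, I, Fg, Hc, Hs)
        return Hs

    def backward(self, dHs):
        x, I, Fg, Hc, Hs = self._cache
        B, T, H = I.shape
        dx = np.empty_like(x)
        dh_next = np.zeros((B, H), F32)
        for t in range(T - 1, -1, -1):
            dh = dHs[:, t] + dh_next
            i, f, hc = I[:, t], Fg[:, t], Hc[:, t]
            h_prev = Hs[:, t - 1] if t > 0 else np.zeros((B, H), F32)
            xt = x[:, t]
            z = np.concatenate([h_prev, xt], axis=1)
            df = dh * (hc - h_prev)
            dhc = dh * f
            dh_prev = dh * (1 - f)
            dac = dhc * (1 - hc * hc)
            zc = np.concatenate([i * h_prev, xt], axis=1)
            self.Wc.grad += zc.T @ dac
            self.bc.grad += dac.sum(axis=0)
            dzc = dac @ self.Wc.value.T
            d_ih = dzc[:, :H]
            dxt = dzc[:, H:].copy()
            di = d_ih * h_prev
            dh_prev += d_ih * i
            dai = di * i * (1 - i)
            daf = df * f * (1 - f)
            self.Wi.grad += z.T @ dai
            self.Wf.grad += z.T @ daf
            self.bi.grad += dai.sum(axis=0)
            self.bf.grad += daf.sum(axis=0)
            dz = dai @ self.Wi.value.T + daf @ self.Wf.value.T
            dh_prev += dz[:, :H]
            dxt += dz[:, H:]
            dx[:, t] = dxt
            dh_next = dh_prev
        return dx


class TakeLast(Layer):
    """Select the final time step of a (B, T, F) sequence."""

    def forward(self, x, train=True):
        if train:
            self._cache = x.shape
        return x[:, -1, :]

    def backward(self, dy):
        B, T, Fdim = self._cache
        dx = np.zeros((B, T, Fdim), F32)
        dx[:, -1, :] = dy
        return dx


class MeanOverTime(Layer):
    """Global average over the time axis of a (B, T, F) sequence."""

    def forward(self, x, train=True):
        if train:
            self._cache = x.shape
        return x.mean(axis=1)

    def backward(self, dy):
        B, T, Fdim = self._cache
        return (np.repeat(dy[:, None, :], T, axis=1) / T).astype(F32)


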