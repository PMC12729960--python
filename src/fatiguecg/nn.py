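"""Minimal NumPy neural-network layers with manual backpropagation.

Implements exactly what the CNN-BiLSTM fatigue classifier needs: strided
1-D convolution (im2col), ReLU, inverted dropout, temporal max-pooling,
bidirectional LSTM with full backpropagation-through-time, dense layers,
softmax cross-entropy, and Adam.  Everything runs in float32 and is
deterministic given the seeds supplied by the caller.

The backward passes propagate input gradients all the way to the first
convolution's activation maps, which is what 1-D Grad-CAM consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

F32 = np.float32


@dataclass
class Param:
    name: str
    value: np.ndarray
    grad: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.value = self.value.astype(F32)
        self.grad = np.zeros_like(self.value)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Layer:
    def params(self) -> list[Param]:
        return []


class Conv1D(Layer):
    """Single-channel strided 1-D convolution: (B, L) -> (B, T, F)."""

    def __init__(self, filters: int, kernel: int, stride: int, rng: np.random.Generator):
        self.kernel = kernel
        self.stride = stride
        # He-scaled init: the layer feeds a ReLU
        self.W = Param("conv.W",
                       rng.standard_normal((filters, kernel)) * np.sqrt(2.0 / kernel))
        self.b = Param("conv.b", np.zeros(filters))
        self._patches: np.ndarray | None = None

    def out_length(self, length: int) -> int:
        return (length - self.kernel) // self.stride + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] < self.kernel:
            raise ValueError(
                f"input length {x.shape[1]} < kernel {self.kernel}: "
                f"floor(({x.shape[1]} - {self.kernel}) / {self.stride}) + 1 < 1"
            )
        view = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=1)
        self._patches = np.ascontiguousarray(view[:, :: self.stride, :], dtype=F32)
        return self._patches @ self.W.value.T + self.b.value

    def backward(self, dout: np.ndarray) -> None:
        B, T, F = dout.shape
        flat_d = dout.reshape(B * T, F)
        flat_p = self._patches.reshape(B * T, self.kernel)
        self.W.grad += flat_d.T @ flat_p
        self.b.grad += flat_d.sum(axis=(0))
        # input gradient unused: the convolution is the first layer

    def params(self) -> list[Param]:
        return [self.W, self.b]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not (0 <= p < 1):
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.p == 0:
            self._mask = None
            return x
        r = self.rng.random(x.shape, dtype=F32)
        self._mask = np.greater_equal(r, self.p).astype(F32)
        self._mask /= F32(1 - self.p)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class MaxPool1D(Layer):
    """Non-overlapping temporal max pooling on (B, T, C)."""

    def __init__(self, size: int):
        self.size = size

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, C = x.shape
        T_out = T // self.size
        xt = x[:, : T_out * self.size, :].reshape(B, T_out, self.size, C)
        self._argmax = xt.argmax(axis=2)
        self._in_shape = x.shape
        return np.take_along_axis(xt, self._argmax[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, T_out, C = dout.shape
        dx = np.zeros(self._in_shape, dtype=F32)
        b, t, c = np.ogrid[:B, :T_out, :C]
        dx[:, : T_out * self.size, :].reshape(B, T_out, self.size, C)[
            b, t, self._argmax, c
        ] = dout
        return dx


class Subsample(Layer):
    """Temporal decimation by a fixed stride on (B, T, C)."""

    def __init__(self, stride: int):
        self.stride = max(int(stride), 1)

    def out_length(self, length: int) -> int:
        return (length + self.stride - 1) // self.stride

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return np.ascontiguousarray(x[:, :: self.stride, :])

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = np.zeros(self._in_shape, dtype=F32)
        dx[:, :: self.stride, :] = dout
        return dx


class ChunkTime(Layer):
    """Strided recurrent framing: group ``stride`` consecutive time steps
    into one flattened step, (B, T, C) -> (B, T//stride, stride*C).
    Trailing frames that do not fill a chunk are dropped."""

    def __init__(self, stride: int):
        self.stride = max(int(stride), 1)

    def out_length(self, length: int) -> int:
        return length // self.stride

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, C = x.shape
        self._in_shape = x.shape
        T_out = T // self.stride
        return np.ascontiguousarray(
            x[:, : T_out * self.stride, :].reshape(B, T_out, self.stride * C)
        )

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, T_out, _ = dout.shape
        dx = np.zeros(self._in_shape, dtype=F32)
        C = self._in_shape[2]
        dx[:, : T_out * self.stride, :] = dout.reshape(B, T_out * self.stride, C)
        return dx


class LSTMDirection:
    """One direction of an LSTM layer; gate order (i, f, o, g).

    The input projection ``x @ Wx`` for all time steps and the gradient
    contractions over time run as single matmuls; only the recurrence
    itself loops over steps.
    """

    def __init__(self, name: str, input_dim: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        k = 1.0 / np.sqrt(hidden)
        self.Wx = Param(f"{name}.Wx", rng.uniform(-k, k, size=(input_dim, 4 * hidden)))
        self.Wh = Param(f"{name}.Wh", rng.uniform(-k, k, size=(hidden, 4 * hidden)))
        b = np.zeros(4 * hidden)
        b[hidden : 2 * hidden] = 1.0  # forget-gate bias init
        self.b = Param(f"{name}.b", b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (B, T, D) -> hidden sequence (B, T, H); caches for BPTT."""
        B, T, D = x.shape
        H = self.hidden
        h = np.zeros((B, H), dtype=F32)
        c = np.zeros((B, H), dtype=F32)
        self._x = x
        zx = x.reshape(B * T, D) @ self.Wx.value + self.b.value
        zx = zx.reshape(B, T, 4 * H)
        gates = np.empty((T, B, 4 * H), dtype=F32)  # post-nonlinearity (i,f,o,g)
        cells = np.empty((T, B, H), dtype=F32)
        tanhc = np.empty((T, B, H), dtype=F32)
        hs = np.empty((B, T, H), dtype=F32)
        for t in range(T):
            z = zx[:, t, :] + h @ self.Wh.value
            z[:, : 3 * H] = _sigmoid(z[:, : 3 * H])
            np.tanh(z[:, 3 * H :], out=z[:, 3 * H :])
            i, f, o = z[:, :H], z[:, H : 2 * H], z[:, 2 * H : 3 * H]
            g = z[:, 3 * H :]
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            gates[t] = z
            cells[t] = c
            tanhc[t] = tc
            hs[:, t, :] = h
        self._gates, self._cells, self._tanhc, self._hs = gates, cells, tanhc, hs
        return hs

    def backward(self, dout: np.ndarray) -> np.ndarray:
        """dout: (B, T, H) gradient on the hidden sequence -> dx (B, T, D)."""
        x = self._x
        B, T, D = x.shape
        H = self.hidden
        gates, cells, tanhc, hs = self._gates, self._cells, self._tanhc, self._hs
        dh_next = np.zeros((B, H), dtype=F32)
        dc_next = np.zeros((B, H), dtype=F32)
        dWh = np.zeros_like(self.Wh.value)
        dz_all = np.empty((T, B, 4 * H), dtype=F32)
        WhT = self.Wh.value.T
        for t in range(T - 1, -1, -1):
            z = gates[t]
            i, f, o = z[:, :H], z[:, H : 2 * H], z[:, 2 * H : 3 * H]
            g = z[:, 3 * H :]
            c_prev = cells[t - 1] if t > 0 else np.zeros((B, H), dtype=F32)
            h_prev = hs[:, t - 1, :] if t > 0 else np.zeros((B, H), dtype=F32)
            tc = tanhc[t]
            dh = dout[:, t, :] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1 - tc * tc)
            dz = dz_all[t]
            dz[:, :H] = dc * g * i * (1 - i)
            dz[:, H : 2 * H] = dc * c_prev * f * (1 - f)
            dz[:, 2 * H : 3 * H] = do * o * (1 - o)
            dz[:, 3 * H :] = dc * i * (1 - g * g)
            dc_next = dc * f
            dWh += h_prev.T @ dz
            dh_next = dz @ WhT
        flat_dz = dz_all.transpose(1, 0, 2).reshape(B * T, 4 * H)
        self.Wx.grad += x.reshape(B * T, D).T @ flat_dz
        self.Wh.grad += dWh
        self.b.grad += flat_dz.sum(axis=0)
        return (flat_dz @ self.Wx.value.T).reshape(B, T, D)

    def params(self) -> list[Param]:
        return [self.Wx, self.Wh, self.b]


class BiLSTM(Layer):
    """Bidirectional LSTM: (B, T, D) -> (B, T, 2H), forward and reversed
    backward hidden sequences concatenated per time step."""

    def __init__(self, name: str, input_dim: int, hidden: int, rng: np.random.Generator):
        self.fwd = LSTMDirection(f"{name}.fwd", input_dim, hidden, rng)
        self.bwd = LSTMDirection(f"{name}.bwd", input_dim, hidden, rng)
        self.hidden = hidden

    def forward(self, x: np.ndarray) -> np.ndarray:
        h_f = self.fwd.forward(x)
        h_b = self.bwd.forward(x[:, ::-1, :])[:, ::-1, :]
        return np.concatenate([h_f, h_b], axis=2)

    def final_state(self, out: np.ndarray) -> np.ndarray:
        """(B, 2H) summary: last forward step and first backward step."""
        H = self.hidden
        return np.concatenate([out[:, -1, :H], out[:, 0, H:]], axis=1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        H = self.hidden
        dx_f = self.fwd.backward(np.ascontiguousarray(dout[:, :, :H]))
        dx_b = self.bwd.backward(np.ascontiguousarray(dout[:, ::-1, H:]))[:, ::-1, :]
        return dx_f + dx_b

    def params(self) -> list[Param]:
        return self.fwd.params() + self.bwd.params()


class Dense(Layer):
    def __init__(self, name: str, input_dim: int, output_dim: int, rng: np.random.Generator):
        self.W = Param(f"{name}.W",
                       rng.standard_normal((input_dim, output_dim)) * np.sqrt(2.0 / input_dim))
        self.b = Param(f"{name}.b", np.zeros(output_dim))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T

    def params(self) -> list[Param]:
        return [self.W, self.b]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and the gradient w.r.t. the logits."""
    n = probs.shape[0]
    eps = 1e-12
    loss = -np.log(probs[np.arange(n), labels] + eps).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), (dlogits / n).astype(F32)


class Adam:
    """Adaptive-moment estimation over a list of Params."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
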