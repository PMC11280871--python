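"""Minimal NumPy building blocks for 1D sequence segmentation networks.

Layers operate on batches shaped ``(N, L, C)`` (batch, length, channels),
cache what they need on ``forward`` and return input gradients from
``backward``.  Convolutions are length-preserving ("same" zero padding,
stride 1); upsampling repeats values; pooling is max over non-overlapping
windows.  Weight gradients accumulate on the layer and are consumed by the
Adam optimizer.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv1D", "ReLU", "Dropout", "MaxPool", "Upsample", "LSTM",
           "Adam", "sigmoid"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Layer:
    """Base: parameterless layer."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def zero_grads(self) -> None:
        for g in self.grads:
            g[...] = 0.0


class Conv1D(Layer):
    """Same-padded stride-1 1D convolution.

    Weights are stored as ``(K*Cin, Cout)`` so the forward pass is a single
    matmul on im2col patches; the tap layout is ``[k, cin]``.  With an even
    kernel the extra pad sample goes on the right.
    """

    def __init__(self, cin: int, cout: int, k: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.cin, self.cout, self.k = cin, cout, k
        limit = np.sqrt(1.0 / (k * cin))       # uniform fan-in init
        self.W = rng.uniform(-limit, limit, size=(k * cin, cout))
        self.b = np.zeros(cout)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [self.W, self.b]
        self.grads = [self.dW, self.db]
        self.pad_left = (k - 1) // 2
        self.pad_right = k - 1 - self.pad_left

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def _patches(self, x: np.ndarray) -> np.ndarray:
        n, length, _ = x.shape
        xp = np.pad(x, ((0, 0), (self.pad_left, self.pad_right), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=1)
        # win: (N, L, C, K) -> (N, L, K, C) -> (N, L, K*C)
        return np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(
            n, length, self.k * self.cin)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        self._col = self._patches(x)
        return self._col @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, length, _ = self._shape
        col2 = self._col.reshape(-1, self.k * self.cin)
        dy2 = dy.reshape(-1, self.cout)
        self.dW += col2.T @ dy2
        self.db += dy2.sum(axis=0)
        dcol = (dy2 @ self.W.T).reshape(n, length, self.k, self.cin)
        dxp = np.zeros((n, length + self.k - 1, self.cin))
        for k in range(self.k):
            dxp[:, k:k + length, :] += dcol[:, :, k, :]
        return dxp[:, self.pad_left:self.pad_left + length, :]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        self.rate = rate
        self.rng: np.random.Generator | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class MaxPool(Layer):
    def __init__(self, size: int = 2) -> None:
        super().__init__()
        self.size = size

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, length, c = x.shape
        xr = x.reshape(n, length // self.size, self.size, c)
        self._argmax = xr.argmax(axis=2)
        self._shape = x.shape
        return xr.max(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, lo, c = dy.shape
        dxr = np.zeros((n, lo, self.size, c))
        np.put_along_axis(dxr, self._argmax[:, :, None, :], dy[:, :, None, :],
                          axis=2)
        return dxr.reshape(self._shape)


class Upsample(Layer):
    """Repeat each time step ``size`` times."""

    def __init__(self, size: int = 2) -> None:
        super().__init__()
        self.size = size

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return np.repeat(x, self.size, axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, length, c = dy.shape
        return dy.reshape(n, length // self.size, self.size, c).sum(axis=2)


class LSTM(Layer):
    """Full-sequence LSTM (one layer, ``units`` memory cells).

    Gate order in the fused weight matrices is (input, forget, cell,
    output).  Parameter count is ``4*((cin + units)*units + units)``.
    """

    def __init__(self, cin: int, units: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.cin, self.units = cin, units
        limit = np.sqrt(1.0 / cin)
        self.Wx = rng.uniform(-limit, limit, size=(cin, 4 * units))
        limit = np.sqrt(1.0 / units)
        self.Wh = rng.uniform(-limit, limit, size=(units, 4 * units))
        self.b = np.zeros(4 * units)
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)
        self.params = [self.Wx, self.Wh, self.b]
        self.grads = [self.dWx, self.dWh, self.db]

    @property
    def n_params(self) -> int:
        return self.Wx.size + self.Wh.size + self.b.size

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, steps, _ = x.shape
        u = self.units
        h = np.zeros((n, u))
        c = np.zeros((n, u))
        self._x = x
        self._cache = []
        out = np.empty((n, steps, u))
        for t in range(steps):
            z = x[:, t] @ self.Wx + h @ self.Wh + self.b
            i = sigmoid(z[:, :u])
            f = sigmoid(z[:, u:2 * u])
            g = np.tanh(z[:, 2 * u:3 * u])
            o = sigmoid(z[:, 3 * u:])
            c_prev, h_prev = c, h
            c = f * c_prev + i * g
            h = o * np.tanh(c)
            out[:, t] = h
            self._cache.append((h_prev, c_prev, i, f, g, o, c))
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, steps, _ = dy.shape
        u = self.units
        dx = np.empty((n, steps, self.cin))
        dh_next = np.zeros((n, u))
        dc_next = np.zeros((n, u))
        for t in range(steps - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, c = self._cache[t]
            tanh_c = np.tanh(c)
            dh = dy[:, t] + dh_next
            do = dh * tanh_c
            dc = dc_next + dh * o * (1.0 - tanh_c ** 2)
            di, df, dg = dc * g, dc * c_prev, dc * i
            dc_next = dc * f
            dz = np.concatenate([di * i * (1 - i), df * f * (1 - f),
                                 dg * (1 - g ** 2), do * o * (1 - o)], axis=1)
            self.dWx += self._x[:, t].T @ dz
            self.dWh += h_prev.T @ dz
            self.db += dz.sum(axis=0)
            dx[:, t] = dz @ self.Wx.T
            dh_next = dz @ self.Wh.T
        return dx


class Adam:
    """Adam with the standard moment defaults."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for idx, (p, g) in enumerate(zip(params, grads)):
            m = self._m.setdefault(idx, np.zeros_like(p))
            v = self._v.setdefault(idx, np.zeros_like(p))
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
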