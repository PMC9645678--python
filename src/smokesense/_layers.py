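"""Minimal NumPy neural-network layers with hand-written backprop.

Everything the CNN-LSTM classifier needs: valid-mode 2-D convolution
(im2col + GEMM), batch normalization, ReLU, non-overlapping max pooling
(trailing partial windows kept so small feature maps never vanish), dense,
inverted dropout, a standard LSTM (gate order i, f, g, o; forget-gate bias
initialized to 1), binary cross-entropy on logits, and Adam.

Float64 throughout; every layer is checked against numerical gradients in the
test suite.  Layers cache what forward saw and consume it in backward; a
layer's ``params()``/``grads()`` expose aligned lists for the optimizer.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D",
    "BatchNorm",
    "ReLU",
    "MaxPool2D",
    "Dense",
    "Dropout",
    "LSTM",
    "Adam",
    "sigmoid",
    "bce_with_logits",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dloss/dlogits)."""
    # softplus(z) - y*z, computed stably
    loss = float(np.mean(np.maximum(logits, 0) - logits * y + np.log1p(np.exp(-np.abs(logits)))))
    grad = (sigmoid(logits) - y) / logits.shape[0]
    return loss, grad


class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Conv2D(Layer):
    """Valid-mode stride-1 convolution on (B, H, W, C) input."""

    def __init__(self, kh: int, kw: int, cin: int, cout: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (kh * kw * cin))
        self.W = rng.standard_normal((kh, kw, cin, cout)) * scale
        self.b = np.zeros(cout)
        self.kh, self.kw, self.cin, self.cout = kh, kw, cin, cout
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        kh, kw = self.kh, self.kw
        view = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(1, 2))
        # view: (B, oh, ow, C, kh, kw)
        B, oh, ow = view.shape[:3]
        cols = view.reshape(B, oh * ow, self.cin * kh * kw)
        Wmat = self.W.transpose(2, 0, 1, 3).reshape(self.cin * kh * kw, self.cout)
        out = cols @ Wmat + self.b
        self._cache = (cols, x.shape, (oh, ow))
        return out.reshape(B, oh, ow, self.cout)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xshape, (oh, ow) = self._cache
        B = dout.shape[0]
        kh, kw = self.kh, self.kw
        dmat = dout.reshape(B, oh * ow, self.cout)
        K = self.cin * kh * kw
        dW_flat = cols.reshape(B * oh * ow, K).T @ dmat.reshape(B * oh * ow, self.cout)
        self.dW = dW_flat.reshape(self.cin, kh, kw, self.cout).transpose(1, 2, 0, 3)
        self.db = dmat.sum(axis=(0, 1))
        Wmat = self.W.transpose(2, 0, 1, 3).reshape(K, self.cout)
        dcols = (dmat @ Wmat.T).reshape(B, oh, ow, self.cin, kh, kw)
        dx = np.zeros(xshape)
        for i in range(kh):
            for j in range(kw):
                dx[:, i : i + oh, j : j + ow, :] += dcols[:, :, :, :, i, j]
        self._cache = None
        return dx

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class BatchNorm(Layer):
    """Batch normalization over all axes but the last (feature) axis."""

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(n_features)
        self.beta = np.zeros(n_features)
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        if train:
            self._cache = (xhat, inv_std, axes, x.shape)
        return xhat * self.gamma + self.beta

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std, axes, shape = self._cache
        n = np.prod([shape[a] for a in axes])
        self.dgamma = (dout * xhat).sum(axis=axes)
        self.dbeta = dout.sum(axis=axes)
        dxhat = dout * self.gamma
        dx = (
            dxhat - dxhat.mean(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes) / n
        ) * inv_std
        self._cache = None
        return dx

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2D(Layer):
    """Non-overlapping max pooling on (B, H, W, C); trailing partial windows
    along either axis are pooled as smaller windows (output dims = ceil(d/p))."""

    def __init__(self, pool: int = 2):
        self.pool = pool

    @staticmethod
    def out_dim(d: int, p: int) -> int:
        return -(-d // p)  # ceil

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        p = self.pool
        B, H, W, C = x.shape
        oh, ow = self.out_dim(H, p), self.out_dim(W, p)
        padded = np.full((B, oh * p, ow * p, C), -np.inf)
        padded[:, :H, :W, :] = x
        tiles = (
            padded.reshape(B, oh, p, ow, p, C)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(B, oh, ow, p * p, C)
        )
        idx = tiles.argmax(axis=3)
        out = np.take_along_axis(tiles, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
        self._cache = (idx, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, (B, H, W, C) = self._cache
        p = self.pool
        oh, ow = self.out_dim(H, p), self.out_dim(W, p)
        dtiles = np.zeros((B, oh, ow, p * p, C))
        np.put_along_axis(dtiles, idx[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
        dpad = (
            dtiles.reshape(B, oh, ow, p, p, C)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(B, oh * p, ow * p, C)
        )
        self._cache = None
        return dpad[:, :H, :W, :]


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        dx = dout @ self.W.T
        self._x = None
        return dx

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        if not train or self.rate == 0:
            self._mask = None
            return x
        assert rng is not None, "training-mode dropout needs an rng"
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class LSTM(Layer):
    """Single LSTM layer over (B, T, D) sequences; returns all hidden states."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        H = n_hidden
        s_x = np.sqrt(1.0 / n_in)
        s_h = np.sqrt(1.0 / H)
        self.Wx = rng.standard_normal((n_in, 4 * H)) * s_x
        self.Wh = rng.standard_normal((H, 4 * H)) * s_h
        self.b = np.zeros(4 * H)
        self.b[H : 2 * H] = 1.0  # forget-gate bias
        self.H = H
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, T, D = x.shape
        H = self.H
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.empty((B, T, H))
        caches = []
        for t in range(T):
            z = x[:, t, :] @ self.Wx + h @ self.Wh + self.b
            i = sigmoid(z[:, :H])
            f = sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            caches.append((x[:, t, :], h, c, i, f, g, o, tc))
            h, c = h_new, c_new
            hs[:, t, :] = h
        self._cache = (caches, x.shape)
        return hs

    def backward(self, dhs: np.ndarray) -> np.ndarray:
        caches, (B, T, D) = self._cache
        H = self.H
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)
        dx = np.empty((B, T, D))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, tc = caches[t]
            dh = dhs[:, t, :] + dh_next
            do = dh * tc
            dc = dh * o * (1 - tc ** 2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g ** 2), do * o * (1 - o)],
                axis=1,
            )
            self.dWx += x_t.T @ dz
            self.dWh += h_prev.T @ dz
            self.db += dz.sum(axis=0)
            dx[:, t, :] = dz @ self.Wx.T
            dh_next = dz @ self.Wh.T
            dc_next = dc * f
        self._cache = None
        return dx

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def grads(self):
        return [self.dWx, self.dWh, self.db]


class Adam:
    """Adam with the standard bias correction (beta1 0.9, beta2 0.999)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-2,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
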