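"""Minimal 1-D neural-network layers with explicit backpropagation.

Everything operates on float64 arrays shaped (N, C, T): batch, channels,
time. Convolutions are 'valid' (no padding) so that a constant input stays
exactly constant through every layer — which, combined with global average
pooling, makes the classifier's output on constant signals independent of
input length, a property the tests exploit as an oracle.

Gradients for every layer are verified against central finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidArgumentError

__all__ = [
    "Param",
    "Module",
    "Conv1d",
    "BatchNorm1d",
    "ReLU",
    "MaxPool1d",
    "SE1d",
    "GlobalAvgPool1d",
    "Linear",
    "ResidualBlock1d",
    "Sequential",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
]


class Param:
    """A trainable array plus its gradient accumulator."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)


class Module:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def out_length(self, t: int) -> int:
        """Output time length for input length t; raises if t is too short."""
        return t


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class Conv1d(Module):
    """Valid (unpadded) 1-D convolution, stride >= 1."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        stride: int = 1,
        rng: np.random.Generator | None = None,
    ):
        if kernel < 1 or stride < 1:
            raise InvalidArgumentError("kernel and stride must be >= 1")
        rng = rng or np.random.default_rng(0)
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel, self.stride = kernel, stride
        self.W = Param("conv.W", _he_init(rng, (out_channels, in_channels, kernel), in_channels * kernel))
        self.b = Param("conv.b", np.zeros(out_channels))
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def out_length(self, t: int) -> int:
        if t < self.kernel:
            raise InvalidArgumentError(
                f"input length {t} shorter than kernel {self.kernel}"
            )
        return (t - self.kernel) // self.stride + 1

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, t = x.shape
        to = self.out_length(t)
        cols = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=2)
        cols = cols[:, :, :: self.stride][:, :, :to]  # (N, C, To, K)
        cols_r = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(
            n * to, c * self.kernel
        )
        w_mat = self.W.value.reshape(self.out_channels, -1)
        y = cols_r @ w_mat.T + self.b.value
        self._cache = (cols_r, x.shape)
        return y.reshape(n, to, self.out_channels).transpose(0, 2, 1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols_r, x_shape = self._cache
        n, c, t = x_shape
        to = dy.shape[2]
        dy_r = dy.transpose(0, 2, 1).reshape(n * to, self.out_channels)
        self.W.grad += (dy_r.T @ cols_r).reshape(self.W.value.shape)
        self.b.grad += dy_r.sum(axis=0)
        dcols = (dy_r @ self.W.value.reshape(self.out_channels, -1)).reshape(
            n, to, c, self.kernel
        ).transpose(0, 2, 1, 3)  # (N, C, To, K)
        dx = np.zeros(x_shape)
        for k in range(self.kernel):
            dx[:, :, k : k + self.stride * to : self.stride] += dcols[:, :, :, k]
        return dx


class BatchNorm1d(Module):
    """Per-channel batch normalization over (batch, time)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param("bn.gamma", np.ones(channels))
        self.beta = Param("bn.beta", np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum, self.eps = momentum, eps
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mu = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None]) * inv_std[None, :, None]
        self._cache = (xhat, inv_std, training, x.shape)
        return self.gamma.value[None, :, None] * xhat + self.beta.value[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std, training, x_shape = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2))
        self.beta.grad += dy.sum(axis=(0, 2))
        dxhat = dy * self.gamma.value[None, :, None]
        if not training:
            return dxhat * inv_std[None, :, None]
        m = x_shape[0] * x_shape[2]
        sum_dxhat = dxhat.sum(axis=(0, 2), keepdims=True)
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        return (inv_std[None, :, None] / m) * (m * dxhat - sum_dxhat - xhat * sum_dxhat_xhat)


class ReLU(Module):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool1d(Module):
    """Non-overlapping max pooling; the length remainder is dropped."""

    def __init__(self, pool: int):
        if pool < 1:
            raise InvalidArgumentError("pool must be >= 1")
        self.pool = pool

    def out_length(self, t: int) -> int:
        if t < self.pool:
            raise InvalidArgumentError(f"input length {t} shorter than pool {self.pool}")
        return t // self.pool

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, t = x.shape
        to = t // self.pool
        xr = x[:, :, : to * self.pool].reshape(n, c, to, self.pool)
        self._argmax = xr.argmax(axis=3)
        self._in_shape = x.shape
        return xr.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, t = self._in_shape
        to = dy.shape[2]
        dx = np.zeros((n, c, to, self.pool))
        idx = np.indices((n, c, to))
        dx[idx[0], idx[1], idx[2], self._argmax] = dy
        out = np.zeros(self._in_shape)
        out[:, :, : to * self.pool] = dx.reshape(n, c, to * self.pool)
        return out


class SE1d(Module):
    """Squeeze-and-excitation channel attention.

    Squeeze: temporal mean per channel. Excitation: two-layer bottleneck
    (reduction r) with ReLU then sigmoid. The input map is rescaled channel-
    wise by the excitation in (0, 1).
    """

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator | None = None):
        if channels % reduction != 0:
            raise InvalidArgumentError(
                f"channels ({channels}) must be divisible by reduction ({reduction})"
            )
        rng = rng or np.random.default_rng(0)
        hidden = channels // reduction
        self.W1 = Param("se.W1", _he_init(rng, (hidden, channels), channels))
        self.b1 = Param("se.b1", np.zeros(hidden))
        self.W2 = Param("se.W2", _he_init(rng, (channels, hidden), hidden))
        self.b2 = Param("se.b2", np.zeros(channels))
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.W1, self.b1, self.W2, self.b2]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        s = x.mean(axis=2)  # (N, C)
        z1 = s @ self.W1.value.T + self.b1.value
        h = np.maximum(z1, 0.0)
        e = 1.0 / (1.0 + np.exp(-(h @ self.W2.value.T + self.b2.value)))
        self._cache = (x, s, z1, h, e)
        return x * e[:, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, s, z1, h, e = self._cache
        t = x.shape[2]
        de = (dy * x).sum(axis=2)
        dx = dy * e[:, :, None]
        dz2 = de * e * (1.0 - e)
        self.W2.grad += dz2.T @ h
        self.b2.grad += dz2.sum(axis=0)
        dh = dz2 @ self.W2.value
        dz1 = dh * (z1 > 0)
        self.W1.grad += dz1.T @ s
        self.b1.grad += dz1.sum(axis=0)
        ds = dz1 @ self.W1.value
        dx += ds[:, :, None] / t
        return dx


class GlobalAvgPool1d(Module):
    """Temporal mean per channel: (N, C, T) -> (N, C)."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._t = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(dy[:, :, None], self._t, axis=2) / self._t


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = Param("fc.W", _he_init(rng, (out_features, in_features), in_features))
        self.b = Param("fc.b", np.zeros(out_features))

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value


class ResidualBlock1d(Module):
    """Two convolutions with BN/ReLU plus a projected, cropped shortcut.

    The shortcut is a strided 1x1 convolution (plus BN) left-cropped to the
    main path's length — valid convolutions shorten the main path more than
    the 1x1 projection, and left-cropping aligns the two paths' receptive-
    field starts.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int = 3,
        stride: int = 2,
        batch_norm: bool = True,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.conv1 = Conv1d(in_channels, out_channels, kernel, stride, rng)
        self.conv2 = Conv1d(out_channels, out_channels, kernel, 1, rng)
        self.proj = Conv1d(in_channels, out_channels, 1, stride, rng)
        self.batch_norm = batch_norm
        if batch_norm:
            self.bn1 = BatchNorm1d(out_channels)
            self.bn2 = BatchNorm1d(out_channels)
            self.bn_proj = BatchNorm1d(out_channels)
        self.relu_mid = ReLU()
        self.relu_out = ReLU()

    def params(self) -> list[Param]:
        out = self.conv1.params() + self.conv2.params() + self.proj.params()
        if self.batch_norm:
            out += self.bn1.params() + self.bn2.params() + self.bn_proj.params()
        return out

    def out_length(self, t: int) -> int:
        return self.conv2.out_length(self.conv1.out_length(t))

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        h = self.conv1.forward(x, training)
        if self.batch_norm:
            h = self.bn1.forward(h, training)
        h = self.relu_mid.forward(h, training)
        h = self.conv2.forward(h, training)
        if self.batch_norm:
            h = self.bn2.forward(h, training)
        s = self.proj.forward(x, training)
        if self.batch_norm:
            s = self.bn_proj.forward(s, training)
        self._crop = h.shape[2]
        self._s_len = s.shape[2]
        return self.relu_out.forward(h + s[:, :, : self._crop], training)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dsum = self.relu_out.backward(dy)
        ds_full = np.zeros((dsum.shape[0], dsum.shape[1], self._s_len))
        ds_full[:, :, : self._crop] = dsum
        if self.batch_norm:
            ds_full = self.bn_proj.backward(ds_full)
        dx = self.proj.backward(ds_full)
        dh = dsum
        if self.batch_norm:
            dh = self.bn2.backward(dh)
        dh = self.conv2.backward(dh)
        dh = self.relu_mid.backward(dh)
        if self.batch_norm:
            dh = self.bn1.backward(dh)
        dx += self.conv1.backward(dh)
        return dx


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def params(self) -> list[Param]:
        return [p for m in self.modules for p in m.params()]

    def out_length(self, t: int) -> int:
        for m in self.modules:
            t = m.out_length(t)
        return t

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for m in self.modules:
            x = m.forward(x, training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for m in reversed(self.modules):
            dy = m.backward(dy)
        return dy


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and gradient w.r.t. logits."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = float(-np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean())
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class Adam:
    """Adam optimiser over a list of Params."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * p.grad
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * p.grad**2
            mhat = self.m[i] / (1 - self.beta1**self.t)
            vhat = self.v[i] / (1 - self.beta2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
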