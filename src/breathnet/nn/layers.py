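"""Layers for 1D convolutional networks, with hand-derived backprop.

Conventions: activations are ``(N, T, C)`` for temporal layers and
``(N, D)`` after flattening; parameters live in ``self.params`` with
matching gradients in ``self.grads`` after ``backward``. L2 regularization
is applied as weight decay on conv/dense kernels during ``backward``
(gradient contribution ``2 * l2 * W``), matching a ``l2 * sum(W**2)``
penalty added to the loss.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Layer:
    """Base layer: forward/backward pair with named params and grads."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def param_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    @property
    def sublayers(self) -> list["Layer"]:
        return []


def _he_init(shape: tuple[int, ...], fan_in: int, rng: np.random.Generator, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv1D(Layer):
    """1D convolution with 'same' padding: output length = ceil(T / stride)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        stride: int = 1,
        l2: float = 0.0,
        rng: np.random.Generator | None = None,
        dtype=DTYPE,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.l2 = l2
        self.params["W"] = _he_init(
            (kernel, in_channels, out_channels), kernel * in_channels, rng, dtype
        )
        self.params["b"] = np.zeros(out_channels, dtype=dtype)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, t, c = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        k, s = self.kernel, self.stride
        out_t = -(-t // s)  # ceil
        pad_total = max((out_t - 1) * s + k - t, 0)
        pad_left = pad_total // 2
        xp = np.pad(x, ((0, 0), (pad_left, pad_total - pad_left), (0, 0)))
        # (N, T_p - K + 1, C, K) view, strided along time, then (N, out_T, K, C)
        windows = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)[:, ::s]
        cols = windows.transpose(0, 1, 3, 2).reshape(n * out_t, k * c)
        wf = self.params["W"].reshape(k * c, self.out_channels)
        y = cols @ wf + self.params["b"]
        self._cache = (cols, (n, t, c), pad_left, xp.shape[1], out_t)
        return y.reshape(n, out_t, self.out_channels)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, (n, t, c), pad_left, t_padded, out_t = self._cache
        k, s = self.kernel, self.stride
        dyf = dy.reshape(n * out_t, self.out_channels)
        dw = (cols.T @ dyf).reshape(k, c, self.out_channels)
        if self.l2:
            dw = dw + 2.0 * self.l2 * self.params["W"]
        self.grads["W"] = dw
        self.grads["b"] = dyf.sum(axis=0)
        dcols = (dyf @ self.params["W"].reshape(k * c, -1).T).reshape(n, out_t, k, c)
        dxp = np.zeros((n, t_padded, c), dtype=dy.dtype)
        for kk in range(k):
            dxp[:, kk : kk + s * out_t : s, :] += dcols[:, :, kk, :]
        return dxp[:, pad_left : pad_left + t, :]


class BatchNorm1D(Layer):
    """Batch normalization over all axes but the channel (last) axis."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5, dtype=DTYPE) -> None:
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(channels, dtype=dtype)
        self.params["beta"] = np.zeros(channels, dtype=dtype)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mu).astype(
                self.running_mean.dtype
            )
            self.running_var = (m * self.running_var + (1 - m) * var).astype(
                self.running_var.dtype
            )
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        self._cache = (xhat, inv_std, x.shape, axes, training)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std, shape, axes, training = self._cache
        self.grads["gamma"] = (dy * xhat).sum(axis=axes)
        self.grads["beta"] = dy.sum(axis=axes)
        g = self.params["gamma"]
        if not training:
            return dy * g * inv_std
        m = np.prod([shape[a] for a in axes])
        dxhat = dy * g
        return (
            inv_std
            / m
            * (m * dxhat - dxhat.sum(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes))
        )


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool1D(Layer):
    """Non-overlapping temporal max pooling; a trailing remainder is dropped."""

    def __init__(self, pool: int = 2) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, t, c = x.shape
        p = self.pool
        t_out = t // p
        xr = x[:, : t_out * p].reshape(n, t_out, p, c)
        self._idx = xr.argmax(axis=2)
        self._in_shape = (n, t, c)
        return np.take_along_axis(xr, self._idx[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, t, c = self._in_shape
        p = self.pool
        t_out = t // p
        dxr = np.zeros((n, t_out, p, c), dtype=dy.dtype)
        np.put_along_axis(dxr, self._idx[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros((n, t, c), dtype=dy.dtype)
        dx[:, : t_out * p] = dxr.reshape(n, t_out * p, c)
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        l2: float = 0.0,
        rng: np.random.Generator | None = None,
        dtype=DTYPE,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_features = in_features
        self.out_features = out_features
        self.l2 = l2
        self.params["W"] = _he_init((in_features, out_features), in_features, rng, dtype)
        self.params["b"] = np.zeros(out_features, dtype=dtype)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dw = self._x.T @ dy
        if self.l2:
            dw = dw + 2.0 * self.l2 * self.params["W"]
        self.grads["W"] = dw
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class TimeDistributedDense(Layer):
    """The same dense map applied independently at every time step."""

    def __init__(
        self,
        in_features: int,
        out_features: int,
        l2: float = 0.0,
        rng: np.random.Generator | None = None,
        dtype=DTYPE,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_features = in_features
        self.out_features = out_features
        self.l2 = l2
        self.params["W"] = _he_init((in_features, out_features), in_features, rng, dtype)
        self.params["b"] = np.zeros(out_features, dtype=dtype)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, t, _ = self._x.shape
        dw = self._x.reshape(n * t, -1).T @ dy.reshape(n * t, -1)
        if self.l2:
            dw = dw + 2.0 * self.l2 * self.params["W"]
        self.grads["W"] = dw
        self.grads["b"] = dy.reshape(n * t, -1).sum(axis=0)
        return dy @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout; active only in training mode, seeded via ``rng``."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class ResidualBlock1D(Layer):
    """Two convolutions with an identity (or projected) shortcut.

    conv(stride) -> BN -> ReLU -> conv(1) -> BN, added to the shortcut and
    passed through a final ReLU. The shortcut is a 1x1 strided projection
    whenever the width or temporal resolution changes.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        stride: int = 1,
        l2: float = 0.0,
        rng: np.random.Generator | None = None,
        dtype=DTYPE,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.conv1 = Conv1D(in_channels, out_channels, kernel, stride, l2, rng, dtype)
        self.bn1 = BatchNorm1D(out_channels, dtype=dtype)
        self.relu1 = ReLU()
        self.conv2 = Conv1D(out_channels, out_channels, kernel, 1, l2, rng, dtype)
        self.bn2 = BatchNorm1D(out_channels, dtype=dtype)
        self.projection: Conv1D | None = None
        if stride != 1 or in_channels != out_channels:
            self.projection = Conv1D(in_channels, out_channels, 1, stride, l2, rng, dtype)

    @property
    def sublayers(self) -> list[Layer]:
        subs = [self.conv1, self.bn1, self.relu1, self.conv2, self.bn2]
        if self.projection is not None:
            subs.append(self.projection)
        return subs

    def param_count(self) -> int:
        return sum(layer.param_count() for layer in self.sublayers)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        h = self.conv1.forward(x, training)
        h = self.bn1.forward(h, training)
        h = self.relu1.forward(h, training)
        h = self.conv2.forward(h, training)
        h = self.bn2.forward(h, training)
        s = x if self.projection is None else self.projection.forward(x, training)
        y = h + s
        self._out_mask = y > 0
        return y * self._out_mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = dy * self._out_mask
        dh = self.bn2.backward(d)
        dh = self.conv2.backward(dh)
        dh = self.relu1.backward(dh)
        dh = self.bn1.backward(dh)
        dx = self.conv1.backward(dh)
        ds = d if self.projection is None else self.projection.backward(d)
        return dx + ds
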