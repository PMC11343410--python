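"""Minimal NumPy layer zoo with hand-written backpropagation.

All activations use channels-last float32 tensors of shape (N, H, W, C) so
that convolutions reduce to one large BLAS matrix product per layer
(im2col followed by a GEMM against a (9*C_in, C_out) kernel matrix).
Each layer caches what its backward pass needs; ``backward`` consumes the
upstream gradient and accumulates parameter gradients in ``.grads``.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Layer:
    """Base class: parameterless layers leave ``params``/``grads`` empty."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def out_shape(self, shape: tuple[int, ...]) -> tuple[int, ...]:
        return shape


class Conv2d(Layer):
    """Zero-padded 2D convolution (same spatial size for odd kernels)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 leaky_slope: float = 0.01) -> None:
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, k
        fan_in = c_in * k * k
        # He init adjusted for the leaky ReLU gain
        gain = np.sqrt(2.0 / (1.0 + leaky_slope**2))
        std = gain / np.sqrt(fan_in)
        self.params["w"] = rng.normal(0.0, std, (k * k * c_in, c_out)).astype(F32)
        self.params["b"] = np.zeros(c_out, dtype=F32)
        self._col: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        col = np.empty((n, h, w, self.k * self.k * c), dtype=F32)
        idx = 0
        for i in range(self.k):
            for j in range(self.k):
                col[..., idx * c : (idx + 1) * c] = xp[:, i : i + h, j : j + w, :]
                idx += 1
        return col

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, _ = x.shape
        col = self._im2col(x)
        y = col.reshape(-1, col.shape[-1]) @ self.params["w"]
        y += self.params["b"]
        self._col = col if train else None
        self._in_shape = x.shape
        return y.reshape(n, h, w, self.c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._col is not None and self._in_shape is not None
        n, h, w, c = self._in_shape
        dy2 = dy.reshape(-1, self.c_out)
        col2 = self._col.reshape(-1, self._col.shape[-1])
        self.grads["w"] = self.grads.get("w", 0) + col2.T @ dy2
        self.grads["b"] = self.grads.get("b", 0) + dy2.sum(axis=0)
        dcol = (dy2 @ self.params["w"].T).reshape(n, h, w, -1)
        p = self.k // 2
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=F32)
        idx = 0
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, i : i + h, j : j + w, :] += dcol[..., idx * c : (idx + 1) * c]
                idx += 1
        self._col = None
        return dxp[:, p : p + h, p : p + w, :] if p else dxp

    def out_shape(self, shape):
        n, h, w, _ = shape
        return (n, h, w, self.c_out)


class BatchNorm(Layer):
    """Per-channel batch normalisation with running statistics.

    Training uses batch statistics and updates the running mean/variance;
    evaluation uses the running statistics only, making inference
    deterministic.
    """

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.params["gamma"] = np.ones(c, dtype=F32)
        self.params["beta"] = np.zeros(c, dtype=F32)
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            axes = (0, 1, 2)
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(F32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        y = xhat * self.params["gamma"] + self.params["beta"]
        if train:
            self._cache = (xhat.astype(F32), inv.astype(F32))
        return y.astype(F32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        m = dy.shape[0] * dy.shape[1] * dy.shape[2]
        axes = (0, 1, 2)
        self.grads["gamma"] = self.grads.get("gamma", 0) + (dy * xhat).sum(axis=axes)
        self.grads["beta"] = self.grads.get("beta", 0) + dy.sum(axis=axes)
        g = self.params["gamma"]
        dxhat = dy * g
        dx = (
            dxhat - dxhat.mean(axis=axes) - xhat * (dxhat * xhat).mean(axis=axes)
        ) * inv
        self._cache = None
        return dx.astype(F32)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01) -> None:
        super().__init__()
        self.slope = slope
        self._mask = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        mask = x > 0
        y = np.where(mask, x, self.slope * x)
        if train:
            self._mask = mask
        return y.astype(F32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.where(self._mask, dy, self.slope * dy)
        self._mask = None
        return dx.astype(F32)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2 (ties route to the first max in scan order)."""

    def __init__(self) -> None:
        super().__init__()
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        assert h % 2 == 0 and w % 2 == 0, "spatial size must be even"
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        xr = xr.reshape(n, h // 2, w // 2, c, 4)
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape)
        return y.astype(F32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, (n, h, w, c) = self._cache
        dxr = np.zeros((n, h // 2, w // 2, c, 4), dtype=F32)
        np.put_along_axis(dxr, idx[..., None], dy[..., None].astype(F32), axis=-1)
        dx = (
            dxr.reshape(n, h // 2, w // 2, c, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, h, w, c)
        )
        self._cache = None
        return dx

    def out_shape(self, shape):
        n, h, w, c = shape
        return (n, h // 2, w // 2, c)


def _up1d(x: np.ndarray, axis: int) -> np.ndarray:
    """Bilinear 2x upsampling along one axis (half-pixel centres)."""
    x = np.moveaxis(x, axis, 1)
    k = x.shape[1]
    prev = x[:, np.r_[0, 0 : k - 1]]       # x[max(k-1, 0)]
    nxt = x[:, np.r_[1:k, k - 1]]          # x[min(k+1, K-1)]
    even = 0.75 * x + 0.25 * prev
    odd = 0.75 * x + 0.25 * nxt
    out = np.empty((x.shape[0], 2 * k) + x.shape[2:], dtype=F32)
    out[:, 0::2] = even
    out[:, 1::2] = odd
    return np.moveaxis(out, 1, axis)


def _up1d_T(dy: np.ndarray, axis: int) -> np.ndarray:
    """Transpose (adjoint) of :func:`_up1d` for the backward pass."""
    dy = np.moveaxis(dy, axis, 1)
    de = dy[:, 0::2]
    do = dy[:, 1::2]
    k = de.shape[1]
    dx = 0.75 * (de + do)
    dx[:, : k - 1] += 0.25 * de[:, 1:]     # even out[k+1] drew on x[k]
    dx[:, 0] += 0.25 * de[:, 0]            # clamped boundary
    dx[:, 1:] += 0.25 * do[:, : k - 1]     # odd out[k-1] drew on x[k]
    dx[:, k - 1] += 0.25 * do[:, k - 1]
    return np.moveaxis(dx.astype(F32), 1, axis)


class BilinearUp2(Layer):
    """Separable bilinear 2x upsampling (half-pixel alignment)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return _up1d(_up1d(x, 1), 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return _up1d_T(_up1d_T(dy, 2), 1)

    def out_shape(self, shape):
        n, h, w, c = shape
        return (n, 2 * h, 2 * w, c)


class Adam:
    """Adam over a list of (params, grads) dicts shared with the layers."""

    def __init__(self, layers, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [
            {k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers
        ]
        self.v = [
            {k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers
        ]

    def step(self) -> None:
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for layer, m, v in zip(self.layers, self.m, self.v):
            for k, p in layer.params.items():
                g = layer.grads.get(k)
                if g is None:
                    continue
                g = g.astype(F32)
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g * g
                p -= self.lr * (m[k] / bc1) / (np.sqrt(v[k] / bc2) + self.eps)

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.grads.clear()
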