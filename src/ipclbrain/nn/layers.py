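"""Minimal CPU layer library: conv, group norm, pooling, linear, L2 head.

All layers operate on float32 ``numpy`` arrays with shape ``(N, C, H, W)``
(convolutional) or ``(N, D)`` (fully connected). Each layer caches what its
backward pass needs during ``forward``; ``backward`` consumes the cache and
accumulates parameter gradients in-place.
"""
from __future__ import annotations

import numpy as np

from ..errors import ConfigurationError


class Parameter:
    """A learnable array with an accumulated gradient."""

    __slots__ = ("name", "data", "grad")

    def __init__(self, name: str, data: np.ndarray):
        self.name = name
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base layer: stateless unless it declares parameters or buffers."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[Parameter]:
        return []

    def buffers(self) -> dict[str, np.ndarray]:
        """Non-learnable persistent state (e.g. running statistics)."""
        return {}


def _im2col(xp: np.ndarray, k: int, stride: int):
    """Extract sliding k x k patches: (N, OH*OW, C*k*k), channel-major."""
    view = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    view = view[:, :, ::stride, ::stride]
    n, c, oh, ow = view.shape[:4]
    cols = view.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh * ow, c * k * k)
    return np.ascontiguousarray(cols), oh, ow


def _col2im(dcols: np.ndarray, padded_shape, k: int, stride: int, oh: int, ow: int):
    n, c, hp, wp = padded_shape
    dxp = np.zeros((n, c, hp, wp), dtype=dcols.dtype)
    d = dcols.reshape(n, oh, ow, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += d[
                :, :, :, :, i, j
            ]
    return dxp


class Conv2d(Layer):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel_size * kernel_size
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, fan_in))
        self.weight = Parameter("weight", w)
        self.bias = Parameter("bias", np.zeros(out_channels))
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self._cache = None

    def forward(self, x, train=False):
        k, s, p = self.kernel_size, self.stride, self.padding
        if p:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        else:
            xp = x
        cols, oh, ow = _im2col(xp, k, s)
        out = cols @ self.weight.data.T + self.bias.data
        self._cache = (cols, xp.shape, oh, ow) if train else None
        n = x.shape[0]
        return np.ascontiguousarray(out.transpose(0, 2, 1).reshape(n, self.out_channels, oh, ow))

    def backward(self, grad):
        cols, padded_shape, oh, ow = self._cache
        n = grad.shape[0]
        g2 = grad.reshape(n, self.out_channels, oh * ow).transpose(0, 2, 1)
        self.weight.grad += np.einsum("npo,npk->ok", g2, cols, optimize=True)
        self.bias.grad += g2.sum(axis=(0, 1))
        dcols = g2 @ self.weight.data
        dxp = _col2im(dcols, padded_shape, self.kernel_size, self.stride, oh, ow)
        p = self.padding
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp

    def parameters(self):
        return [self.weight, self.bias]


class GroupNorm(Layer):
    """Normalizes groups of channels per sample; affine scale/shift per channel.

    Accepts (N, C) or (N, C, H, W). With default affine parameters (gamma=1,
    beta=0) the output has zero mean / unit variance within each (sample,
    group) slice.
    """

    def __init__(self, num_groups: int, num_channels: int, eps: float = 1e-5):
        if num_channels % num_groups != 0:
            raise ConfigurationError(
                f"norm_groups={num_groups} does not divide channels={num_channels}"
            )
        self.num_groups = num_groups
        self.num_channels = num_channels
        self.eps = eps
        self.gamma = Parameter("gamma", np.ones(num_channels))
        self.beta = Parameter("beta", np.zeros(num_channels))
        self._cache = None

    def _group_view(self, x):
        n = x.shape[0]
        return x.reshape(n, self.num_groups, -1)

    def forward(self, x, train=False):
        shape = x.shape
        g = self._group_view(x)
        mean = g.mean(axis=2, keepdims=True)
        var = g.var(axis=2, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (g - mean) * inv
        xhat = xhat.reshape(shape)
        if x.ndim == 4:
            gamma = self.gamma.data[None, :, None, None]
            beta = self.beta.data[None, :, None, None]
        else:
            gamma = self.gamma.data[None, :]
            beta = self.beta.data[None, :]
        if train:
            self._cache = (xhat, inv, shape)
        return xhat * gamma + beta

    def backward(self, grad):
        xhat, inv, shape = self._cache
        if grad.ndim == 4:
            axes = (0, 2, 3)
            gamma = self.gamma.data[None, :, None, None]
        else:
            axes = (0,)
            gamma = self.gamma.data[None, :]
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        dxhat = self._group_view(grad * gamma)
        xh = self._group_view(xhat)
        m1 = dxhat.mean(axis=2, keepdims=True)
        m2 = (dxhat * xh).mean(axis=2, keepdims=True)
        dx = inv * (dxhat - m1 - xh * m2)
        return dx.reshape(shape)

    def parameters(self):
        return [self.gamma, self.beta]


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, grad):
        return grad * self._mask


class MaxPool2d(Layer):
    """Max pooling with possibly overlapping windows (e.g. k=3, stride=2)."""

    def __init__(self, kernel_size: int, stride: int | None = None):
        self.kernel_size = kernel_size
        self.stride = stride or kernel_size
        self._cache = None

    def forward(self, x, train=False):
        k, s = self.kernel_size, self.stride
        view = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        view = view[:, :, ::s, ::s]
        n, c, oh, ow = view.shape[:4]
        flat = view.reshape(n, c, oh, ow, k * k)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape, oh, ow)
        return np.ascontiguousarray(out)

    def backward(self, grad):
        idx, xshape, oh, ow = self._cache
        k, s = self.kernel_size, self.stride
        n, c, h, w = xshape
        di, dj = idx // k, idx % k
        rows = (np.arange(oh) * s)[None, None, :, None] + di
        cols = (np.arange(ow) * s)[None, None, None, :] + dj
        dx = np.zeros(xshape, dtype=grad.dtype)
        nn_idx = np.arange(n)[:, None, None, None]
        cc_idx = np.arange(c)[None, :, None, None]
        flat_index = ((nn_idx * c + cc_idx) * h + rows) * w + cols
        np.add.at(dx.reshape(-1), flat_index.ravel(), grad.ravel())
        return dx

    def parameters(self):
        return []


class Flatten(Layer):
    """(N, C, H, W) -> (N, C*H*W); channel-major, then spatial row-major."""

    def __init__(self):
        self._shape = None

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / in_features), size=(out_features, in_features))
        self.weight = Parameter("weight", w)
        self.bias = Parameter("bias", np.zeros(out_features))
        self.in_features = in_features
        self.out_features = out_features
        self._x = None

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, grad):
        self.weight.grad += grad.T @ self._x
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.data

    def parameters(self):
        return [self.weight, self.bias]


class BatchCenter(Layer):
    """Centers features across the batch; running mean applied in eval mode.

    Placed before an L2 projection this removes the shared (image-
    independent) component of the embedding each step, so the encoder cannot
    satisfy the view-alignment pressure by mapping all inputs to one point —
    the degenerate optimum of small-scale contrastive training.
    """

    def __init__(self, dim: int, momentum: float = 0.9):
        self.dim = dim
        self.momentum = momentum
        self.running_mean = np.zeros(dim, dtype=np.float32)
        self.initialized = False

    def forward(self, x, train=False):
        if train:
            mu = x.mean(axis=0)
            if not self.initialized:
                self.running_mean[...] = mu
                self.initialized = True
            else:
                self.running_mean[...] = (
                    self.momentum * self.running_mean + (1 - self.momentum) * mu
                )
            return x - mu
        return x - self.running_mean

    def backward(self, grad):
        return grad - grad.mean(axis=0)

    def buffers(self):
        return {
            "running_mean": self.running_mean,
            "initialized": np.asarray([1.0 if self.initialized else 0.0],
                                      dtype=np.float32),
        }

    def load_buffers(self, buffers: dict) -> None:
        self.running_mean[...] = buffers["running_mean"]
        self.initialized = bool(buffers["initialized"][0])


class L2Normalize(Layer):
    """Projects each row to the unit hypersphere."""

    def __init__(self, eps: float = 1e-12):
        self.eps = eps
        self._cache = None

    def forward(self, x, train=False):
        norm = np.sqrt((x * x).sum(axis=1, keepdims=True)) + self.eps
        z = x / norm
        if train:
            self._cache = (z, norm)
        return z

    def backward(self, grad):
        z, norm = self._cache
        return (grad - (grad * z).sum(axis=1, keepdims=True) * z) / norm
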