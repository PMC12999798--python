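"""Minimal NumPy neural-network core for small 3D convolutional models.

Implements exactly the layers the classification networks need — 3D
convolution (strided, dilated, per-axis padding), instance normalization,
ReLU, global average pooling, linear layers, dropout — each with an explicit
backward pass, plus He initialization, Adam, and a softmax cross-entropy
loss.  Every layer caches what its backward pass needs during ``forward``;
``backward`` consumes the upstream gradient and accumulates parameter
gradients in place.

Tensors are ``float32`` with layout ``(N, C, D, H, W)`` for volumetric data
and ``(N, F)`` for vectors.
"""

from __future__ import annotations

import itertools

import numpy as np

__all__ = [
    "Param",
    "Module",
    "Conv3d",
    "InstanceNorm3d",
    "ReLU",
    "GlobalAvgPool3d",
    "Flatten",
    "Linear",
    "Dropout",
    "Sequential",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
    "he_normal",
]


def he_normal(shape, fan_in, rng):
    """He (Kaiming) normal initialization: N(0, sqrt(2 / fan_in))."""
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Param:
    """A trainable array with an accumulated gradient."""

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
    """Base class: parameter discovery and train/eval mode switching."""

    training: bool = True

    def params(self) -> list[Param]:
        found: list[Param] = []
        for value in vars(self).values():
            if isinstance(value, Param):
                found.append(value)
            elif isinstance(value, Module):
                found.extend(value.params())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        found.extend(item.params())
        return found

    def submodules(self) -> list["Module"]:
        subs: list[Module] = []
        for value in vars(self).values():
            if isinstance(value, Module):
                subs.append(value)
            elif isinstance(value, (list, tuple)):
                subs.extend(item for item in value if isinstance(item, Module))
        return subs

    def set_training(self, mode: bool) -> None:
        self.training = mode
        for sub in self.submodules():
            sub.set_training(mode)

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)

    # --- state (de)serialization -------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.params()]

    def load_state_arrays(self, arrays) -> None:
        own = self.params()
        if len(arrays) != len(own):
            raise ValueError(
                f"state mismatch: module has {len(own)} parameter arrays, "
                f"got {len(arrays)}"
            )
        for p, a in zip(own, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch: {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float32).copy()
            p.grad = np.zeros_like(p.data)


def _triple(v) -> tuple[int, int, int]:
    if np.isscalar(v):
        return (int(v),) * 3
    t = tuple(int(x) for x in v)
    if len(t) != 3:
        raise ValueError(f"expected a scalar or length-3 value, got {v!r}")
    return t


class Conv3d(Module):
    """3D convolution with stride, dilation and per-axis zero padding.

    The forward pass gathers one strided view of the padded input per
    kernel offset and reduces the stacked views with a single matrix
    product; the backward pass scatters gradients back through the same
    views, so no explicit im2col buffer copy is needed on the way back.
    """

    def __init__(self, in_channels, out_channels, kernel_size=3, stride=1,
                 padding=1, dilation=1, bias=True, rng=None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_channels = int(in_channels)
        self.out_channels = int(out_channels)
        self.kernel_size = _triple(kernel_size)
        self.stride = _triple(stride)
        self.padding = _triple(padding)
        self.dilation = _triple(dilation)
        k3 = int(np.prod(self.kernel_size))
        fan_in = self.in_channels * k3
        # weight layout (out_c, kd, kh, kw, in_c): kernel offset outer,
        # channel inner, matching the stacked-view flattening below
        self.weight = Param(
            he_normal((self.out_channels,) + self.kernel_size + (self.in_channels,),
                      fan_in, rng))
        self.bias = Param(np.zeros(self.out_channels, dtype=np.float32)) if bias else None
        self._cache = None

    def out_shape(self, spatial) -> tuple[int, int, int]:
        out = []
        for size, k, s, p, d in zip(spatial, self.kernel_size, self.stride,
                                    self.padding, self.dilation):
            span = (k - 1) * d + 1
            o = (size + 2 * p - span) // s + 1
            if o < 1:
                raise ValueError(
                    f"spatial size {size} too small for kernel {k} "
                    f"(dilation {d}, padding {p})")
            out.append(o)
        return tuple(out)

    def _offset_slices(self, out_sp):
        s, d = self.stride, self.dilation
        for (i, j, l) in itertools.product(*(range(k) for k in self.kernel_size)):
            yield (
                slice(i * d[0], i * d[0] + s[0] * out_sp[0], s[0]),
                slice(j * d[1], j * d[1] + s[1] * out_sp[1], s[1]),
                slice(l * d[2], l * d[2] + s[2] * out_sp[2], s[2]),
            )

    def forward(self, x):
        n, c = x.shape[:2]
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        p = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p[0], p[0]), (p[1], p[1]), (p[2], p[2])))
        out_sp = self.out_shape(x.shape[2:])
        views = [xp[:, :, sl[0], sl[1], sl[2]] for sl in self._offset_slices(out_sp)]
        # (N, k3, C, oD, oH, oW) -> (N, k3*C, OV)
        patches = np.stack(views, axis=1)
        k3 = len(views)
        ov = int(np.prod(out_sp))
        cols = patches.reshape(n, k3 * c, ov)
        w2 = self.weight.data.reshape(self.out_channels, k3 * c)
        out = np.matmul(w2[None], cols)  # (N, out_c, OV)
        if self.bias is not None:
            out += self.bias.data[None, :, None]
        self._cache = (x.shape, xp.shape, cols, out_sp)
        return np.ascontiguousarray(out.reshape(n, self.out_channels, *out_sp))

    def backward(self, dy):
        x_shape, xp_shape, cols, out_sp = self._cache
        n, c = x_shape[:2]
        k3 = int(np.prod(self.kernel_size))
        ov = int(np.prod(out_sp))
        dyf = dy.reshape(n, self.out_channels, ov)
        w2 = self.weight.data.reshape(self.out_channels, k3 * c)
        self.weight.grad += np.einsum("nov,ncv->oc", dyf, cols,
                                      optimize=True).reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += dyf.sum(axis=(0, 2))
        dcols = np.matmul(w2.T[None], dyf)  # (N, k3*C, OV)
        dpatches = dcols.reshape(n, k3, c, *out_sp)
        dxp = np.zeros(xp_shape, dtype=np.float32)
        for idx, sl in enumerate(self._offset_slices(out_sp)):
            dxp[:, :, sl[0], sl[1], sl[2]] += dpatches[:, idx]
        p = self.padding
        d, h, w = x_shape[2:]
        return dxp[:, :, p[0]:p[0] + d, p[1]:p[1] + h, p[2]:p[2] + w]


class InstanceNorm3d(Module):
    """Per-sample, per-channel normalization over the spatial axes.

    Batch-size independent, so a model behaves identically at batch size 1
    during inference and at the training batch size.
    """

    def __init__(self, channels, eps=1e-5):
        self.channels = int(channels)
        self.eps = float(eps)
        self.gamma = Param(np.ones((1, channels, 1, 1, 1), dtype=np.float32))
        self.beta = Param(np.zeros((1, channels, 1, 1, 1), dtype=np.float32))
        self._cache = None

    def forward(self, x):
        ax = (2, 3, 4)
        mu = x.mean(axis=ax, keepdims=True)
        var = x.var(axis=ax, keepdims=True)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        self._cache = (xhat, inv_std)
        return (self.gamma.data * xhat + self.beta.data).astype(np.float32)

    def backward(self, dy):
        xhat, inv_std = self._cache
        ax = (2, 3, 4)
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3, 4), keepdims=True)
        self.beta.grad += dy.sum(axis=(0, 2, 3, 4), keepdims=True)
        dxhat = dy * self.gamma.data
        m1 = dxhat.mean(axis=ax, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=ax, keepdims=True)
        return (inv_std * (dxhat - m1 - xhat * m2)).astype(np.float32)


class ReLU(Module):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0).astype(np.float32)


class GlobalAvgPool3d(Module):
    """(N, C, D, H, W) -> (N, C) by spatial averaging."""

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4)).astype(np.float32)

    def backward(self, dy):
        n, c, d, h, w = self._shape
        scale = 1.0 / (d * h * w)
        return np.broadcast_to(
            dy[:, :, None, None, None] * scale, self._shape).astype(np.float32)


class Flatten(Module):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Linear(Module):
    def __init__(self, in_features, out_features, rng=None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.weight = Param(he_normal((out_features, in_features), in_features, rng))
        self.bias = Param(np.zeros(out_features, dtype=np.float32))
        self._cache = None

    def forward(self, x):
        self._cache = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, dy):
        x = self._cache
        self.weight.grad += dy.T @ x
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.data


class Dropout(Module):
    """Inverted dropout; active only in training mode."""

    def __init__(self, p=0.5, rng=None):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = float(p)
        self.rng = rng if rng is not None else np.random.default_rng(0)
        self._mask = None

    def forward(self, x):
        if not self.training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return (x * self._mask).astype(np.float32)

    def backward(self, dy):
        if self._mask is None:
            return dy
        return (dy * self._mask).astype(np.float32)


class Sequential(Module):
    def __init__(self, *modules):
        self.modules = list(modules)

    def forward(self, x):
        for m in self.modules:
            x = m(x)
        return x

    def backward(self, dy):
        for m in reversed(self.modules):
            dy = m.backward(dy)
        return dy


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over the batch.

    Returns ``(loss, dlogits)`` where ``dlogits`` is the gradient of the
    mean loss with respect to the logits.
    """
    n = logits.shape[0]
    probs = softmax(logits.astype(np.float64))
    eps = 1e-12
    loss = -np.log(probs[np.arange(n), labels] + eps).mean()
    dlogits = probs
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), (dlogits / n).astype(np.float32)


class Adam:
    """Adam optimizer over a fixed parameter list."""

    def __init__(self, params: list[Param], lr=1e-4, beta1=0.9, beta2=0.999,
                 eps=1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad * p.grad
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
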