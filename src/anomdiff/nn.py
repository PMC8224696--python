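"""Minimal dense/convolutional network engine on numpy.

Implements exactly the layer set the residual classifier needs — N-d
convolutions (via im2col and BLAS matrix products), batch normalization with
an optional learnable per-channel activation threshold, pooling, a dense head,
softmax-based losses and Adam — with hand-derived backward passes.  Arrays are
float32 throughout; spatial layout is channels-first: ``(batch, C, L)`` in 1-D
and ``(batch, C, H, W)`` in 2-D.

Every layer reports its trainable parameters with names and shapes, so the
whole network can be audited and counted analytically.
"""

from __future__ import annotations

import math
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Parameter",
    "Layer",
    "Conv",
    "BatchNorm",
    "Activation",
    "MaxPool",
    "AvgPoolStride2",
    "GlobalAvgPool",
    "Dense",
    "Sequential",
    "ResidualBlock",
    "Adam",
    "softmax",
    "mse_softmax_loss",
    "cross_entropy_loss",
]

DTYPE = np.float32


class Parameter:
    """A named trainable array with its gradient buffer."""

    def __init__(self, name: str, data: np.ndarray):
        self.name = name
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:  # pragma: no cover
        return f"Parameter({self.name}, shape={self.data.shape})"


class Layer:
    """Base class: forward/backward plus parameter introspection."""

    name: str = ""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> List[Parameter]:
        return []

    def param_count(self) -> int:
        return sum(p.size for p in self.parameters())


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------


class Conv(Layer):
    """N-d convolution without bias (bias is delegated to the norm layer).

    ``kernel`` is an int tuple, e.g. ``(5,)`` in 1-D or ``(3, 3)`` in 2-D;
    padding defaults to "same" (k//2 per axis) so stride-2 convolutions halve
    lengths with ceiling rounding.  Weights use He initialization.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: Tuple[int, ...],
        stride: int = 1,
        rng: Optional[np.random.Generator] = None,
        name: str = "conv",
    ):
        self.name = name
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = tuple(kernel)
        self.ndim = len(self.kernel)
        self.stride = stride
        self.pad = tuple(k // 2 for k in self.kernel)
        fan_in = in_channels * int(np.prod(self.kernel))
        scale = math.sqrt(2.0 / fan_in)
        rng = rng or np.random.default_rng(0)
        w = rng.standard_normal((out_channels, fan_in)).astype(DTYPE) * DTYPE(scale)
        self.weight = Parameter(f"{name}.weight", w)
        self._cols: Optional[np.ndarray] = None
        self._in_shape: Optional[Tuple[int, ...]] = None

    def parameters(self) -> List[Parameter]:
        return [self.weight]

    # -- im2col helpers ----------------------------------------------------
    def _im2col(self, x: np.ndarray) -> Tuple[np.ndarray, Tuple[int, ...]]:
        if self.ndim == 1:
            (k,) = self.kernel
            (p,) = self.pad
            xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
            win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)
            win = win[:, :, :: self.stride]  # (B, C, Lo, k)
            B, C, Lo, _ = win.shape
            cols = win.transpose(0, 2, 1, 3).reshape(B, Lo, C * k)
            return np.ascontiguousarray(cols), (Lo,)
        kh, kw = self.kernel
        ph, pw = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        win = win[:, :, :: self.stride, :: self.stride]  # (B, C, Ho, Wo, kh, kw)
        B, C, Ho, Wo, _, _ = win.shape
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B, Ho * Wo, C * kh * kw)
        return np.ascontiguousarray(cols), (Ho, Wo)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._in_shape = x.shape
        cols, out_sp = self._im2col(x)
        B = x.shape[0]
        n_out = int(np.prod(out_sp))
        cols2 = cols.reshape(B * n_out, -1)  # one large GEMM instead of B small ones
        self._cols = cols2 if training else None
        y = cols2 @ self.weight.data.T  # (B*n_out, Cout)
        y = y.reshape(B, n_out, self.out_channels).transpose(0, 2, 1)
        self._out_sp = out_sp
        return np.ascontiguousarray(y.reshape(B, self.out_channels, *out_sp))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._cols is not None and self._in_shape is not None
        B = grad.shape[0]
        n_out = int(np.prod(self._out_sp))
        g = np.ascontiguousarray(
            grad.reshape(B, self.out_channels, n_out).transpose(0, 2, 1)
        ).reshape(B * n_out, self.out_channels)
        self.weight.grad += g.T @ self._cols
        dcols = (g @ self.weight.data).reshape(B, n_out, -1)
        self._cols = None
        return self._col2im(dcols)

    def _col2im(self, dcols: np.ndarray) -> np.ndarray:
        B = dcols.shape[0]
        C = self.in_channels
        if self.ndim == 1:
            (k,) = self.kernel
            (p,) = self.pad
            L = self._in_shape[2]
            (Lo,) = self._out_sp
            d = dcols.reshape(B, Lo, C, k).transpose(0, 2, 1, 3)  # (B, C, Lo, k)
            dxp = np.zeros((B, C, L + 2 * p), dtype=DTYPE)
            s = self.stride
            span = s * (Lo - 1) + 1
            for j in range(k):  # taps land on regular strided slices
                dxp[:, :, j : j + span : s] += d[:, :, :, j]
            return dxp[:, :, p : p + L]
        kh, kw = self.kernel
        ph, pw = self.pad
        H, W = self._in_shape[2], self._in_shape[3]
        Ho, Wo = self._out_sp
        d = dcols.reshape(B, Ho, Wo, C, kh, kw).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((B, C, H + 2 * ph, W + 2 * pw), dtype=DTYPE)
        s = self.stride
        hspan = s * (Ho - 1) + 1
        wspan = s * (Wo - 1) + 1
        for jh in range(kh):
            for jw in range(kw):
                dxp[:, :, jh : jh + hspan : s, jw : jw + wspan : s] += d[:, :, :, :, jh, jw]
        return dxp[:, :, ph : ph + H, pw : pw + W]


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


class BatchNorm(Layer):
    """Batch normalization over (batch, spatial) per channel.

    Carries scale ``gamma`` and shift ``beta``; when ``threshold`` is set, a
    third per-channel parameter ``theta`` — the activation threshold — is
    subtracted from the normalized output, so a following activation fires
    only above a learned level.  Running statistics track the training
    batches for evaluation mode.
    """

    def __init__(
        self,
        channels: int,
        threshold: bool = True,
        zero_init: bool = False,
        momentum: float = 0.1,
        eps: float = 1e-5,
        name: str = "bn",
    ):
        self.name = name
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        init_gamma = np.zeros(channels) if zero_init else np.ones(channels)
        self.gamma = Parameter(f"{name}.gamma", init_gamma)
        self.beta = Parameter(f"{name}.beta", np.zeros(channels))
        self.theta = Parameter(f"{name}.theta", np.zeros(channels)) if threshold else None
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self._cache = None

    def parameters(self) -> List[Parameter]:
        ps = [self.gamma, self.beta]
        if self.theta is not None:
            ps.append(self.theta)
        return ps

    def _axes(self, x: np.ndarray) -> Tuple[int, ...]:
        return (0,) + tuple(range(2, x.ndim))

    def _bshape(self, x: np.ndarray) -> Tuple[int, ...]:
        return (1, self.channels) + (1,) * (x.ndim - 2)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        axes = self._axes(x)
        shape = self._bshape(x)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * inv.reshape(shape)
        if training:
            m = x.size // self.channels
            self._cache = (xhat, inv, m)
        offset = self.beta.data - (self.theta.data if self.theta is not None else 0.0)
        return self.gamma.data.reshape(shape) * xhat + offset.reshape(shape)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv, m = self._cache
        self._cache = None
        axes = self._axes(grad)
        shape = self._bshape(grad)
        dbeta = grad.sum(axis=axes)
        self.beta.grad += dbeta
        if self.theta is not None:
            self.theta.grad -= dbeta
        dgamma = (grad * xhat).sum(axis=axes)
        self.gamma.grad += dgamma
        g = grad * self.gamma.data.reshape(shape)
        dx = (
            g - g.mean(axis=axes).reshape(shape) - xhat * (g * xhat).mean(axis=axes).reshape(shape)
        ) * inv.reshape(shape)
        return dx.astype(DTYPE, copy=False)


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

_ACTS: Dict[str, Tuple[Callable, Callable]] = {
    "relu": (
        lambda x: np.maximum(x, 0.0),
        lambda x, y, g: g * (x > 0),
    ),
    "leaky_relu": (
        lambda x: np.where(x > 0, x, DTYPE(0.01) * x),
        lambda x, y, g: g * np.where(x > 0, DTYPE(1.0), DTYPE(0.01)),
    ),
    "elu": (
        lambda x: np.where(x > 0, x, np.expm1(np.minimum(x, 0.0))),
        lambda x, y, g: g * np.where(x > 0, DTYPE(1.0), y + 1.0),
    ),
    "sigmoid": (
        lambda x: 1.0 / (1.0 + np.exp(-x)),
        lambda x, y, g: g * y * (1.0 - y),
    ),
}


class Activation(Layer):
    def __init__(self, kind: str = "relu", name: str = "act"):
        if kind not in _ACTS:
            raise ValueError(f"unknown activation {kind!r}; allowed: {sorted(_ACTS)}")
        self.kind = kind
        self.name = name
        self._fwd, self._bwd = _ACTS[kind]
        self._cache = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        y = self._fwd(x).astype(DTYPE, copy=False)
        if training:
            self._cache = (x, y)
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, y = self._cache
        self._cache = None
        return self._bwd(x, y, grad).astype(DTYPE, copy=False)


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------


class MaxPool(Layer):
    """Max pooling, kernel 3 / stride 2 / padding 1 (the stem pool)."""

    def __init__(self, ndim: int, name: str = "maxpool"):
        self.ndim = ndim
        self.name = name
        self._cache = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        pad_width = ((0, 0), (0, 0)) + ((1, 1),) * self.ndim
        xp = np.pad(x, pad_width, constant_values=-np.inf)
        if self.ndim == 1:
            win = np.lib.stride_tricks.sliding_window_view(xp, 3, axis=2)[:, :, ::2]
            flat = win.reshape(*win.shape[:3], 3)
            arg = flat.argmax(axis=-1)
            y = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        else:
            win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))[
                :, :, ::2, ::2
            ]
            flat = win.reshape(*win.shape[:4], 9)
            arg = flat.argmax(axis=-1)
            y = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        if training:
            self._cache = (x.shape, arg)
        return np.ascontiguousarray(y.astype(DTYPE, copy=False))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        in_shape, arg = self._cache
        self._cache = None
        B, C = in_shape[0], in_shape[1]
        if self.ndim == 1:
            L = in_shape[2]
            dxp = np.zeros((B, C, L + 2), dtype=DTYPE)
            Lo = grad.shape[2]
            base = np.arange(Lo) * 2
            idx = base[None, None, :] + arg
            np.add.at(
                dxp,
                (np.arange(B)[:, None, None], np.arange(C)[None, :, None], idx),
                grad,
            )
            return dxp[:, :, 1 : 1 + L]
        H, W = in_shape[2], in_shape[3]
        dxp = np.zeros((B, C, H + 2, W + 2), dtype=DTYPE)
        Ho, Wo = grad.shape[2], grad.shape[3]
        hb = (np.arange(Ho) * 2)[None, None, :, None]
        wb = (np.arange(Wo) * 2)[None, None, None, :]
        ih = hb + arg // 3
        iw = wb + arg % 3
        np.add.at(
            dxp,
            (
                np.arange(B)[:, None, None, None],
                np.arange(C)[None, :, None, None],
                ih,
                iw,
            ),
            grad,
        )
        return dxp[:, :, 1 : 1 + H, 1 : 1 + W]


class AvgPoolStride2(Layer):
    """Average pooling with kernel 2 / stride 2, ceil mode.

    Used on the identity shortcut of downsampling blocks so its output length
    matches the stride-2 convolution of the main branch (ceil rounding); an
    odd tail element forms a window of its own.
    """

    def __init__(self, ndim: int, name: str = "avgpool"):
        self.ndim = ndim
        self.name = name
        self._in_shape = None

    def _pool_axis(self, x: np.ndarray, axis: int) -> np.ndarray:
        n = x.shape[axis]
        even = n - (n % 2)
        main = np.take(x, range(0, even), axis=axis)
        sh = list(main.shape)
        sh[axis] = even // 2
        sh.insert(axis + 1, 2)
        y = main.reshape(sh).mean(axis=axis + 1)
        if n % 2:
            tail = np.take(x, [n - 1], axis=axis)
            y = np.concatenate([y, tail], axis=axis)
        return y

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._in_shape = x.shape
        y = x
        for ax in range(2, 2 + self.ndim):
            y = self._pool_axis(y, ax)
        return np.ascontiguousarray(y.astype(DTYPE, copy=False))

    def _unpool_axis(self, g: np.ndarray, axis: int, n: int) -> np.ndarray:
        odd = n % 2
        main = np.take(g, range(0, g.shape[axis] - odd), axis=axis)
        out = np.repeat(main * DTYPE(0.5), 2, axis=axis)
        if odd:
            tail = np.take(g, [g.shape[axis] - 1], axis=axis)
            out = np.concatenate([out, tail], axis=axis)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = grad
        for ax in range(2, 2 + self.ndim):
            g = self._unpool_axis(g, ax, self._in_shape[ax])
        return np.ascontiguousarray(g.astype(DTYPE, copy=False))


class GlobalAvgPool(Layer):
    """Mean over all spatial axes -> (batch, channels).

    An optional per-sample validity mask (set via :meth:`set_mask` before the
    forward pass) restricts the average to positions that carry signal, so
    zero-padded tails of short inputs do not dilute the pooled features.
    """

    def __init__(self, name: str = "gap"):
        self.name = name
        self._in_shape = None
        self._mask = None  # (batch, spatial...) boolean
        self._used_mask = None

    def set_mask(self, mask: Optional[np.ndarray]) -> None:
        self._mask = mask

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._in_shape = x.shape
        if self._mask is None:
            self._used_mask = None
            return x.mean(axis=tuple(range(2, x.ndim)))
        m = self._mask.astype(DTYPE)
        counts = m.reshape(m.shape[0], -1).sum(axis=1)
        counts = np.maximum(counts, 1.0)
        w = (m / counts.reshape((-1,) + (1,) * (m.ndim - 1)))[:, None]
        self._used_mask = w  # (batch, 1, spatial...)
        return (x * w).sum(axis=tuple(range(2, x.ndim)))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        sp = self._in_shape[2:]
        g = grad.reshape(grad.shape + (1,) * len(sp))
        if self._used_mask is None:
            g = g / DTYPE(np.prod(sp))
            return np.broadcast_to(g, self._in_shape).astype(DTYPE)
        return (g * self._used_mask).astype(DTYPE)


# ---------------------------------------------------------------------------
# dense
# ---------------------------------------------------------------------------


class Dense(Layer):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: Optional[np.random.Generator] = None,
        name: str = "dense",
    ):
        self.name = name
        rng = rng or np.random.default_rng(0)
        scale = math.sqrt(1.0 / in_features)
        self.weight = Parameter(
            f"{name}.weight",
            rng.uniform(-scale, scale, (out_features, in_features)),
        )
        self.bias = Parameter(f"{name}.bias", np.zeros(out_features))
        self._x = None

    def parameters(self) -> List[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += grad.T @ self._x
        self.bias.grad += grad.sum(axis=0)
        self._x = None
        return grad @ self.weight.data


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer], name: str = "seq"):
        self.layers = list(layers)
        self.name = name

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self) -> List[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]


class ResidualBlock(Layer):
    """Basic residual unit: two convolutions plus a skip connection.

    ``main`` is conv-norm-act-conv-norm (the last norm zero-initialized so
    the unit starts as the identity); ``shortcut`` is either the identity or
    a projection (average-pool + 1x1 conv + norm on downsampling blocks).
    The post-addition activation closes the unit.
    """

    def __init__(self, main: Sequential, shortcut: Optional[Sequential], act: Activation,
                 name: str = "block"):
        self.main = main
        self.shortcut = shortcut
        self.act = act
        self.name = name

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        fx = self.main.forward(x, training)
        sx = self.shortcut.forward(x, training) if self.shortcut is not None else x
        return self.act.forward(fx + sx, training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.act.backward(grad)
        gx = self.main.backward(g)
        if self.shortcut is not None:
            gx = gx + self.shortcut.backward(g)
        else:
            gx = gx + g
        return gx

    def parameters(self) -> List[Parameter]:
        ps = self.main.parameters()
        if self.shortcut is not None:
            ps += self.shortcut.parameters()
        return ps


# ---------------------------------------------------------------------------
# losses and optimizer
# ---------------------------------------------------------------------------


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def mse_softmax_loss(logits: np.ndarray, targets: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Per-sample squared error between softmax outputs and one-hot targets.

    Returns ``(losses, dlogits)`` where ``losses[i] = sum_j (p_ij - t_ij)^2``
    and ``dlogits`` is the gradient of ``losses[i]`` w.r.t. the logits (not
    yet averaged over the batch).
    """
    p = softmax(logits)
    diff = p - targets
    losses = np.sum(diff * diff, axis=1)
    g = 2.0 * diff
    dlogits = p * (g - np.sum(g * p, axis=1, keepdims=True))
    return losses, dlogits.astype(DTYPE, copy=False)


def cross_entropy_loss(logits: np.ndarray, targets: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Per-sample cross-entropy of softmax outputs against one-hot targets."""
    p = softmax(logits)
    losses = -np.sum(targets * np.log(np.clip(p, 1e-12, None)), axis=1)
    dlogits = (p - targets).astype(DTYPE, copy=False)
    return losses, dlogits


LOSSES = {"MSE": mse_softmax_loss, "cross-entropy": cross_entropy_loss}


class Adam:
    """Adam optimizer with the standard moment estimates."""

    def __init__(
        self,
        params: Sequence[Parameter],
        lr: float = 3e-4,
        betas: Tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        lr_t = self.lr * math.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - self.b1) * (p.grad - m)
            v += (1 - self.b2) * (p.grad * p.grad - v)
            p.data -= DTYPE(lr_t) * m / (np.sqrt(v) + self.eps)
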