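"""Layers, losses and the Adam optimizer.

Tensors are ``(N, C, T, H, W)`` float arrays. Convolutions are evaluated as
a sum of strided-slice GEMMs over kernel offsets — memory-light and fast
enough on one CPU for the reduced-width models used at desk scale. Backward
passes mirror the forward algebra exactly; finite-difference tests pin them
down.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np

from ..types import ValidationError


class Parameter:
    """A trainable array with its gradient accumulator."""

    def __init__(self, data: np.ndarray, decay: bool = True):
        self.data = np.ascontiguousarray(data)
        self.grad = np.zeros_like(self.data)
        #: whether weight decay applies (disabled for norm params and biases)
        self.decay = decay

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
    """Base class: forward caches whatever backward needs."""

    training: bool = True

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def set_training(self, flag: bool) -> None:
        self.training = flag
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.set_training(flag)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.set_training(flag)

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _triple(v) -> tuple[int, int, int]:
    if np.isscalar(v):
        return (int(v),) * 3
    t = tuple(int(i) for i in v)
    if len(t) != 3:
        raise ValidationError(f"expected 3 values, got {v!r}")
    return t


class Conv3d(Module):
    """3D convolution with stride and zero padding (no dilation).

    He-normal initialization from the supplied generator. A kernel with a
    singleton time extent and inputs with T=1 make this a 2D convolution.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel,
        stride=1,
        padding=None,
        bias: bool = False,
        rng: Optional[np.random.Generator] = None,
        dtype=np.float32,
    ):
        self.kernel = _triple(kernel)
        self.stride = _triple(stride)
        if padding is None:
            padding = tuple(k // 2 for k in self.kernel)
        self.padding = _triple(padding)
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * int(np.prod(self.kernel))
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(out_channels, in_channels, *self.kernel))
        self.weight = Parameter(w.astype(dtype))
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype), decay=False) if bias else None
        self._cache = None

    def _out_shape(self, shape):
        return tuple(
            (shape[d] + 2 * self.padding[d] - self.kernel[d]) // self.stride[d] + 1
            for d in range(3)
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, *spatial = x.shape
        pt, ph, pw = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pt), (ph, ph), (pw, pw)))
        to, ho, wo = self._out_shape(spatial)
        st, sh, sw = self.stride
        w = self.weight.data
        acc = None
        for i in range(self.kernel[0]):
            for j in range(self.kernel[1]):
                for k in range(self.kernel[2]):
                    xs = xp[:, :, i : i + st * to : st, j : j + sh * ho : sh,
                            k : k + sw * wo : sw]
                    # (N,T,H,W,O) accumulation layout: one transpose at the end
                    term = np.tensordot(xs, w[:, :, i, j, k], axes=([1], [1]))
                    acc = term if acc is None else acc + term
        out = np.moveaxis(acc, -1, 1)
        if self.bias is not None:
            out = out + self.bias.data[None, :, None, None, None]
        self._cache = (xp, x.shape)
        return np.ascontiguousarray(out)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xp, x_shape = self._cache
        n, c = x_shape[0], x_shape[1]
        to, ho, wo = gout.shape[2:]
        st, sh, sw = self.stride
        pt, ph, pw = self.padding
        g = np.moveaxis(gout, 1, -1)  # (N,T,H,W,O)
        w = self.weight.data
        gxp = np.zeros_like(xp)
        for i in range(self.kernel[0]):
            for j in range(self.kernel[1]):
                for k in range(self.kernel[2]):
                    sl = (
                        slice(None), slice(None),
                        slice(i, i + st * to, st),
                        slice(j, j + sh * ho, sh),
                        slice(k, k + sw * wo, sw),
                    )
                    xs = xp[sl]
                    self.weight.grad[:, :, i, j, k] += np.tensordot(
                        g, xs, axes=([0, 1, 2, 3], [0, 2, 3, 4])
                    )
                    gxp[sl] += np.moveaxis(
                        np.tensordot(g, w[:, :, i, j, k], axes=([4], [0])), -1, 1
                    )
        if self.bias is not None:
            self.bias.grad += gout.sum(axis=(0, 2, 3, 4))
        t, h, wd = x_shape[2:]
        return gxp[:, :, pt : pt + t, ph : ph + h, pw : pw + wd]


class BatchNorm(Module):
    """Per-channel batch normalization over (N, T, H, W)."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32):
        self.gamma = Parameter(np.ones(num_features, dtype=dtype), decay=False)
        self.beta = Parameter(np.zeros(num_features, dtype=dtype), decay=False)
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(num_features, dtype=np.float64)
        self.running_var = np.ones(num_features, dtype=np.float64)
        self._cache = None

    @staticmethod
    def _expand(v: np.ndarray, ndim: int) -> np.ndarray:
        return v.reshape((1, -1) + (1,) * (ndim - 2))

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = (0,) + tuple(range(2, x.ndim))
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        inv = 1.0 / np.sqrt(var + self.eps)
        xn = (x - self._expand(mean, x.ndim)) * self._expand(inv, x.ndim)
        self._cache = (xn, inv, axes)
        return self._expand(self.gamma.data, x.ndim) * xn + self._expand(self.beta.data, x.ndim)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xn, inv, axes = self._cache
        m = float(np.prod([gout.shape[a] for a in axes]))
        self.gamma.grad += (gout * xn).sum(axis=axes)
        self.beta.grad += gout.sum(axis=axes)
        gxn = gout * self._expand(self.gamma.data, gout.ndim)
        if self.training:
            gx = (
                gxn
                - self._expand(gxn.mean(axis=axes), gout.ndim)
                - xn * self._expand((gxn * xn).mean(axis=axes), gout.ndim)
            ) * self._expand(inv, gout.ndim)
        else:
            gx = gxn * self._expand(inv, gout.ndim)
        return gx


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * self._mask


class GlobalAvgPool(Module):
    """(N, C, T, H, W) → (N, C) spatial-temporal mean."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=tuple(range(2, x.ndim)))

    def backward(self, gout: np.ndarray) -> np.ndarray:
        shape = self._shape
        scale = float(np.prod(shape[2:]))
        return np.broadcast_to(
            gout.reshape(shape[:2] + (1,) * (len(shape) - 2)), shape
        ) / scale


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: Optional[np.random.Generator] = None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        bound = np.sqrt(1.0 / in_features)
        self.weight = Parameter(
            rng.uniform(-bound, bound, size=(out_features, in_features)).astype(dtype)
        )
        self.bias = Parameter(np.zeros(out_features, dtype=dtype), decay=False)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, gout: np.ndarray) -> np.ndarray:
        self.weight.grad += gout.T @ self._x
        self.bias.grad += gout.sum(axis=0)
        return gout @ self.weight.data


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for m in self.modules:
            x = m(x)
        return x

    def backward(self, gout: np.ndarray) -> np.ndarray:
        for m in reversed(self.modules):
            gout = m.backward(gout)
        return gout


class ResidualBlock3d(Module):
    """Two 3×3×3 conv+BN with identity (or 1×1×1 projected) shortcut."""

    def __init__(self, in_channels: int, out_channels: int, stride=1,
                 rng: Optional[np.random.Generator] = None, dtype=np.float32):
        stride = _triple(stride)
        self.conv1 = Conv3d(in_channels, out_channels, 3, stride=stride, rng=rng, dtype=dtype)
        self.bn1 = BatchNorm(out_channels, dtype=dtype)
        self.relu1 = ReLU()
        self.conv2 = Conv3d(out_channels, out_channels, 3, rng=rng, dtype=dtype)
        self.bn2 = BatchNorm(out_channels, dtype=dtype)
        self.relu2 = ReLU()
        if stride != (1, 1, 1) or in_channels != out_channels:
            self.proj: Optional[Sequential] = Sequential(
                Conv3d(in_channels, out_channels, 1, stride=stride, padding=0,
                       rng=rng, dtype=dtype),
                BatchNorm(out_channels, dtype=dtype),
            )
        else:
            self.proj = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = self.relu1(self.bn1(self.conv1(x)))
        out = self.bn2(self.conv2(out))
        shortcut = self.proj(x) if self.proj is not None else x
        return self.relu2(out + shortcut)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = self.relu2.backward(gout)
        g_short = self.proj.backward(g) if self.proj is not None else g
        g_main = self.conv1.backward(
            self.bn1.backward(self.relu1.backward(self.conv2.backward(self.bn2.backward(g))))
        )
        return g_main + g_short


class Model(Module):
    """Named sequence of modules with activation/gradient capture.

    ``forward`` can record the activation at a named stage and ``backward``
    the gradient arriving there — the hooks class-activation mapping needs.
    """

    def __init__(self, stages: Sequence[tuple[str, Module]]):
        self.stages = list(stages)
        self.activations: dict[str, np.ndarray] = {}
        self.gradients: dict[str, np.ndarray] = {}
        self._capture: set[str] = set()

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for _, mod in self.stages:
            out.extend(mod.parameters())
        return out

    def set_training(self, flag: bool) -> None:
        self.training = flag
        for _, mod in self.stages:
            mod.set_training(flag)

    def stage_names(self) -> list[str]:
        return [name for name, _ in self.stages]

    def capture(self, *names: str) -> None:
        unknown = set(names) - set(self.stage_names())
        if unknown:
            raise ValidationError(f"unknown stage(s) {sorted(unknown)}; "
                                  f"available: {self.stage_names()}")
        self._capture = set(names)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for name, mod in self.stages:
            x = mod(x)
            if name in self._capture:
                self.activations[name] = x
        return x

    def backward(self, gout: np.ndarray) -> np.ndarray:
        for name, mod in reversed(self.stages):
            if name in self._capture:
                self.gradients[name] = gout
            gout = mod.backward(gout)
        return gout


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = -np.mean(np.log(np.maximum(p[np.arange(n), labels], 1e-12)))
    grad = p
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(logits.dtype)


class Adam:
    """Adam with L2 weight decay added to the gradient (skipping biases and
    normalization parameters)."""

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self.v = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad.astype(np.float64)
            if self.weight_decay and p.decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)
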