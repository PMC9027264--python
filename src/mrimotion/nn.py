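"""Minimal convolutional-network core with explicit backward passes.

Layers operate on NCHW float64 arrays and implement `forward(x,
training)` / `backward(grad_out) -> grad_in`, accumulating parameter
gradients in place.  The design goal is a small, deterministic,
CPU-only stack sufficient for the restoration and discriminator
networks: strided convolution and transposed convolution via
im2col/col2im, batch normalization with running statistics, the usual
pointwise activations, global average pooling, and Adam.  Every layer's
backward pass is verified against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Module",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "ReLU",
    "Tanh",
    "Sigmoid",
    "GlobalAvgPool",
    "Sequential",
    "Adam",
]


class Param:
    def __init__(self, value: np.ndarray, trainable: bool = True, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.trainable = trainable
        self.name = name


class Module:
    def params(self) -> list[Param]:
        return []

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.forward(x, training=training)

    def state(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping of parameters and buffers."""
        out = {}
        for i, p in enumerate(self.params()):
            out[p.name or f"p{i}"] = p.value
        return out


def _he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    """2-D convolution (cross-correlation form, the deep-learning convention)."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        stride: int = 1,
        pad: int | None = None,
        rng: np.random.Generator | None = None,
        zero_init: bool = False,
        name: str = "conv",
    ):
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch, self.k, self.stride = in_ch, out_ch, kernel, stride
        self.pad = (kernel - 1) // 2 if pad is None else pad
        fan_in = in_ch * kernel * kernel
        w = np.zeros((out_ch, in_ch, kernel, kernel)) if zero_init else _he_init(rng, (out_ch, in_ch, kernel, kernel), fan_in)
        self.w = Param(w, name=f"{name}.w")
        self.b = Param(np.zeros(out_ch), name=f"{name}.b")
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def out_size(self, n: int) -> int:
        return (n + 2 * self.pad - self.k) // self.stride + 1

    def forward(self, x, training=False):
        N, C, H, W = x.shape
        if C != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {C}")
        s, k, p = self.stride, self.k, self.pad
        Ho, Wo = self.out_size(H), self.out_size(W)
        if Ho < 1 or Wo < 1:
            raise ValueError(f"input {H}x{W} too small for kernel {k} stride {s}")
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        v = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        cols = np.ascontiguousarray(v.transpose(0, 2, 3, 1, 4, 5)).reshape(N * Ho * Wo, C * k * k)
        y = cols @ self.w.value.reshape(self.out_ch, -1).T + self.b.value
        self._cache = (cols, x.shape, xp.shape, Ho, Wo)
        return y.reshape(N, Ho, Wo, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, grad):
        cols, xshape, xpshape, Ho, Wo = self._cache
        N, C, H, W = xshape
        s, k, p = self.stride, self.k, self.pad
        g = np.ascontiguousarray(grad.transpose(0, 2, 3, 1)).reshape(-1, self.out_ch)
        self.w.grad += (g.T @ cols).reshape(self.w.value.shape)
        self.b.grad += g.sum(axis=0)
        dcols = (g @ self.w.value.reshape(self.out_ch, -1)).reshape(N, Ho, Wo, C, k, k)
        dxp = np.zeros(xpshape)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * Ho : s, j : j + s * Wo : s] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, p : p + H, p : p + W]


class ConvTranspose2d(Module):
    """Strided transposed convolution (exact adjoint of Conv2d)."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        stride: int = 2,
        pad: int = 1,
        output_pad: int = 1,
        rng: np.random.Generator | None = None,
        name: str = "convT",
    ):
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        self.stride, self.pad, self.output_pad = stride, pad, output_pad
        fan_in = in_ch * kernel * kernel
        self.w = Param(_he_init(rng, (in_ch, out_ch, kernel, kernel), fan_in), name=f"{name}.w")
        self.b = Param(np.zeros(out_ch), name=f"{name}.b")
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def out_size(self, n: int) -> int:
        return (n - 1) * self.stride - 2 * self.pad + self.k + self.output_pad

    def forward(self, x, training=False):
        N, C, H, W = x.shape
        s, k, p, op = self.stride, self.k, self.pad, self.output_pad
        Hp, Wp = (H - 1) * s + k + op, (W - 1) * s + k + op
        Ho, Wo = self.out_size(H), self.out_size(W)
        xf = np.ascontiguousarray(x.transpose(0, 2, 3, 1)).reshape(N * H * W, C)
        prod = (xf @ self.w.value.reshape(C, -1)).reshape(N, H, W, self.out_ch, k, k)
        yp = np.zeros((N, self.out_ch, Hp, Wp))
        for i in range(k):
            for j in range(k):
                yp[:, :, i : i + s * H : s, j : j + s * W : s] += prod[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        self._cache = (xf, x.shape, (Hp, Wp))
        return yp[:, :, p : p + Ho, p : p + Wo] + self.b.value[None, :, None, None]

    def backward(self, grad):
        xf, xshape, (Hp, Wp) = self._cache
        N, C, H, W = xshape
        s, k, p = self.stride, self.k, self.pad
        Ho, Wo = grad.shape[2], grad.shape[3]
        gyp = np.zeros((N, self.out_ch, Hp, Wp))
        gyp[:, :, p : p + Ho, p : p + Wo] = grad
        dprod = np.empty((N, H, W, self.out_ch, k, k))
        for i in range(k):
            for j in range(k):
                dprod[:, :, :, :, i, j] = gyp[:, :, i : i + s * H : s, j : j + s * W : s].transpose(0, 2, 3, 1)
        dpf = dprod.reshape(N * H * W, -1)
        self.w.grad += (xf.T @ dpf).reshape(self.w.value.shape)
        self.b.grad += grad.sum(axis=(0, 2, 3))
        dx = dpf @ self.w.value.reshape(C, -1).T
        return dx.reshape(N, H, W, C).transpose(0, 3, 1, 2)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5, name: str = "bn"):
        self.gamma = Param(np.ones(channels), name=f"{name}.gamma")
        self.beta = Param(np.zeros(channels), name=f"{name}.beta")
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        ivstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * ivstd[None, :, None, None]
        self._cache = (xhat, ivstd, training, x.shape)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, grad):
        xhat, ivstd, training, shape = self._cache
        N, C, H, W = shape
        m = N * H * W
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.value[None, :, None, None]
        if not training:
            return g * ivstd[None, :, None, None]
        sg = g.sum(axis=(0, 2, 3))[None, :, None, None]
        sgx = (g * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return (g - sg / m - xhat * sgx / m) * ivstd[None, :, None, None]


class ReLU(Module):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Tanh(Module):
    def forward(self, x, training=False):
        self._y = np.tanh(x)
        return self._y

    def backward(self, grad):
        return grad * (1.0 - self._y**2)


class Sigmoid(Module):
    def forward(self, x, training=False):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class GlobalAvgPool(Module):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        N, C, H, W = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / (H * W)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, training=False):
        for l in self.layers:
            x = l.forward(x, training=training)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-4, betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.trainable]
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
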