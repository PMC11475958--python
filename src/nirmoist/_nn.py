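"""Minimal 1-D neural-network layers with manual backpropagation.

Self-contained numpy building blocks for the spectral regressors: 1-D
convolution, max pooling, batch normalisation, dense layers, residual
blocks, and an Adam optimiser.  Tensors use channels-last layout
``(batch, length, channels)`` so convolutions reduce to a handful of
GEMMs over shifted views; everything runs in float32 and is fully
deterministic for a fixed numpy Generator.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(DTYPE)
        self.grad = np.zeros_like(self.value)


class Module:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1d(Module):
    """1-D convolution, channels-last, zero padding, He-normal init."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.kernel, self.stride = kernel, stride
        self.pad = (kernel - 1) // 2 if pad is None else pad
        scale = np.sqrt(2.0 / (in_ch * kernel))
        self.w = Param(rng.normal(0.0, scale, size=(kernel, in_ch, out_ch)))
        self.b = Param(np.zeros(out_ch))

    def params(self):
        return [self.w, self.b]

    def _out_len(self, L: int) -> int:
        return (L + 2 * self.pad - self.kernel) // self.stride + 1

    def forward(self, x, train):
        B, L, C = x.shape
        L_out = self._out_len(L)
        if L_out < 1:
            raise ValueError(
                f"input length {L} too short for kernel {self.kernel} "
                f"with stride {self.stride}"
            )
        xp = np.pad(x, ((0, 0), (self.pad, self.pad), (0, 0)))
        y = np.zeros((B * L_out, self.b.value.size), dtype=DTYPE)
        for dk in range(self.kernel):
            sl = xp[:, dk : dk + self.stride * L_out : self.stride, :]
            y += np.ascontiguousarray(sl).reshape(B * L_out, C) @ self.w.value[dk]
        y += self.b.value
        self._cache = (xp, (B, L, C), L_out)
        return y.reshape(B, L_out, -1)

    def backward(self, grad):
        xp, (B, L, C), L_out = self._cache
        g2 = grad.reshape(B * L_out, -1)
        self.b.grad += grad.sum(axis=(0, 1))
        dxp = np.zeros_like(xp)
        for dk in range(self.kernel):
            sl = xp[:, dk : dk + self.stride * L_out : self.stride, :]
            self.w.grad[dk] += sl.reshape(B * L_out, C).T @ g2
            dxp[:, dk : dk + self.stride * L_out : self.stride, :] += (
                g2 @ self.w.value[dk].T
            ).reshape(B, L_out, C)
        return dxp[:, self.pad : self.pad + L, :] if self.pad else dxp


class Dense(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator | None = None,
                 zero_init: bool = False):
        rng = rng or np.random.default_rng(0)
        if zero_init:
            w = np.zeros((in_f, out_f))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / in_f), size=(in_f, out_f))
        self.w, self.b = Param(w), Param(np.zeros(out_f))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad):
        self.w.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value.T


class ReLU(Module):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Flatten(Module):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class GlobalAvgPool(Module):
    """Mean over the length axis: (B, L, C) -> (B, C)."""

    def forward(self, x, train):
        self._L = x.shape[1]
        return x.mean(axis=1)

    def backward(self, grad):
        return np.repeat(grad[:, None, :], self._L, axis=1) / self._L


class MaxPool1d(Module):
    def __init__(self, kernel: int = 2, stride: int | None = None, pad: int = 0):
        self.kernel = kernel
        self.stride = stride or kernel
        self.pad = pad

    def forward(self, x, train):
        B, L, C = x.shape
        L_out = (L + 2 * self.pad - self.kernel) // self.stride + 1
        if L_out < 1:
            raise ValueError(f"input length {L} too short for pooling kernel {self.kernel}")
        xp = np.pad(x, ((0, 0), (self.pad, self.pad), (0, 0)), constant_values=-np.inf)
        windows = np.stack(
            [xp[:, dk : dk + self.stride * L_out : self.stride, :] for dk in range(self.kernel)],
            axis=0,
        )
        self._arg = windows.argmax(axis=0)
        self._shape = (B, L, C)
        self._L_out = L_out
        return windows.max(axis=0)

    def backward(self, grad):
        B, L, C = self._shape
        dxp = np.zeros((B, L + 2 * self.pad, C), dtype=grad.dtype)
        for dk in range(self.kernel):
            sel = grad * (self._arg == dk)
            dxp[:, dk : dk + self.stride * self._L_out : self.stride, :] += sel
        return dxp[:, self.pad : self.pad + L, :] if self.pad else dxp


class BatchNorm1d(Module):
    """Batch normalisation per channel over (batch, length)."""

    def __init__(self, n_ch: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(n_ch))
        self.beta = Param(np.zeros(n_ch))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(n_ch, dtype=DTYPE)
        self.running_var = np.ones(n_ch, dtype=DTYPE)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_sd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_sd
        self._cache = (xhat, inv_sd, x.shape[0] * x.shape[1], train)
        return xhat * self.gamma.value + self.beta.value

    def backward(self, grad):
        xhat, inv_sd, m, train = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=(0, 1))
        self.beta.grad += grad.sum(axis=(0, 1))
        g = grad * self.gamma.value
        if not train:
            return g * inv_sd
        # standard batchnorm backward through batch statistics
        return (inv_sd / m) * (
            m * g - g.sum(axis=(0, 1)) - xhat * (g * xhat).sum(axis=(0, 1))
        )


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class ResidualBlock(Module):
    """Basic 1-D residual block: two 3-tap convolutions with batch norm.

    Output is ``relu(F(x) + shortcut(x))``.  The shortcut is the identity
    (no trainable parameters) when shape is preserved, and a strided 1-tap
    projection convolution + batch norm when channel width or length change.
    """

    def __init__(self, in_ch: int, out_ch: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.body = Sequential(
            Conv1d(in_ch, out_ch, 3, stride=stride, rng=rng),
            BatchNorm1d(out_ch),
            ReLU(),
            Conv1d(out_ch, out_ch, 3, rng=rng),
            BatchNorm1d(out_ch),
        )
        if stride != 1 or in_ch != out_ch:
            self.shortcut: Sequential | None = Sequential(
                Conv1d(in_ch, out_ch, 1, stride=stride, pad=0, rng=rng),
                BatchNorm1d(out_ch),
            )
        else:
            self.shortcut = None

    def params(self):
        out = self.body.params()
        if self.shortcut is not None:
            out += self.shortcut.params()
        return out

    def forward(self, x, train):
        f = self.body.forward(x, train)
        s = x if self.shortcut is None else self.shortcut.forward(x, train)
        pre = f + s
        self._mask = pre > 0
        return pre * self._mask

    def backward(self, grad):
        grad = grad * self._mask
        dx = self.body.backward(grad)
        if self.shortcut is None:
            dx = dx + grad
        else:
            dx = dx + self.shortcut.backward(grad)
        return dx


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.beta1 * m + (1 - self.beta1) * p.grad
            v[...] = self.beta2 * v + (1 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def fit_mse(
    net: Module,
    x: np.ndarray,
    y: np.ndarray,
    epochs: int,
    batch_size: int,
    lr: float,
    rng: np.random.Generator,
) -> list[float]:
    """Train ``net`` on mean squared error for exactly ``epochs`` epochs.

    The epoch count is the sole stopping criterion (no early stopping).
    Returns the per-epoch mean training loss.
    """
    x = x.astype(DTYPE)
    y = y.astype(DTYPE).ravel()
    n = x.shape[0]
    opt = Adam(net.params(), lr=lr)
    losses = []
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb, yb = x[idx], y[idx]
            opt.zero_grad()
            pred = net.forward(xb, train=True).ravel()
            resid = pred - yb
            epoch_loss += float(resid @ resid)
            grad = (2.0 * resid / len(idx)).astype(DTYPE).reshape(-1, 1)
            net.backward(grad)
            opt.step()
        losses.append(epoch_loss / n)
    return losses
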