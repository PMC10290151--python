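"""Minimal explicit-backprop neural-network engine on NumPy.

One-dimensional convolutional building blocks sufficient for the multiscale
SE-residual ECG network and its contrastive pretraining: Conv1d (im2col via
stride tricks), BatchNorm1d, ReLU, Dropout, Linear, global average pooling,
and SGD-with-momentum / Adam optimizers.  Each module implements ``forward``
(caching what backward needs) and ``backward`` (returning the gradient with
respect to its input and accumulating parameter gradients).  There is no
autograd graph; composite architectures wire their own backward pass, which
keeps the engine small and every gradient explicit and testable against
finite differences.

Tensor convention: signals are ``(batch, channels, length)``; dense features
are ``(batch, features)``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = np.zeros_like(self.data)
        self.name = name

    @property
    def size(self) -> int:
        return self.data.size


class Module:
    """Base class; children are discovered by attribute scan."""

    train_mode: bool = True

    def modules(self) -> list["Module"]:
        found: list[Module] = []
        for value in self.__dict__.values():
            if isinstance(value, Module):
                found.append(value)
            elif isinstance(value, (list, tuple)):
                found.extend(v for v in value if isinstance(v, Module))
        return found

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = [
            v for v in self.__dict__.values() if isinstance(v, Parameter)]
        for child in self.modules():
            params.extend(child.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def set_train(self, mode: bool) -> None:
        self.train_mode = mode
        for child in self.modules():
            child.set_train(mode)

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # state = trainable params + buffers (BN running stats), for checkpoints
    def state_arrays(self) -> list[np.ndarray]:
        arrays = [p.data for p in self.parameters()]
        for mod in self._all_modules():
            if isinstance(mod, BatchNorm1d):
                arrays.extend([mod.running_mean, mod.running_var])
        return arrays

    def _all_modules(self) -> list["Module"]:
        out: list[Module] = [self]
        for child in self.modules():
            out.extend(child._all_modules())
        return out

    def get_state(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    def set_state(self, state: list[np.ndarray]) -> None:
        targets = self.state_arrays()
        if len(targets) != len(state):
            raise ValueError(
                f"state has {len(state)} arrays, model needs {len(targets)}")
        for dst, src in zip(targets, state):
            if dst.shape != src.shape:
                raise ValueError("state shape mismatch")
            dst[...] = src

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def he_init(rng: np.random.Generator, shape: tuple[int, ...],
            fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class Conv1d(Module):
    """1-D convolution with 'same'-style padding: out_len = ceil(L/stride)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride = kernel, stride
        self.weight = Parameter(
            he_init(rng, (out_ch, in_ch, kernel), in_ch * kernel), "conv.w")
        self.bias = Parameter(np.zeros(out_ch), "conv.b") if bias else None

    def _pad(self, length: int) -> tuple[int, int, int]:
        out_len = -(-length // self.stride)  # ceil
        total = max(0, (out_len - 1) * self.stride + self.kernel - length)
        left = total // 2
        return out_len, left, total - left

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, length = x.shape
        out_len, pl, pr = self._pad(length)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        # (B, C, out_len, K)
        windows = sliding_window_view(xp, self.kernel, axis=2)[
            :, :, ::self.stride][:, :, :out_len]
        cols = windows.transpose(0, 2, 1, 3).reshape(b, out_len, -1)
        w2 = self.weight.data.reshape(self.out_ch, -1)
        y = cols @ w2.T
        if self.bias is not None:
            y += self.bias.data
        self._cache = (cols, x.shape, xp.shape, pl)
        return np.ascontiguousarray(y.transpose(0, 2, 1))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, x_shape, xp_shape, pl = self._cache
        b, c, length = x_shape
        out_len = dy.shape[2]
        dy2 = dy.transpose(0, 2, 1)                      # (B, out_len, O)
        w2 = self.weight.data.reshape(self.out_ch, -1)
        dw = dy2.reshape(-1, self.out_ch).T @ cols.reshape(-1, cols.shape[2])
        self.weight.grad += dw.reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2))
        dcols = (dy2 @ w2).reshape(b, out_len, c, self.kernel)
        dxp = np.zeros(xp_shape)
        s = self.stride
        for k in range(self.kernel):
            dxp[:, :, k:k + s * out_len:s] += dcols[:, :, :, k].transpose(
                0, 2, 1)
        return dxp[:, :, pl:pl + length]


class Linear(Module):
    def __init__(self, in_f: int, out_f: int,
                 rng: np.random.Generator | None = None, zero_init=False):
        rng = rng or np.random.default_rng(0)
        w = (np.zeros((out_f, in_f)) if zero_init
             else he_init(rng, (out_f, in_f), in_f))
        self.weight = Parameter(w, "linear.w")
        self.bias = Parameter(np.zeros(out_f), "linear.b")

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.weight.grad += dy.T @ self._x
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.data


class BatchNorm1d(Module):
    """Per-channel normalisation over batch and time for (B, C, L) input."""

    def __init__(self, channels: int, eps: float = 1e-5,
                 momentum: float = 0.1):
        self.gamma = Parameter(np.ones(channels), "bn.gamma")
        self.beta = Parameter(np.zeros(channels), "bn.beta")
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.eps, self.momentum = eps, momentum

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.train_mode:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        self._cache = (xhat, inv, x.shape)
        return self.gamma.data[None, :, None] * xhat + \
            self.beta.data[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        m = shape[0] * shape[2]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2))
        self.beta.grad += dy.sum(axis=(0, 2))
        dxhat = dy * self.gamma.data[None, :, None]
        if not self.train_mode:
            return dxhat * inv[None, :, None]
        term = dxhat - dxhat.mean(axis=(0, 2), keepdims=True) \
            - xhat * (dxhat * xhat).mean(axis=(0, 2), keepdims=True)
        return term * inv[None, :, None]


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Dropout(Module):
    """Inverted dropout; a shared Generator keeps runs reproducible."""

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0,1)")
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def reseed(self, seed: int) -> None:
        self.rng = np.random.default_rng(seed)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.train_mode or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class GlobalAvgPool(Module):
    """(B, C, L) -> (B, C) average over time."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._length = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(dy[:, :, None], self._length, axis=2) / self._length


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=axis, keepdims=True))


# ---------------------------------------------------------------------------
# optimizers

class SGD:
    """SGD with classical momentum and L2 weight decay."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 momentum: float = 0.9, weight_decay: float = 0.0):
        self.params = params
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.velocity = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v


class Adam:
    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
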