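"""Neural-network layers and optimizers built on the autodiff engine.

All randomness (weight init, dropout masks) flows through an explicit
``numpy.random.Generator`` so that training runs are reproducible bit for
bit given a seed.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


def glorot(rng: np.random.Generator, shape, fan_in, fan_out) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Module:
    def parameters(self):
        params = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def set_training(self, flag: bool):
        for v in vars(self).values():
            if isinstance(v, Module):
                v.set_training(flag)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.set_training(flag)
        if hasattr(self, "training"):
            self.training = flag

    def state_dict(self):
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state):
        for p, s in zip(self.parameters(), state):
            p.data = np.asarray(s, dtype=np.float64).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Dense(Module):
    def __init__(self, in_dim, out_dim, rng, activation=None):
        self.w = glorot(rng, (in_dim, out_dim), in_dim, out_dim)
        self.b = Tensor(np.zeros(out_dim), requires_grad=True)
        self.activation = activation

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.w + self.b
        if self.activation == "relu":
            out = out.relu()
        elif self.activation == "sigmoid":
            out = out.sigmoid()
        elif self.activation == "tanh":
            out = out.tanh()
        return out


class Conv2D(Module):
    """NCHW convolution; ``padding='same'`` keeps out = ceil(in / stride)."""

    def __init__(self, in_c, out_c, kernel, stride, rng, padding="same",
                 activation=None):
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        fan_in, fan_out = in_c * kh * kw, out_c * kh * kw
        self.w = glorot(rng, (out_c, in_c, kh, kw), fan_in, fan_out)
        self.b = Tensor(np.zeros(out_c), requires_grad=True)
        self.stride = stride
        self.pad = ((kh - 1) // 2, (kw - 1) // 2) if padding == "same" else (0, 0)
        self.activation = activation

    def forward(self, x: Tensor) -> Tensor:
        out = ad.conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)
        if self.activation == "relu":
            out = out.relu()
        return out


class ConvTranspose2D(Module):
    """Stride-2, kernel-3 transposed convolution doubling spatial size."""

    def __init__(self, in_c, out_c, rng, kernel=3, stride=2, activation=None):
        kh = kw = kernel
        fan_in, fan_out = in_c * kh * kw, out_c * kh * kw
        self.w = glorot(rng, (in_c, out_c, kh, kw), fan_in, fan_out)
        self.b = Tensor(np.zeros(out_c), requires_grad=True)
        self.stride = stride
        self.pad = ((kh - 1) // 2, (kw - 1) // 2)
        self.activation = activation

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        out = ad.conv_transpose2d(
            x, self.w, self.b, stride=self.stride, pad=self.pad,
            output_size=(self.stride * h, self.stride * w),
        )
        if self.activation == "relu":
            out = out.relu()
        elif self.activation == "sigmoid":
            out = out.sigmoid()
        return out


class BatchNorm(Module):
    """Batch normalization over all axes except the feature axis.

    ``axis=1`` normalizes conv channels (NCHW); ``axis=-1`` dense features.
    """

    def __init__(self, n_features, axis=-1, momentum=0.9, eps=1e-5):
        self.gamma = Tensor(np.ones(n_features), requires_grad=True)
        self.beta = Tensor(np.zeros(n_features), requires_grad=True)
        self.axis = axis
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.training = True

    def forward(self, x: Tensor) -> Tensor:
        ndim = x.ndim
        axis = self.axis % ndim
        reduce_axes = tuple(a for a in range(ndim) if a != axis)
        bshape = [1] * ndim
        bshape[axis] = -1
        if self.training:
            mean = x.data.mean(axis=reduce_axes)
            var = x.data.var(axis=reduce_axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            )
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        # mean/var treated as constants of the batch: a standard simplification
        # that keeps gradients cheap and is exact at convergence
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - Tensor(mean.reshape(bshape))) * Tensor(inv.reshape(bshape))
        return xhat * self.gamma.reshape(bshape) + self.beta.reshape(bshape)


class Dropout(Module):
    def __init__(self, rate, rng):
        self.rate = rate
        self.rng = rng
        self.training = True

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate <= 0:
            return x
        mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * Tensor(mask)


class Flatten(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.reshape(x.shape[0], -1)


class LSTM(Module):
    """Single-layer LSTM; input (N, T, D); returns full sequence (N, T, H)."""

    def __init__(self, in_dim, hidden, rng):
        self.hidden = hidden
        d = in_dim + hidden
        self.w = glorot(rng, (d, 4 * hidden), d, 4 * hidden)
        self.b = Tensor(np.zeros(4 * hidden), requires_grad=True)
        # forget-gate bias starts at 1 to ease gradient flow early in training
        self.b.data[hidden:2 * hidden] = 1.0

    def forward(self, x: Tensor) -> Tensor:
        n, t, d = x.shape
        h = Tensor(np.zeros((n, self.hidden)))
        c = Tensor(np.zeros((n, self.hidden)))
        hs = []
        H = self.hidden
        for step in range(t):
            xt = x[:, step, :]
            gates = ad.concat([xt, h], axis=1) @ self.w + self.b
            i = gates[:, :H].sigmoid()
            f = gates[:, H:2 * H].sigmoid()
            g = gates[:, 2 * H:3 * H].tanh()
            o = gates[:, 3 * H:].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            hs.append(h.reshape(n, 1, H))
        return ad.concat(hs, axis=1)


class Sequential(Module):
    def __init__(self, *modules):
        self.modules = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.modules:
            x = m(x)
        return x


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class RMSprop:
    def __init__(self, params, lr=1e-3, rho=0.9, eps=1e-8):
        self.params = params
        self.lr, self.rho, self.eps = lr, rho, eps
        self.sq = [np.zeros_like(p.data) for p in params]

    def step(self):
        for p, s in zip(self.params, self.sq):
            if p.grad is None:
                continue
            s *= self.rho
            s += (1 - self.rho) * p.grad ** 2
            p.data -= self.lr * p.grad / (np.sqrt(s) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def make_optimizer(name: str, params, lr: float):
    if name == "adam":
        return Adam(params, lr=lr)
    if name == "rmsprop":
        return RMSprop(params, lr=lr)
    raise ValueError(f"unknown optimizer {name!r}; expected 'adam' or 'rmsprop'")
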