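"""Neural-network building blocks and the AdamW optimizer.

Everything operates on NCHW :class:`~dcanet.autograd.Tensor` batches.
Weight initialization is driven by an explicit ``numpy.random.Generator``
so that model construction is fully deterministic given a seed.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: recursive parameter discovery, train/eval mode, state dict."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = ""):
        for name, v in self.__dict__.items():
            path = f"{prefix}{name}"
            if isinstance(v, Parameter):
                yield path, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{path}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{path}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for m_name, buf_name, arr in self._named_buffers():
            state[f"{m_name}{buf_name}"] = arr.copy()
        return state

    def _named_buffers(self):
        for name, v in self.__dict__.items():
            if isinstance(v, Module):
                for sub, buf, arr in v._named_buffers():
                    yield f"{name}.{sub}", buf, arr
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        for sub, buf, arr in item._named_buffers():
                            yield f"{name}.{i}.{sub}", buf, arr
        for buf in getattr(self, "_buffers", ()):
            yield "", buf, getattr(self, buf)

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        for key, arr in state.items():
            arr = np.asarray(arr, dtype=np.float64).copy()
            if key in own:
                own[key].data = arr
            else:
                self._set_buffer(key, arr)

    def _set_buffer(self, dotted: str, arr: np.ndarray) -> None:
        parts = dotted.split(".")
        obj = self
        for p in parts[:-1]:
            obj = obj[int(p)] if isinstance(obj, (list, tuple)) else getattr(obj, p)
        setattr(obj, parts[-1], arr)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def _he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    def __init__(self, rng, in_ch, out_ch, kernel=3, stride=1, padding=0,
                 bias=True, zero_init=False):
        super().__init__()
        self.stride, self.padding = stride, padding
        fan_in = in_ch * kernel * kernel
        w = np.zeros((out_ch, in_ch, kernel, kernel)) if zero_init else \
            _he_normal(rng, (out_ch, in_ch, kernel, kernel), fan_in)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x):
        return ag.conv2d(x, self.weight, self.bias,
                         stride=self.stride, padding=self.padding)


class Linear(Module):
    """y = W x applied to the channel axis of (..., C, M) tensors."""

    def __init__(self, rng, in_dim, out_dim, bias=True):
        super().__init__()
        self.weight = Parameter(_he_normal(rng, (out_dim, in_dim), in_dim))
        self.bias = Parameter(np.zeros(out_dim)) if bias else None

    def forward(self, x):
        out = ag.matmul(self.weight, x)
        if self.bias is not None:
            out = out + ag.reshape(self.bias, (-1, 1))
        return out


class BatchNorm2d(Module):
    _buffers = ("running_mean", "running_var")

    def __init__(self, channels, eps=1e-5, momentum=0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x):
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x + ag.mul(mu, -1.0)) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        xhat = (x + ag.mul(mu, -1.0)) / ag.sqrt(var + self.eps)
        g = ag.reshape(self.gamma, (1, -1, 1, 1))
        b = ag.reshape(self.beta, (1, -1, 1, 1))
        return xhat * g + b


class LayerNorm2d(Module):
    """Layer normalization over the channel axis, independently per position."""

    def __init__(self, channels, eps=1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))

    def forward(self, x):
        mu = x.mean(axis=1, keepdims=True)
        var = ((x + ag.mul(mu, -1.0)) ** 2).mean(axis=1, keepdims=True)
        xhat = (x + ag.mul(mu, -1.0)) / ag.sqrt(var + self.eps)
        g = ag.reshape(self.gamma, (1, -1, 1, 1))
        b = ag.reshape(self.beta, (1, -1, 1, 1))
        return xhat * g + b


class ReLU(Module):
    def forward(self, x):
        return ag.relu(x)


class GELU(Module):
    def forward(self, x):
        return ag.gelu(x)


def conv_bn_relu(rng, in_ch, out_ch, kernel=3, stride=1, padding=1):
    return Sequential(
        Conv2d(rng, in_ch, out_ch, kernel=kernel, stride=stride, padding=padding,
               bias=False),
        BatchNorm2d(out_ch),
        ReLU(),
    )


class AdamW(Module):
    """Decoupled weight decay Adam (β1, β2, ε and decay as in the protocol)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8,
                 weight_decay=1e-4):
        super().__init__()
        self.params = list(params)
        self.lr, self.beta1, self.beta2 = lr, beta1, beta2
        self.eps, self.weight_decay = eps, weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p.data = p.data - self.lr * (
                mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data
            )
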