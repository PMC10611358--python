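"""Neural-network layers on top of the autodiff core.

Layers follow the usual conventions: a :class:`Module` owns
:class:`Parameter` leaves and child modules, ``train()``/``eval()`` toggle
stochastic behaviour (dropout, batch-norm statistics), and ``state_dict``
round-trips the learned arrays. All random initialization draws from an
explicit ``numpy`` generator so that a given seed reproduces a model exactly.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concatenate, conv1d, maxpool1d

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "Linear",
    "Conv1d",
    "BatchNorm1d",
    "ChannelLayerNorm",
    "MaxPool1d",
    "Dropout",
    "GELU",
    "ReLU",
    "LSTM",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    # -- traversal ------------------------------------------------------------

    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def modules(self):
        yield self
        for _, child in self._children():
            yield from child.modules()

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- mode and state -------------------------------------------------------

    def train(self, flag: bool = True):
        for m in self.modules():
            m.training = flag
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, m in self._named_modules():
            for bname, buf in getattr(m, "_buffers", {}).items():
                state[f"{name}{bname}"] = buf.copy()
        return state

    def _named_modules(self, prefix: str = ""):
        yield prefix, self
        for name, child in self._children():
            yield from child._named_modules(prefix + name + ".")

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = {
            f"{name}{bname}": (m, bname)
            for name, m in self._named_modules()
            for bname in getattr(m, "_buffers", {})
        }
        for key, arr in state.items():
            if key in params:
                if params[key].data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {key}")
                params[key].data = np.asarray(arr, dtype=np.float32)
            elif key in buffers:
                m, bname = buffers[key]
                m._buffers[bname] = np.asarray(arr, dtype=np.float32)
            else:
                raise KeyError(f"unexpected key {key!r} in state dict")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        limit = np.sqrt(6.0 / (in_features + out_features))
        self.weight = Parameter(rng.uniform(-limit, limit, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    """Stride-1 valid convolution over (batch, channels, time)."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator):
        super().__init__()
        fan_in = in_channels * kernel
        self.weight = Parameter(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                           (out_channels, in_channels, kernel)))
        self.bias = Parameter(np.zeros(out_channels))
        self.kernel = kernel

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias)


class BatchNorm1d(Module):
    """Per-feature-channel normalization over batch and time for (B, C, L) data.

    Training mode normalizes with batch statistics and tracks running
    estimates (momentum 0.1); evaluation mode uses the running estimates, so
    per-sample outputs are independent of the rest of the batch.
    """

    def __init__(self, n_channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones((1, n_channels, 1)))
        self.beta = Parameter(np.zeros((1, n_channels, 1)))
        self.eps = eps
        self.momentum = momentum
        self._buffers = {
            "running_mean": np.zeros((1, n_channels, 1), dtype=np.float32),
            "running_var": np.ones((1, n_channels, 1), dtype=np.float32),
        }

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            m = x.mean(axis=(0, 2), keepdims=True)
            xc = x - m
            v = (xc * xc).mean(axis=(0, 2), keepdims=True)
            self._buffers["running_mean"] = (
                (1 - self.momentum) * self._buffers["running_mean"] + self.momentum * m.data
            )
            self._buffers["running_var"] = (
                (1 - self.momentum) * self._buffers["running_var"] + self.momentum * v.data
            )
            xhat = xc * ((v + self.eps) ** -0.5)
        else:
            m = Tensor(self._buffers["running_mean"])
            v = Tensor(self._buffers["running_var"])
            xhat = (x - m) * ((v + self.eps) ** -0.5)
        return self.gamma * xhat + self.beta


class ChannelLayerNorm(Module):
    """Layer-style normalization over the feature-channel axis of (B, C, L) data."""

    def __init__(self, n_channels: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones((1, n_channels, 1)))
        self.beta = Parameter(np.zeros((1, n_channels, 1)))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        m = x.mean(axis=1, keepdims=True)
        xc = x - m
        v = (xc * xc).mean(axis=1, keepdims=True)
        return self.gamma * (xc * ((v + self.eps) ** -0.5)) + self.beta


class MaxPool1d(Module):
    def __init__(self, k: int):
        super().__init__()
        self.k = k

    def forward(self, x: Tensor) -> Tensor:
        return maxpool1d(x, self.k)


class Dropout(Module):
    """Inverted dropout; active only in training mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError(f"dropout rate must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class GELU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.gelu()


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class LSTM(Module):
    """Single-layer LSTM over (batch, time, features); returns the final hidden state.

    Gate order in the packed weight matrices is input, forget, cell, output;
    the forget-gate bias starts at 1 (standard recipe for gradient flow early
    in training).
    """

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        super().__init__()
        s = 1.0 / np.sqrt(hidden_size)
        self.w_x = Parameter(rng.uniform(-s, s, (input_size, 4 * hidden_size)))
        self.w_h = Parameter(rng.uniform(-s, s, (hidden_size, 4 * hidden_size)))
        bias = np.zeros(4 * hidden_size)
        bias[hidden_size : 2 * hidden_size] = 1.0
        self.bias = Parameter(bias)
        self.hidden_size = hidden_size

    def forward(self, x: Tensor) -> Tensor:
        B, T, F = x.shape
        H = self.hidden_size
        xw = x.reshape(B * T, F) @ self.w_x + self.bias
        xw = xw.reshape(B, T, 4 * H)
        h = Tensor(np.zeros((B, H), dtype=np.float32))
        c = Tensor(np.zeros((B, H), dtype=np.float32))
        for t in range(T):
            z = xw[:, t] + h @ self.w_h
            i = z[:, :H].sigmoid()
            f = z[:, H : 2 * H].sigmoid()
            g = z[:, 2 * H : 3 * H].tanh()
            o = z[:, 3 * H :].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
        return h


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax (the max shift is treated as a constant)."""
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    z = x - shift
    return z - z.exp().sum(axis=axis, keepdims=True).log()


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer class labels under the logits."""
    ls = log_softmax(logits, axis=1)
    n = logits.shape[0]
    picked = ls[np.arange(n), np.asarray(labels, dtype=np.intp)]
    return -picked.mean()


def branch_concat(parts: list[Tensor], axis: int = 1) -> Tensor:
    return concatenate(parts, axis=axis)
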