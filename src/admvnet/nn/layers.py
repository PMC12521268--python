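"""Network building blocks on top of the autodiff core.

Parameter initialisation is always driven by an explicit ``numpy`` Generator
so that model construction is reproducible from a single seed.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from . import core
from .core import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Container with recursive parameter discovery and train/eval modes."""

    def __init__(self):
        self.training = True

    def modules(self) -> Iterator["Module"]:
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Parameter):
                yield name, v
            elif isinstance(v, Module):
                yield from v.named_parameters(prefix=name + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{name}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{name}.{i}", item

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    # -- checkpointing -------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.data.copy() for k, v in self.named_parameters()}
        for m_name, m in self._named_modules():
            for b_name, buf in getattr(m, "_buffers", {}).items():
                state[f"{m_name}{b_name}"] = np.array(buf)
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        for k, v in state.items():
            if k in params:
                params[k].data = np.asarray(v).astype(params[k].dtype).reshape(params[k].shape)
            else:
                self._set_buffer_by_name(k, v)

    def _named_modules(self, prefix: str = ""):
        yield prefix, self
        for k, v in self.__dict__.items():
            if isinstance(v, Module):
                yield from v._named_modules(prefix=f"{prefix}{k}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item._named_modules(prefix=f"{prefix}{k}.{i}.")

    def _set_buffer_by_name(self, name: str, value):
        for m_name, m in self._named_modules():
            bufs = getattr(m, "_buffers", None)
            if bufs is None or not name.startswith(m_name):
                continue
            key = name[len(m_name):]
            if key in bufs:
                bufs[key] = np.asarray(value)
                return

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self.items = list(mods)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, i):
        return self.items[i]

    def __len__(self):
        return len(self.items)

    def append(self, m):
        self.items.append(m)


def _kaiming(rng: np.random.Generator, shape, fan_in: int, dtype):
    std = math.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(dtype)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True, init_scale: float = 1.0, dtype=np.float32):
        super().__init__()
        self.w = Parameter(init_scale * _kaiming(rng, (n_in, n_out), n_in, dtype))
        self.b = Parameter(np.zeros(n_out, dtype=dtype)) if bias else None

    def forward(self, x):
        y = core.matmul(x, self.w)
        if self.b is not None:
            y = y + self.b
        return y


class Conv3d(Module):
    def __init__(self, n_in: int, n_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, bias: bool = True, dtype=np.float32):
        super().__init__()
        fan_in = n_in * kernel ** 3
        self.w = Parameter(_kaiming(rng, (n_out, n_in, kernel, kernel, kernel), fan_in, dtype))
        self.b = Parameter(np.zeros(n_out, dtype=dtype)) if bias else None
        self.stride, self.padding = stride, padding

    def forward(self, x):
        return core.conv3d(x, self.w, self.b, stride=self.stride, padding=self.padding)


class DepthwiseSeparableConv3d(Module):
    """Depthwise 3D conv followed by a pointwise (1x1x1) mixing conv."""

    def __init__(self, channels: int, kernel: int, rng: np.random.Generator,
                 padding: int | None = None, dtype=np.float32):
        super().__init__()
        if padding is None:
            padding = kernel // 2
        self.dw = Parameter(_kaiming(rng, (channels, kernel, kernel, kernel),
                                     kernel ** 3, dtype))
        self.dw_b = Parameter(np.zeros(channels, dtype=dtype))
        self.pw = Conv3d(channels, channels, 1, rng, dtype=dtype)
        self.padding = padding

    def forward(self, x):
        y = core.depthwise_conv3d(x, self.dw, self.dw_b, padding=self.padding)
        return self.pw(y)


class BatchNorm3d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32):
        super().__init__()
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))
        self.eps, self.momentum = eps, momentum
        self._buffers = {
            "running_mean": np.zeros(channels, dtype=dtype),
            "running_var": np.ones(channels, dtype=dtype),
        }

    def forward(self, x):
        c = x.shape[1]
        if self.training:
            mu = core.tmean(x, axis=(0, 2, 3, 4), keepdims=True)
            var = core.tmean((x - mu) ** 2.0, axis=(0, 2, 3, 4), keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] = ((1 - m) * self._buffers["running_mean"]
                                             + m * mu.data.reshape(c))
            self._buffers["running_var"] = ((1 - m) * self._buffers["running_var"]
                                            + m * var.data.reshape(c))
        else:
            mu = Tensor(self._buffers["running_mean"].reshape(1, c, 1, 1, 1))
            var = Tensor(self._buffers["running_var"].reshape(1, c, 1, 1, 1))
        xhat = (x - mu) / core.sqrt(var + self.eps)
        return xhat * self.gamma.reshape(1, c, 1, 1, 1) + self.beta.reshape(1, c, 1, 1, 1)


class GRUCell(Module):
    """Gated-recurrent cell.

    Convention: h' = z * n + (1 - z) * h, so a closed update gate (z = 0)
    leaves the hidden state untouched.
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator,
                 dtype=np.float32, candidate_identity: bool = False):
        super().__init__()
        def w(shape, fan, scale=1.0):
            return Parameter(scale * _kaiming(rng, shape, fan, dtype))
        # with an identity candidate the gates start flat (z = r = 1/2 for
        # every unit) so the update is driven by the input coordinate itself;
        # random gate weights would imprint a fixed per-unit pattern that
        # swamps the input signal.  Both remain fully trainable.
        gate_scale = 0.0 if candidate_identity else 1.0
        self.w_z = w((n_in, n_hidden), n_in, gate_scale)
        self.u_z = w((n_hidden, n_hidden), n_hidden, gate_scale)
        self.b_z = Parameter(np.zeros(n_hidden, dtype=dtype))
        self.w_r = w((n_in, n_hidden), n_in, gate_scale)
        self.u_r = w((n_hidden, n_hidden), n_hidden, gate_scale)
        self.b_r = Parameter(np.zeros(n_hidden, dtype=dtype))
        if candidate_identity and n_in == n_hidden:
            # identity-dominated candidate: the new state starts out driven
            # by its own input coordinate; the small hidden mixing keeps the
            # reset-gate path trainable from the first step
            self.w_n = Parameter(np.eye(n_in, dtype=dtype))
            self.u_n = Parameter((1e-3 * rng.standard_normal((n_hidden, n_hidden))).astype(dtype))
        else:
            self.w_n = w((n_in, n_hidden), n_in)
            self.u_n = w((n_hidden, n_hidden), n_hidden)
        self.b_n = Parameter(np.zeros(n_hidden, dtype=dtype))

    def forward(self, x, h):
        z = core.sigmoid(x @ self.w_z + h @ self.u_z + self.b_z)
        r = core.sigmoid(x @ self.w_r + h @ self.u_r + self.b_r)
        n = core.tanh(x @ self.w_n + (r * h) @ self.u_n + self.b_n)
        return z * n + (1.0 - z) * h


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x):
        if not self.training or self.p <= 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * Tensor(mask)
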