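"""Thin neural-network layer over the autodiff core.

Modules hold named :class:`Parameter` leaves and submodules; ``state_dict``
round-trips through plain ``dict[str, ndarray]`` so checkpoints are ``.npz``
files.  Default dtype is float32.
"""

from __future__ import annotations

import math

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

DTYPE = np.float32


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)


class Module:
    """Minimal container with automatic parameter/submodule registration."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
                isinstance(v, Module) for v in value):
            for i, v in enumerate(value):
                self._modules[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def n_params(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)} "
                           f"unexpected={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=DTYPE)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng, fan_in, shape, gain: float = 1.0):
    return rng.normal(0.0, gain / math.sqrt(fan_in), shape).astype(DTYPE)


class Linear(Module):
    """Channel map y = x @ W.T + b applied to the last axis.

    A reduced ``gain`` (e.g. 0.1) is used on the output projection of
    residual branches and on classifier heads so a freshly built network is
    near-identity with near-uniform class probabilities.
    """

    def __init__(self, in_features, out_features, bias=True, rng=None,
                 gain: float = 1.0):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(_kaiming(rng, in_features,
                                         (out_features, in_features), gain))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = ad.matmul(x, ad.transpose(self.weight, (1, 0)))
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv3d(Module):
    def __init__(self, in_ch, out_ch, kernel=3, stride=1, padding=None,
                 bias=True, rng=None, gain: float = 1.0):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if padding is None:
            padding = kernel // 2
        self.stride, self.padding = stride, padding
        fan_in = in_ch * kernel ** 3
        shape = (out_ch, in_ch, kernel, kernel, kernel)
        self.weight = Parameter(_kaiming(rng, fan_in, shape, gain))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv3d(x, self.weight, self.bias,
                         stride=self.stride, padding=self.padding)


class ConvTranspose3d2x(Module):
    """Kernel-2 stride-2 transposed convolution (exact x2 upsampling)."""

    def __init__(self, in_ch, out_ch, bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(_kaiming(rng, in_ch, (in_ch, out_ch, 2, 2, 2)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv_transpose3d_2x(x, self.weight, self.bias)


class LayerNorm(Module):
    """Normalization over the trailing (channel) axis."""

    def __init__(self, dim, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def forward(self, x: Tensor) -> Tensor:
        return ad.layer_norm(x, self.gamma, self.beta, self.eps)


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

class AdamW:
    """AdamW with decoupled weight decay."""

    def __init__(self, params, lr=2e-4, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=1e-2):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.betas
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
                mhat / (np.sqrt(vhat) + self.eps)
                + self.weight_decay * p.data)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def cosine_warm_restart_lr(epoch: int, initial_lr: float, min_lr: float,
                           cycle: int) -> float:
    """Cosine-annealing-with-warm-restarts schedule.

    The rate resets to `initial_lr` at the start of each `cycle`-epoch cycle
    and decays to `min_lr` by cosine within the cycle.
    """
    phase = (epoch % cycle) / cycle
    return min_lr + 0.5 * (initial_lr - min_lr) * (1.0 + math.cos(math.pi * phase))
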