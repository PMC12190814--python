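"""Iterative axial factorization attention (IAFT).

Full 3D self-attention over N = H*W*D voxels costs O(N^2); axial
factorization runs multi-head scaled dot-product attention along one spatial
axis at a time, folding the two remaining axes into the batch, which brings
the score/value cost down to O(N^(4/3)) on cubes.  One IAF pass sweeps the
three axes sequentially, adding a SiLU-activated residual after each axis
(a "summed" variant that aggregates the three axial outputs inside a single
SiLU is kept behind a switch).

Two parallel implementations live here:

* plain-NumPy functional ops (`fold_axis`, `axial_mhsa`, `iaf_attention`,
  `full_mhsa_oracle`) used for oracle-level verification, and
* autodiff Modules (`AxialMHSA`, `IAFAttention`, `IAFTBlock`) used by the
  trainable network.

Token order is a depth-fastest raster scan: H outermost, then W, then D.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import LayerNorm, Linear, Module

__all__ = [
    "TokenSequence",
    "AxialAttentionParams",
    "IAFTBlockParams",
    "fold_axis",
    "unfold_axis",
    "axial_mhsa",
    "iaf_attention",
    "iaft_block",
    "full_mhsa_oracle",
    "attention_mac_count",
    "MacCount",
    "AxialMHSA",
    "IAFAttention",
    "IAFTBlock",
]

AXES = ("H", "W", "D")


@dataclass
class TokenSequence:
    """A flattened (B, N, C) feature sequence with its 3D geometry."""

    data: np.ndarray
    dims: tuple[int, int, int]

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected (B, N, C), got {self.data.shape}")
        if self.data.shape[1] != int(np.prod(self.dims)):
            raise ValueError(
                f"N={self.data.shape[1]} != prod(dims)={np.prod(self.dims)}")


@dataclass
class AxialAttentionParams:
    """Projections for one axis: WQ/WK/WV/WO are (C, C), biases length C."""

    WQ: np.ndarray
    WK: np.ndarray
    WV: np.ndarray
    WO: np.ndarray
    bQ: np.ndarray
    bK: np.ndarray
    bV: np.ndarray
    bO: np.ndarray
    num_heads: int = 1

    @classmethod
    def create(cls, channels: int, num_heads: int = 1,
               rng: np.random.Generator | None = None) -> "AxialAttentionParams":
        if channels % num_heads:
            raise ValueError("num_heads must divide channels")
        rng = rng or np.random.default_rng(0)
        s = 1.0 / np.sqrt(channels)
        mats = [rng.normal(0.0, s, (channels, channels)) for _ in range(4)]
        zeros = [np.zeros(channels) for _ in range(4)]
        return cls(*mats, *zeros, num_heads=num_heads)


@dataclass
class IAFTBlockParams:
    """One transformer block: pre-norms, per-axis attention, channel MLP."""

    attn: dict  # axis label -> AxialAttentionParams
    ln1_gamma: np.ndarray
    ln1_beta: np.ndarray
    ln2_gamma: np.ndarray
    ln2_beta: np.ndarray
    mlp_W1: np.ndarray
    mlp_b1: np.ndarray
    mlp_W2: np.ndarray
    mlp_b2: np.ndarray
    iterations: int = 1
    aggregation: Literal["sequential", "summed"] = "sequential"

    @classmethod
    def create(cls, channels: int, num_heads: int = 1, mlp_ratio: float = 2.0,
               iterations: int = 1, aggregation: str = "sequential",
               rng: np.random.Generator | None = None) -> "IAFTBlockParams":
        rng = rng or np.random.default_rng(0)
        hidden = int(round(mlp_ratio * channels))
        s1 = 1.0 / np.sqrt(channels)
        s2 = 1.0 / np.sqrt(hidden)
        return cls(
            attn={ax: AxialAttentionParams.create(channels, num_heads, rng)
                  for ax in AXES},
            ln1_gamma=np.ones(channels), ln1_beta=np.zeros(channels),
            ln2_gamma=np.ones(channels), ln2_beta=np.zeros(channels),
            mlp_W1=rng.normal(0.0, s1, (hidden, channels)),
            mlp_b1=np.zeros(hidden),
            mlp_W2=rng.normal(0.0, s2, (channels, hidden)),
            mlp_b2=np.zeros(channels),
            iterations=iterations, aggregation=aggregation,
        )


# ---------------------------------------------------------------------------
# functional (NumPy) path
# ---------------------------------------------------------------------------

_FOLD_PERM = {"H": (0, 2, 3, 1, 4), "W": (0, 1, 3, 2, 4), "D": (0, 1, 2, 3, 4)}


def fold_axis(tokens: TokenSequence, axis: str) -> np.ndarray:
    """Rearrange (B, N, C) into an axis-major batch (B*N/L, L, C)."""
    if axis not in AXES:
        raise ValueError(f"axis must be one of {AXES}, got {axis!r}")
    B, N, C = tokens.data.shape
    H, W, D = tokens.dims
    L = dict(zip(AXES, tokens.dims))[axis]
    grid = tokens.data.reshape(B, H, W, D, C)
    return grid.transpose(_FOLD_PERM[axis]).reshape(B * N // L, L, C)


def unfold_axis(folded: np.ndarray, axis: str, dims, batch: int
                ) -> TokenSequence:
    """Invert :func:`fold_axis`."""
    H, W, D = dims
    C = folded.shape[-1]
    order = {"H": (W, D, H), "W": (H, D, W), "D": (H, W, D)}[axis]
    grid = folded.reshape((batch,) + order + (C,))
    inv = {"H": (0, 3, 1, 2, 4), "W": (0, 1, 3, 2, 4), "D": (0, 1, 2, 3, 4)}
    grid = grid.transpose(inv[axis])
    return TokenSequence(grid.reshape(batch, H * W * D, C), tuple(dims))


def _np_softmax(x, axis=-1):
    e = np.exp(x - x.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def _np_silu(x):
    return x / (1.0 + np.exp(-x))


def axial_mhsa(axis_batch: np.ndarray,
               params: AxialAttentionParams) -> np.ndarray:
    """Multi-head scaled dot-product attention along the isolated axis.

    `axis_batch` is (M, L, C); each head attends over the L positions with
    scale 1/sqrt(C/num_heads).
    """
    M, L, C = axis_batch.shape
    h = params.num_heads
    if C % h:
        raise ValueError("num_heads must divide channels")
    c = C // h

    def proj(W, b):
        y = axis_batch @ W.T + b
        return y.reshape(M, L, h, c).transpose(0, 2, 1, 3)   # (M, h, L, c)

    q = proj(params.WQ, params.bQ)
    k = proj(params.WK, params.bK)
    v = proj(params.WV, params.bV)
    scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(c)
    attn = _np_softmax(scores, axis=-1)
    out = (attn @ v).transpose(0, 2, 1, 3).reshape(M, L, C)
    return out @ params.WO.T + params.bO


def iaf_attention(tokens: TokenSequence, params: dict,
                  mode: str = "sequential", t: int = 1) -> TokenSequence:
    """One or more sweeps of axial attention over H, W, D.

    sequential: for each axis a, Z <- Z + silu(Attn_a(Z)) (the updated state
    feeds the next axis); summed: Z <- Z + silu(sum_a Attn_a(Z)).
    """
    if t < 1:
        raise ValueError("iterations t must be >= 1")
    B = tokens.data.shape[0]
    z = tokens.data
    for _ in range(t):
        if mode == "sequential":
            for ax in AXES:
                seq = TokenSequence(z, tokens.dims)
                a = axial_mhsa(fold_axis(seq, ax), params[ax])
                z = z + _np_silu(unfold_axis(a, ax, tokens.dims, B).data)
        elif mode == "summed":
            seq = TokenSequence(z, tokens.dims)
            total = np.zeros_like(z)
            for ax in AXES:
                a = axial_mhsa(fold_axis(seq, ax), params[ax])
                total = total + unfold_axis(a, ax, tokens.dims, B).data
            z = z + _np_silu(total)
        else:
            raise ValueError(f"unknown aggregation mode {mode!r}")
    return TokenSequence(z, tokens.dims)


def _np_layer_norm(x, gamma, beta, eps=1e-5):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    return (x - mu) / np.sqrt(var + eps) * gamma + beta


def iaft_block(tokens: TokenSequence, params: IAFTBlockParams) -> TokenSequence:
    """Pre-norm transformer block: Z' = Z + IAF(LN(Z)); Z'' = Z' + MLP(LN(Z'))."""
    z = tokens.data
    normed = TokenSequence(
        _np_layer_norm(z, params.ln1_gamma, params.ln1_beta), tokens.dims)
    z = z + iaf_attention(normed, params.attn, params.aggregation,
                          params.iterations).data
    h = _np_layer_norm(z, params.ln2_gamma, params.ln2_beta)
    h = _np_silu(h @ params.mlp_W1.T + params.mlp_b1)
    z = z + (h @ params.mlp_W2.T + params.mlp_b2)
    return TokenSequence(z, tokens.dims)


def full_mhsa_oracle(tokens: TokenSequence, params: AxialAttentionParams,
                     max_tokens: int = 4096) -> TokenSequence:
    """Dense softmax attention over all N tokens (test-scale baseline)."""
    if tokens.data.shape[1] > max_tokens:
        raise ValueError(f"oracle guard: N={tokens.data.shape[1]} > {max_tokens}")
    out = axial_mhsa(tokens.data, params)
    return TokenSequence(out, tokens.dims)


# ---------------------------------------------------------------------------
# complexity accounting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MacCount:
    """Multiply-accumulate counts for one attention application."""

    score_value: int   # QK^T and AV products
    projections: int   # Q, K, V and output projections

    @property
    def total(self) -> int:
        return self.score_value + self.projections


def attention_mac_count(dims, C: int, num_heads: int = 1,
                        mode: str = "axial") -> MacCount:
    """Closed-form MAC count of one attention pass over an (H, W, D) grid.

    Head count does not change the totals (it only blocks the channel axis).
    For cubes of side s the axial score/value term is 6*s^4*C ~ N^(4/3) while
    the full-attention term is 2*N^2*C.
    """
    H, W, D = dims
    N = H * W * D
    if mode == "axial":
        # a singleton axis degenerates to a copy: no score/value products
        score_value = sum(2 * N * L * C for L in (H, W, D) if L > 1)
        projections = 3 * 4 * N * C * C
    elif mode == "full":
        score_value = 2 * N * N * C
        projections = 4 * N * C * C
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return MacCount(int(score_value), int(projections))


# ---------------------------------------------------------------------------
# trainable modules (autodiff path)
# ---------------------------------------------------------------------------

def _fold_t(x: Tensor, dims, axis: str) -> Tensor:
    B, N, C = x.shape
    H, W, D = dims
    L = dict(zip(AXES, dims))[axis]
    grid = ad.reshape(x, (B, H, W, D, C))
    grid = ad.transpose(grid, _FOLD_PERM[axis])
    return ad.reshape(grid, (B * N // L, L, C))


def _unfold_t(x: Tensor, dims, axis: str, batch: int) -> Tensor:
    H, W, D = dims
    C = x.shape[-1]
    order = {"H": (W, D, H), "W": (H, D, W), "D": (H, W, D)}[axis]
    grid = ad.reshape(x, (batch,) + order + (C,))
    inv = {"H": (0, 3, 1, 2, 4), "W": (0, 1, 3, 2, 4), "D": (0, 1, 2, 3, 4)}
    grid = ad.transpose(grid, inv[axis])
    return ad.reshape(grid, (batch, H * W * D, C))


class AxialMHSA(Module):
    """Single-axis multi-head attention with its own Q/K/V/O projections."""

    def __init__(self, channels: int, num_heads: int, rng=None):
        super().__init__()
        if channels % num_heads:
            raise ValueError("num_heads must divide channels")
        self.channels, self.num_heads = channels, num_heads
        rng = rng or np.random.default_rng(0)
        self.q = Linear(channels, channels, rng=rng)
        self.k = Linear(channels, channels, rng=rng)
        self.v = Linear(channels, channels, rng=rng)
        self.o = Linear(channels, channels, rng=rng, gain=0.1)

    def forward(self, x: Tensor) -> Tensor:
        M, L, C = x.shape
        h, c = self.num_heads, self.channels // self.num_heads

        def heads(t):
            return ad.transpose(ad.reshape(t, (M, L, h, c)), (0, 2, 1, 3))

        q, k, v = heads(self.q(x)), heads(self.k(x)), heads(self.v(x))
        scores = ad.matmul(q, ad.transpose(k, (0, 1, 3, 2))) * (1.0 / np.sqrt(c))
        attn = ad.softmax(scores, axis=-1)
        out = ad.matmul(attn, v)
        out = ad.reshape(ad.transpose(out, (0, 2, 1, 3)), (M, L, C))
        return self.o(out)


class IAFAttention(Module):
    """Residual SiLU aggregation of per-axis attention (sequential/summed)."""

    def __init__(self, channels: int, num_heads: int,
                 aggregation: str = "sequential", iterations: int = 1,
                 rng=None):
        super().__init__()
        if iterations < 1:
            raise ValueError("iterations must be >= 1")
        self.aggregation, self.iterations = aggregation, iterations
        rng = rng or np.random.default_rng(0)
        self.attn_h = AxialMHSA(channels, num_heads, rng)
        self.attn_w = AxialMHSA(channels, num_heads, rng)
        self.attn_d = AxialMHSA(channels, num_heads, rng)

    def _axis_attn(self, z: Tensor, dims, axis: str) -> Tensor:
        mod = {"H": self.attn_h, "W": self.attn_w, "D": self.attn_d}[axis]
        B = z.shape[0]
        return _unfold_t(mod(_fold_t(z, dims, axis)), dims, axis, B)

    def forward(self, z: Tensor, dims) -> Tensor:
        for _ in range(self.iterations):
            if self.aggregation == "sequential":
                for ax in AXES:
                    z = z + ad.silu(self._axis_attn(z, dims, ax))
            else:
                total = None
                for ax in AXES:
                    a = self._axis_attn(z, dims, ax)
                    total = a if total is None else total + a
                z = z + ad.silu(total)
        return z


class IAFTBlock(Module):
    """Pre-norm block: Z' = Z + IAF(LN(Z)); Z'' = Z' + MLP(LN(Z'))."""

    def __init__(self, channels: int, num_heads: int, mlp_ratio: float = 2.0,
                 aggregation: str = "sequential", iterations: int = 1,
                 rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        hidden = int(round(mlp_ratio * channels))
        self.ln1 = LayerNorm(channels)
        self.iaf = IAFAttention(channels, num_heads, aggregation, iterations,
                                rng)
        self.ln2 = LayerNorm(channels)
        self.fc1 = Linear(channels, hidden, rng=rng)
        self.fc2 = Linear(hidden, channels, rng=rng, gain=0.1)

    def forward(self, z: Tensor, dims) -> Tensor:
        z = z + self.iaf(self.ln1(z), dims)
        h = ad.silu(self.fc1(self.ln2(z)))
        return z + self.fc2(h)
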