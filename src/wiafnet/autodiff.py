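"""Compact reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records, for every produced value,
its parent tensors and a closure that maps the upstream gradient to parent
gradients.  ``Tensor.backward()`` runs a topological sweep over that tape.

Only the operations the segmentation network needs are implemented:
elementwise arithmetic with broadcasting, batched matmul, shape manipulation,
softmax / layer-norm / SiLU-family activations, 3D convolution (stride 1 or 2),
2×2×2-kernel transposed convolution, trilinear resizing, and the orthonormal
3D Haar analysis/synthesis pair (whose adjoints are each other's inverses).
All structural ops keep gradients exact; nothing here is stochastic.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "add", "sub", "mul", "div", "neg", "pow_", "matmul",
    "exp", "log", "sqrt", "sigmoid", "silu", "relu", "softmax",
    "sum_", "mean", "reshape", "transpose", "concat", "getitem",
    "layer_norm", "conv3d", "conv_transpose3d_2x", "trilinear_resize",
    "haar_dwt3_op", "haar_idwt3_op",
]


class Tensor:
    """An array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents=(), backward=None):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents)
        self.grad = None
        self._parents = tuple(parents) if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- conveniences -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self):
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # operator sugar
    def __add__(self, other):
        return add(self, as_tensor(other))

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, as_tensor(other))

    def __rsub__(self, other):
        return sub(as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, as_tensor(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, as_tensor(other))

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, as_tensor(other))

    def __pow__(self, p):
        return pow_(self, p)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis, keepdims)

    # -- backward sweep ---------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if g is None or not parent.requires_grad:
                    continue
                g = np.asarray(g, dtype=parent.data.dtype)
                if parent.grad is None:
                    parent.grad = g.copy() if g.base is not None else g
                else:
                    parent.grad = parent.grad + g


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# elementwise & reductions
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data
    return Tensor(out, parents=(a, b), backward=lambda g: (
        _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)))


def sub(a: Tensor, b: Tensor) -> Tensor:
    out = a.data - b.data
    return Tensor(out, parents=(a, b), backward=lambda g: (
        _unbroadcast(g, a.data.shape), _unbroadcast(-g, b.data.shape)))


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data * b.data
    return Tensor(out, parents=(a, b), backward=lambda g: (
        _unbroadcast(g * b.data, a.data.shape),
        _unbroadcast(g * a.data, b.data.shape)))


def div(a: Tensor, b: Tensor) -> Tensor:
    out = a.data / b.data
    return Tensor(out, parents=(a, b), backward=lambda g: (
        _unbroadcast(g / b.data, a.data.shape),
        _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape)))


def neg(a: Tensor) -> Tensor:
    return Tensor(-a.data, parents=(a,), backward=lambda g: (-g,))


def pow_(a: Tensor, p: float) -> Tensor:
    out = a.data ** p
    return Tensor(out, parents=(a,),
                  backward=lambda g: (g * p * a.data ** (p - 1),))


def exp(a: Tensor) -> Tensor:
    out = np.exp(a.data)
    return Tensor(out, parents=(a,), backward=lambda g: (g * out,))


def log(a: Tensor) -> Tensor:
    return Tensor(np.log(a.data), parents=(a,),
                  backward=lambda g: (g / a.data,))


def sqrt(a: Tensor) -> Tensor:
    out = np.sqrt(a.data)
    return Tensor(out, parents=(a,), backward=lambda g: (g / (2.0 * out),))


def sigmoid(a: Tensor) -> Tensor:
    out = 1.0 / (1.0 + np.exp(-a.data))
    return Tensor(out, parents=(a,),
                  backward=lambda g: (g * out * (1.0 - out),))


def silu(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.data))
    out = a.data * s
    return Tensor(out, parents=(a,),
                  backward=lambda g: (g * (s * (1.0 + a.data * (1.0 - s))),))


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    return Tensor(a.data * mask, parents=(a,), backward=lambda g: (g * mask,))


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * out).sum(axis=axis, keepdims=True)
        return ((g - dot) * out,)

    return Tensor(out, parents=(a,), backward=backward)


def sum_(a: Tensor, axis=None, keepdims=False) -> Tensor:
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            return (np.broadcast_to(g, a.data.shape),)
        ax = axis if isinstance(axis, tuple) else (axis,)
        if not keepdims:
            g = np.expand_dims(g, ax)
        return (np.broadcast_to(g, a.data.shape),)

    return Tensor(out, parents=(a,), backward=backward)


def mean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[i] for i in (axis if isinstance(axis, tuple) else (axis,))])
    s = sum_(a, axis, keepdims)
    return mul(s, as_tensor(np.asarray(1.0 / n, dtype=a.data.dtype)))


# ---------------------------------------------------------------------------
# shape manipulation
# ---------------------------------------------------------------------------

def reshape(a: Tensor, shape) -> Tensor:
    old = a.data.shape
    return Tensor(a.data.reshape(shape), parents=(a,),
                  backward=lambda g: (g.reshape(old),))


def transpose(a: Tensor, axes) -> Tensor:
    inv = np.argsort(axes)
    return Tensor(a.data.transpose(axes), parents=(a,),
                  backward=lambda g: (g.transpose(inv),))


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(out, parents=tuple(tensors), backward=backward)


def getitem(a: Tensor, idx) -> Tensor:
    out = a.data[idx]

    def backward(g):
        full = np.zeros_like(a.data)
        np.add.at(full, idx, g)
        return (full,)

    return Tensor(out, parents=(a,), backward=backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data @ b.data

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        return (_unbroadcast(ga, a.data.shape), _unbroadcast(gb, b.data.shape))

    return Tensor(out, parents=(a, b), backward=backward)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc ** 2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = xhat * gamma.data + beta.data
    n = x.data.shape[-1]

    def backward(g):
        gg = (g * xhat).sum(axis=tuple(range(g.ndim - 1)))
        gb = g.sum(axis=tuple(range(g.ndim - 1)))
        gx_hat = g * gamma.data
        gx = (gx_hat - gx_hat.mean(axis=-1, keepdims=True)
              - xhat * (gx_hat * xhat).mean(axis=-1, keepdims=True)) * inv
        return (gx, gg, gb)

    return Tensor(out, parents=(x, gamma, beta), backward=backward)


# ---------------------------------------------------------------------------
# 3D convolution family (channels-first (B, C, H, W, D))
# ---------------------------------------------------------------------------

def conv3d(x: Tensor, w: Tensor, b: Tensor | None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """Dense 3D convolution (cross-correlation), kernel (Co, Ci, k, k, k)."""
    xd = x.data
    if padding:
        xd = np.pad(xd, ((0, 0), (0, 0)) + ((padding, padding),) * 3)
    B, Ci, H, W, D = xd.shape
    Co, Ci2, k, _, _ = w.data.shape
    assert Ci == Ci2, "channel mismatch"
    Ho, Wo, Do = (H - k) // stride + 1, (W - k) // stride + 1, (D - k) // stride + 1

    win = np.lib.stride_tricks.sliding_window_view(xd, (k, k, k), axis=(2, 3, 4))
    win = win[:, :, ::stride, ::stride, ::stride]          # B,Ci,Ho,Wo,Do,k,k,k
    col = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(
        B, Ho * Wo * Do, Ci * k ** 3)
    wmat = w.data.reshape(Co, Ci * k ** 3)
    out = (col @ wmat.T).reshape(B, Ho, Wo, Do, Co).transpose(0, 4, 1, 2, 3)
    if b is not None:
        out = out + b.data.reshape(1, Co, 1, 1, 1)

    def backward(g):
        gmat = g.transpose(0, 2, 3, 4, 1).reshape(B * Ho * Wo * Do, Co)
        gw = (gmat.T @ col.reshape(-1, Ci * k ** 3)).reshape(w.data.shape)
        gxp = np.zeros((B, Ci, H, W, D), dtype=xd.dtype)
        # scatter per kernel offset; slices for distinct (p,q,r) may overlap
        # only when stride < k, handled by +=
        for p in range(k):
            for q in range(k):
                for r in range(k):
                    t = np.einsum("bohwd,oc->bchwd", g, w.data[:, :, p, q, r],
                                  optimize=True)
                    gxp[:, :, p:p + stride * Ho:stride,
                        q:q + stride * Wo:stride,
                        r:r + stride * Do:stride] += t
        if padding:
            gxp = gxp[:, :, padding:H - padding, padding:W - padding,
                      padding:D - padding]
        gb = None
        if b is not None:
            gb = g.sum(axis=(0, 2, 3, 4))
        return (gxp, gw, gb)

    parents = (x, w, b) if b is not None else (x, w)
    if b is None:
        return Tensor(out, parents=parents,
                      backward=lambda g: backward(g)[:2])
    return Tensor(out, parents=parents, backward=backward)


def conv_transpose3d_2x(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Transposed 3D convolution, kernel 2, stride 2 (exact ×2 upsampling).

    Weight layout (Ci, Co, 2, 2, 2); every output voxel receives exactly one
    kernel tap, so forward and backward are eight strided einsums.
    """
    B, Ci, H, W, D = x.data.shape
    Ci2, Co = w.data.shape[:2]
    assert Ci == Ci2, "channel mismatch"
    out = np.empty((B, Co, 2 * H, 2 * W, 2 * D), dtype=x.data.dtype)
    for p in range(2):
        for q in range(2):
            for r in range(2):
                out[:, :, p::2, q::2, r::2] = np.einsum(
                    "bihwd,io->bohwd", x.data, w.data[:, :, p, q, r],
                    optimize=True)
    if b is not None:
        out += b.data.reshape(1, Co, 1, 1, 1)

    def backward(g):
        gx = np.zeros_like(x.data)
        gw = np.zeros_like(w.data)
        for p in range(2):
            for q in range(2):
                for r in range(2):
                    gs = g[:, :, p::2, q::2, r::2]
                    gx += np.einsum("bohwd,io->bihwd", gs, w.data[:, :, p, q, r],
                                    optimize=True)
                    gw[:, :, p, q, r] = np.einsum(
                        "bihwd,bohwd->io", x.data, gs, optimize=True)
        gb = g.sum(axis=(0, 2, 3, 4)) if b is not None else None
        return (gx, gw, gb)

    parents = (x, w, b) if b is not None else (x, w)
    if b is None:
        return Tensor(out, parents=parents, backward=lambda g: backward(g)[:2])
    return Tensor(out, parents=parents, backward=backward)


def _linear_resize_matrix(n_in: int, n_out: int, dtype) -> np.ndarray:
    """Dense (n_out, n_in) linear-interpolation matrix (half-pixel centers)."""
    A = np.zeros((n_out, n_in), dtype=dtype)
    if n_in == 1:
        A[:, 0] = 1.0
        return A
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    t = src - lo
    A[np.arange(n_out), lo] += 1.0 - t
    A[np.arange(n_out), hi] += t
    return A


def trilinear_resize(x: Tensor, size: tuple[int, int, int]) -> Tensor:
    """Separable trilinear resampling of (B, C, H, W, D) to `size`."""
    B, C, H, W, D = x.data.shape
    if (H, W, D) == tuple(size):
        return x
    Ah = _linear_resize_matrix(H, size[0], x.data.dtype)
    Aw = _linear_resize_matrix(W, size[1], x.data.dtype)
    Ad = _linear_resize_matrix(D, size[2], x.data.dtype)

    def apply(v, mh, mw, md):
        v = np.einsum("hH,bcHwd->bchwd", mh, v, optimize=True)
        v = np.einsum("wW,bchWd->bchwd", mw, v, optimize=True)
        v = np.einsum("dD,bchwD->bchwd", md, v, optimize=True)
        return v

    out = apply(x.data, Ah, Aw, Ad)
    return Tensor(out, parents=(x,),
                  backward=lambda g: (apply(g, Ah.T, Aw.T, Ad.T),))


# ---------------------------------------------------------------------------
# orthonormal 3D Haar transform as an autodiff op
# ---------------------------------------------------------------------------
# The raw array routines live in wavelet_frontend; imported lazily to avoid a
# circular import at module load.

def haar_dwt3_op(x: Tensor) -> Tensor:
    """(B, C, H, W, D) -> (B, 8C, H/2, W/2, D/2); adjoint = inverse."""
    from .wavelet_frontend import _dwt3_array, _idwt3_array
    out = _dwt3_array(x.data)
    return Tensor(out, parents=(x,),
                  backward=lambda g: (_idwt3_array(g),))


def haar_idwt3_op(x: Tensor) -> Tensor:
    """(B, 8C, h, w, d) -> (B, C, 2h, 2w, 2d); adjoint = inverse."""
    from .wavelet_frontend import _dwt3_array, _idwt3_array
    out = _idwt3_array(x.data)
    return Tensor(out, parents=(x,),
                  backward=lambda g: (_dwt3_array(g),))
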