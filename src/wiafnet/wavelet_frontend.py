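"""Adaptive wavelet-domain feature decoupling (AWD-FD) front end.

The first encoder stage replaces strided-convolution downsampling with a
single-level 3D Haar analysis transform: each input channel is split into
eight half-resolution sub-bands (LLL … HHH, letters ordered height, width,
depth), the 8C sub-band channels are recalibrated by a squeeze-and-excitation
style sigmoid gate, and a learnable 1×1×1 projection maps them into the
stage-1 feature width.  The fixed (non-learnable) Haar filter pair can be
serialized to HDF5.

Conventions
-----------
* Orthonormal Haar filters, phi = (1, 1)/sqrt(2), psi = (1, -1)/sqrt(2), so the
  transform preserves energy (Parseval) and the synthesis transform is the
  exact adjoint/inverse of the analysis transform.
* Decimation uses non-overlapping voxel pairs starting at index 0; every
  spatial dimension of a transform input must therefore be even.
* Band order is channel-major: all eight bands of input channel 0 first, then
  channel 1, etc., with bands enumerated LLL, LLH, LHL, LHH, HLL, HLH, HHL,
  HHH (depth letter varies fastest).
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

__all__ = [
    "BAND_ORDER",
    "FilterBank",
    "MultiChannelVolume",
    "SubbandStack",
    "GateParams",
    "haar_analysis_filters",
    "dwt3",
    "idwt3",
    "gate_weights",
    "recalibrate",
    "awdfd_forward",
    "save_filter_bank",
    "load_filter_bank",
]

_SQRT2 = np.sqrt(2.0)

#: Sub-band names in serialization order; letters map to (height, width, depth).
BAND_ORDER = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")


@dataclass(frozen=True)
class FilterBank:
    """A two-tap analysis filter pair."""

    low: np.ndarray
    high: np.ndarray
    normalization: str = "orthonormal"

    def __post_init__(self):
        object.__setattr__(self, "low", np.asarray(self.low, dtype=np.float64))
        object.__setattr__(self, "high", np.asarray(self.high, dtype=np.float64))
        if self.low.shape != (2,) or self.high.shape != (2,):
            raise ValueError("filters must be length-2 vectors")


@dataclass
class MultiChannelVolume:
    """A (C, H, W, D) image with optional voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected rank-4 (C,H,W,D), got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class SubbandStack:
    """An (8C, H/2, W/2, D/2) stack of wavelet coefficients."""

    data: np.ndarray
    band_order: tuple[str, ...] = BAND_ORDER

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4 or self.data.shape[0] % 8 != 0:
            raise ValueError(
                f"sub-band stack needs 8C channels, got shape {self.data.shape}")

    @property
    def source_channels(self) -> int:
        return self.data.shape[0] // 8


@dataclass
class GateParams:
    """Two-layer sigmoid gate acting on per-channel means of the sub-bands.

    ``w = sigmoid(W2 @ relu(W1 @ GAP(X_sub) + b1) + b2)``; the hidden width
    defaults to ``8C / reduction_ratio`` but may be set directly (the frozen
    reference configuration uses an expansion hidden layer, see the model
    docs).
    """

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    reduction_ratio: int | None = 4

    @classmethod
    def create(cls, channels: int, reduction_ratio: int = 4,
               hidden: int | None = None,
               rng: np.random.Generator | None = None) -> "GateParams":
        if hidden is None:
            if channels % reduction_ratio:
                raise ValueError("reduction_ratio must divide channel count")
            hidden = channels // reduction_ratio
        rng = rng or np.random.default_rng(0)
        s1 = np.sqrt(2.0 / channels)
        s2 = np.sqrt(2.0 / hidden)
        return cls(
            W1=rng.normal(0.0, s1, (hidden, channels)),
            b1=np.zeros(hidden),
            W2=rng.normal(0.0, s2, (channels, hidden)),
            b2=np.zeros(channels),
            reduction_ratio=reduction_ratio,
        )

    @property
    def n_params(self) -> int:
        return self.W1.size + self.b1.size + self.W2.size + self.b2.size


def haar_analysis_filters() -> FilterBank:
    """Return the orthonormal Haar analysis pair."""
    return FilterBank(low=np.array([1.0, 1.0]) / _SQRT2,
                      high=np.array([1.0, -1.0]) / _SQRT2)


# ---------------------------------------------------------------------------
# raw array transforms (shared by the functional API and the autodiff op)
# ---------------------------------------------------------------------------

def _split_axis(x: np.ndarray, axis: int, low: np.ndarray, high: np.ndarray):
    """Two-tap filtering + stride-2 decimation along one axis."""
    n = x.shape[axis]
    if n % 2 or n < 2:
        raise ValueError(f"axis {axis} has odd/short length {n}; "
                         "DWT input dims must be even and >= 2")
    even = np.take(x, np.arange(0, n, 2), axis=axis)
    odd = np.take(x, np.arange(1, n, 2), axis=axis)
    return low[0] * even + low[1] * odd, high[0] * even + high[1] * odd


def _dwt3_array(x: np.ndarray, filters: FilterBank | None = None) -> np.ndarray:
    """(..., C, H, W, D) -> (..., 8C, H/2, W/2, D/2), channel-major bands."""
    fb = filters or haar_analysis_filters()
    lo, hi = fb.low, fb.high
    h_l, h_h = _split_axis(x, -3, lo, hi)
    bands_w = []
    for part in (h_l, h_h):
        w_l, w_h = _split_axis(part, -2, lo, hi)
        bands_w.extend((w_l, w_h))
    bands = []
    for part in bands_w:
        d_l, d_h = _split_axis(part, -1, lo, hi)
        bands.extend((d_l, d_h))
    # bands is ordered LLL,LLH,LHL,LHH,HLL,... each of shape (...,C,h,w,d);
    # interleave to channel-major: (...,C,8,h,w,d) -> (...,8C,h,w,d)
    stacked = np.stack(bands, axis=-4)               # (...,C,8,h,w,d)
    shp = stacked.shape
    return stacked.reshape(shp[:-5] + (shp[-5] * 8,) + shp[-3:])


def _merge_axis(lo_part: np.ndarray, hi_part: np.ndarray, axis: int,
                low: np.ndarray, high: np.ndarray) -> np.ndarray:
    even = low[0] * lo_part + high[0] * hi_part
    odd = low[1] * lo_part + high[1] * hi_part
    out_shape = list(lo_part.shape)
    out_shape[axis] *= 2
    out = np.empty(out_shape, dtype=lo_part.dtype)
    sl_even = [slice(None)] * out.ndim
    sl_even[axis] = slice(0, None, 2)
    sl_odd = [slice(None)] * out.ndim
    sl_odd[axis] = slice(1, None, 2)
    out[tuple(sl_even)] = even
    out[tuple(sl_odd)] = odd
    return out


def _idwt3_array(y: np.ndarray, filters: FilterBank | None = None) -> np.ndarray:
    """Exact inverse of :func:`_dwt3_array` for orthonormal filters."""
    fb = filters or haar_analysis_filters()
    lo, hi = fb.low, fb.high
    if y.shape[-4] % 8:
        raise ValueError(f"channel count {y.shape[-4]} not divisible by 8")
    c = y.shape[-4] // 8
    shp = y.shape
    bands = y.reshape(shp[:-4] + (c, 8) + shp[-3:])   # (...,C,8,h,w,d)
    b = [np.take(bands, i, axis=-4) for i in range(8)]
    # invert depth axis: pairs (LL?,?), bands differ in last letter
    wl_l = _merge_axis(b[0], b[1], -1, lo, hi)   # LL*
    wl_h = _merge_axis(b[2], b[3], -1, lo, hi)   # LH*
    wh_l = _merge_axis(b[4], b[5], -1, lo, hi)   # HL*
    wh_h = _merge_axis(b[6], b[7], -1, lo, hi)   # HH*
    h_l = _merge_axis(wl_l, wl_h, -2, lo, hi)    # L**
    h_h = _merge_axis(wh_l, wh_h, -2, lo, hi)    # H**
    return _merge_axis(h_l, h_h, -3, lo, hi)


# ---------------------------------------------------------------------------
# spec-level operations
# ---------------------------------------------------------------------------

def dwt3(volume: MultiChannelVolume,
         filters: FilterBank | None = None) -> SubbandStack:
    """Single-level separable 3D DWT of every channel."""
    return SubbandStack(_dwt3_array(volume.data.astype(np.float64),
                                    filters))


def idwt3(subbands: SubbandStack,
          filters: FilterBank | None = None) -> MultiChannelVolume:
    """Synthesis transform; exact inverse of :func:`dwt3`."""
    return MultiChannelVolume(_idwt3_array(subbands.data.astype(np.float64),
                                           filters))


def gate_weights(subbands: SubbandStack, params: GateParams) -> np.ndarray:
    """Per-channel sigmoid gate computed from spatial means (GAP)."""
    gap = subbands.data.reshape(subbands.data.shape[0], -1).mean(axis=1)
    h = np.maximum(params.W1 @ gap + params.b1, 0.0)
    return 1.0 / (1.0 + np.exp(-(params.W2 @ h + params.b2)))


def recalibrate(subbands: SubbandStack, w: np.ndarray) -> SubbandStack:
    """Scale channel i of the stack by w[i] (Hadamard recalibration)."""
    w = np.asarray(w)
    if w.shape != (subbands.data.shape[0],):
        raise ValueError(
            f"weight length {w.shape} != channels {subbands.data.shape[0]}")
    return SubbandStack(subbands.data * w[:, None, None, None],
                        band_order=subbands.band_order)


def awdfd_forward(volume: MultiChannelVolume, gate: GateParams,
                  projection_weight: np.ndarray,
                  projection_bias: np.ndarray | None = None
                  ) -> MultiChannelVolume:
    """DWT -> sigmoid gate -> recalibration -> 1x1x1 channel projection.

    `projection_weight` has shape (c1, 8C); output is (c1, H/2, W/2, D/2).
    """
    sub = dwt3(volume)
    w = gate_weights(sub, gate)
    recal = recalibrate(sub, w)
    out = np.einsum("oc,chwd->ohwd", projection_weight, recal.data,
                    optimize=True)
    if projection_bias is not None:
        out = out + np.asarray(projection_bias)[:, None, None, None]
    return MultiChannelVolume(out, spacing=volume.spacing)


# ---------------------------------------------------------------------------
# trainable front-end module (autodiff path) lives in network.py; the op used
# there is autodiff.haar_dwt3_op, which shares _dwt3_array/_idwt3_array above.
# ---------------------------------------------------------------------------

def save_filter_bank(path, filters: FilterBank | None = None) -> None:
    """Serialize the fixed analysis filters to HDF5.

    Layout: float64 datasets ``/haar/low`` and ``/haar/high`` plus a
    ``band_order`` attribute on the ``/haar`` group.
    """
    fb = filters or haar_analysis_filters()
    with h5py.File(path, "w") as f:
        grp = f.create_group("haar")
        grp.create_dataset("low", data=fb.low.astype(np.float64))
        grp.create_dataset("high", data=fb.high.astype(np.float64))
        grp.attrs["band_order"] = ",".join(BAND_ORDER)
        grp.attrs["normalization"] = fb.normalization


def load_filter_bank(path) -> FilterBank:
    with h5py.File(path, "r") as f:
        grp = f["haar"]
        order = tuple(grp.attrs["band_order"].split(","))
        if order != BAND_ORDER:
            raise ValueError(f"unexpected band order {order}")
        return FilterBank(low=grp["low"][()], high=grp["high"][()],
                          normalization=str(grp.attrs["normalization"]))
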