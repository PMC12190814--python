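"""The WIAF segmentation network and its ablation variants.

Encoder: stage 1 downsamples with the adaptive wavelet front end (AWD-FD);
stages 2-4 use stride-2 3x3x3 convolutions with channel expansion; every
stage stacks IAFT blocks.  Decoder (MSFFD): per-level axial refinement at
native resolution, alignment to the stride-2 grid, channel concatenation and
compression, progressive upsampling back to input resolution, and a
pointwise classifier.

Ablation variants mirror the published study design:

* ``B``              - conv downsampling + standard MHSA (stage-1 keys/values
                       spatially reduced) + plain transposed-conv decoder
* ``B+MSFFD``        - as B but with the multi-scale fusion decoder
* ``B+MSFFD+IAFT``   - as B+MSFFD with IAFT blocks instead of standard MHSA
* ``full``           - B+MSFFD+IAFT with the wavelet front end as stage 1
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from . import budgets
from .autodiff import Tensor
from .axial_attention import AxialMHSA, IAFAttention, IAFTBlock
from .config import ModelConfig
from .nn import (Conv3d, ConvTranspose3d2x, LayerNorm, Linear, Module,
                 DTYPE)
from .wavelet_frontend import MultiChannelVolume

__all__ = [
    "FeaturePyramid", "WIAF", "build_variant",
    "encoder_forward", "msffd_forward", "wiaf_forward",
    "count_params", "count_macs",
]


@dataclass
class FeaturePyramid:
    """Encoder features C1..C4 at strides 2/4/8/16 (each (c_i, h, w, d))."""

    features: list

    def __post_init__(self):
        if len(self.features) != 4:
            raise ValueError("expected four pyramid levels")
        for lo, hi in zip(self.features, self.features[1:]):
            if tuple(hi.shape[-3:]) != tuple(s // 2 for s in lo.shape[-3:]):
                raise ValueError("each level must halve the previous dims")


def _vol_to_tokens(x: Tensor) -> tuple[Tensor, tuple]:
    B, C, H, W, D = x.shape
    t = ad.reshape(ad.transpose(x, (0, 2, 3, 4, 1)), (B, H * W * D, C))
    return t, (H, W, D)


def _tokens_to_vol(t: Tensor, dims) -> Tensor:
    B, N, C = t.shape
    H, W, D = dims
    return ad.transpose(ad.reshape(t, (B, H, W, D, C)), (0, 4, 1, 2, 3))


class AWDFDStem(Module):
    """Wavelet decomposition -> sigmoid sub-band gate -> 1x1x1 projection."""

    def __init__(self, in_channels: int, out_channels: int, gate_hidden: int,
                 rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        bands = 8 * in_channels
        self.gate_fc1 = Linear(bands, gate_hidden, rng=rng)
        self.gate_fc2 = Linear(gate_hidden, bands, rng=rng)
        self.proj = Conv3d(bands, out_channels, kernel=1, padding=0, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        sub = ad.haar_dwt3_op(x)                     # (B, 8C, h, w, d)
        gap = ad.mean(sub, axis=(2, 3, 4))           # (B, 8C)
        w = ad.sigmoid(self.gate_fc2(ad.relu(self.gate_fc1(gap))))
        B, bands = w.shape
        recal = sub * ad.reshape(w, (B, bands, 1, 1, 1))
        return self.proj(recal)


class IAFTStageBlock(Module):
    """IAFT transformer block operating on a (B, C, H, W, D) volume."""

    def __init__(self, channels, num_heads, mlp_ratio, aggregation,
                 iterations, rng=None):
        super().__init__()
        self.block = IAFTBlock(channels, num_heads, mlp_ratio, aggregation,
                               iterations, rng)

    def forward(self, x: Tensor) -> Tensor:
        t, dims = _vol_to_tokens(x)
        return _tokens_to_vol(self.block(t, dims), dims)


class StdAttnBlock(Module):
    """Standard pre-norm MHSA block; optional stride-2 K/V reduction."""

    def __init__(self, channels, num_heads, mlp_ratio, kv_reduce=False,
                 rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.channels, self.num_heads = channels, num_heads
        self.kv_reduce = kv_reduce
        if kv_reduce:
            self.reduce = Conv3d(channels, channels, kernel=3, stride=2,
                                 padding=1, rng=rng)
        self.ln1 = LayerNorm(channels)
        self.q = Linear(channels, channels, rng=rng)
        self.k = Linear(channels, channels, rng=rng)
        self.v = Linear(channels, channels, rng=rng)
        self.o = Linear(channels, channels, rng=rng, gain=0.1)
        hidden = int(round(mlp_ratio * channels))
        self.ln2 = LayerNorm(channels)
        self.fc1 = Linear(channels, hidden, rng=rng)
        self.fc2 = Linear(hidden, channels, rng=rng, gain=0.1)

    def forward(self, x: Tensor) -> Tensor:
        tokens, dims = _vol_to_tokens(x)
        zq = self.ln1(tokens)
        if self.kv_reduce:
            red = self.reduce(_tokens_to_vol(zq, dims))
            zkv, _ = _vol_to_tokens(red)
        else:
            zkv = zq
        B, N, C = zq.shape
        h, c = self.num_heads, C // self.num_heads

        def heads(t):
            M, L, _ = t.shape
            return ad.transpose(ad.reshape(t, (M, L, h, c)), (0, 2, 1, 3))

        q = heads(self.q(zq))
        k = heads(self.k(zkv))
        v = heads(self.v(zkv))
        attn = ad.softmax(ad.matmul(q, ad.transpose(k, (0, 1, 3, 2)))
                          * (1.0 / np.sqrt(c)), axis=-1)
        out = ad.reshape(ad.transpose(ad.matmul(attn, v), (0, 2, 1, 3)),
                         (B, N, C))
        tokens = tokens + self.o(out)
        hdn = ad.silu(self.fc1(self.ln2(tokens)))
        tokens = tokens + self.fc2(hdn)
        return _tokens_to_vol(tokens, dims)


class DecoderAxialRefine(Module):
    """Pre-norm axial-attention refinement: F + (IAF(LN(F)) - LN(F))."""

    def __init__(self, channels, num_heads, rng=None):
        super().__init__()
        self.ln = LayerNorm(channels)
        self.iaf = IAFAttention(channels, num_heads, "sequential", 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        t, dims = _vol_to_tokens(x)
        a = self.ln(t)
        t = t + (self.iaf(a, dims) - a)
        return _tokens_to_vol(t, dims)


class MSFFD(Module):
    """Multi-scale feature fusion decoder."""

    def __init__(self, cfg: ModelConfig, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        c = cfg.stage_channels
        dec = cfg.decoder
        w, f, g = dec.attn_widths, dec.fusion_width, dec.compress_width
        self.pre = [Conv3d(c[i], w[i], kernel=1, padding=0, rng=rng)
                    for i in range(4)]
        self.refine = [DecoderAxialRefine(w[i], dec.num_heads, rng)
                       for i in range(4)]
        self.align0 = Conv3d(w[0], f, kernel=1, padding=0, rng=rng)
        self.align = [ConvTranspose3d2x(w[i], f, rng=rng) for i in (1, 2, 3)]
        self.compress = Conv3d(4 * f, g, kernel=1, padding=0, rng=rng)
        self.up = ConvTranspose3d2x(g, g, rng=rng)
        self.classifier = Conv3d(g, cfg.num_classes, kernel=1, padding=0,
                                 rng=rng, gain=0.1)

    def forward(self, pyramid: list, out_size) -> Tensor:
        half = tuple(s // 2 for s in out_size)
        aligned = []
        for i, feat in enumerate(pyramid):
            x = self.refine[i](self.pre[i](feat))
            if i == 0:
                x = self.align0(x)
            else:
                x = self.align[i - 1](x)
            x = ad.trilinear_resize(x, half)
            aligned.append(x)
        fused = self.compress(ad.concat(aligned, axis=1))
        up = ad.trilinear_resize(self.up(fused), out_size)
        return self.classifier(up)


class PlainDecoder(Module):
    """Transposed-conv-only decoder used by the ablation baseline."""

    def __init__(self, cfg: ModelConfig, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        c = cfg.stage_channels
        f = cfg.decoder.fusion_width
        self.pre = [Conv3d(c[i], f, kernel=1, padding=0, rng=rng)
                    for i in range(4)]
        self.chains = [[ConvTranspose3d2x(f, f, rng=rng) for _ in range(i)]
                       for i in range(4)]
        for i, chain in enumerate(self.chains):
            for j, m in enumerate(chain):
                self._modules[f"chain{i}.{j}"] = m
        self.fuse = Conv3d(4 * f, f, kernel=1, padding=0, rng=rng)
        self.up = ConvTranspose3d2x(f, f, rng=rng)
        self.classifier = Conv3d(f, cfg.num_classes, kernel=1, padding=0,
                                 rng=rng, gain=0.1)

    def forward(self, pyramid: list, out_size) -> Tensor:
        half = tuple(s // 2 for s in out_size)
        aligned = []
        for i, feat in enumerate(pyramid):
            x = self.pre[i](feat)
            for m in self.chains[i]:
                x = m(x)
            x = ad.trilinear_resize(x, half)
            aligned.append(x)
        fused = self.fuse(ad.concat(aligned, axis=1))
        up = ad.trilinear_resize(self.up(fused), out_size)
        return self.classifier(up)


class WIAF(Module):
    """Encoder-decoder segmentation model (see module docstring)."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        c = cfg.stage_channels
        use_iaft = cfg.variant in ("full", "B+MSFFD+IAFT")

        if cfg.variant == "full":
            self.stem = AWDFDStem(cfg.in_channels, c[0],
                                  cfg.resolved_gate_hidden, rng)
        else:
            self.stem = Conv3d(cfg.in_channels, c[0], kernel=3, stride=2,
                               padding=1, rng=rng)

        def make_blocks(i):
            blocks = []
            for _ in range(cfg.blocks_per_stage[i]):
                if use_iaft:
                    blocks.append(IAFTStageBlock(
                        c[i], cfg.num_heads[i], cfg.mlp_ratio,
                        cfg.aggregation, cfg.iterations, rng))
                else:
                    blocks.append(StdAttnBlock(
                        c[i], cfg.num_heads[i], cfg.mlp_ratio,
                        kv_reduce=(i == 0), rng=rng))
            return blocks

        self.stage1 = make_blocks(0)
        self.down2 = Conv3d(c[0], c[1], kernel=3, stride=2, padding=1, rng=rng)
        self.stage2 = make_blocks(1)
        self.down3 = Conv3d(c[1], c[2], kernel=3, stride=2, padding=1, rng=rng)
        self.stage3 = make_blocks(2)
        self.down4 = Conv3d(c[2], c[3], kernel=3, stride=2, padding=1, rng=rng)
        self.stage4 = make_blocks(3)

        if cfg.variant == "B":
            self.decoder = PlainDecoder(cfg, rng)
        else:
            self.decoder = MSFFD(cfg, rng)

    # -- forward ----------------------------------------------------------
    def encode(self, x: Tensor) -> list:
        dims = x.shape[-3:]
        if any(s % 16 for s in dims):
            raise ValueError(f"input dims {dims} must be divisible by 16")
        feats = []
        h = self.stem(x)
        for blk in self.stage1:
            h = blk(h)
        feats.append(h)
        for down, stage in ((self.down2, self.stage2),
                            (self.down3, self.stage3),
                            (self.down4, self.stage4)):
            h = down(h)
            for blk in stage:
                h = blk(h)
            feats.append(h)
        return feats

    def forward(self, x: Tensor) -> Tensor:
        out_size = tuple(x.shape[-3:])
        return self.decoder(self.encode(x), out_size)


# ---------------------------------------------------------------------------
# spec-level functional interface
# ---------------------------------------------------------------------------

def build_variant(cfg: ModelConfig, variant: str | None = None,
                  seed: int = 0) -> WIAF:
    """Instantiate a model, optionally overriding the configured variant."""
    if variant is not None:
        d = cfg.to_dict()
        d["variant"] = variant
        cfg = ModelConfig.from_dict(d)
    return WIAF(cfg, seed=seed)


def _as_batch(volume) -> np.ndarray:
    data = volume.data if isinstance(volume, MultiChannelVolume) else np.asarray(volume)
    return data[None].astype(DTYPE)


def encoder_forward(model: WIAF, volume) -> FeaturePyramid:
    feats = model.encode(Tensor(_as_batch(volume)))
    return FeaturePyramid([f.data[0] for f in feats])


def msffd_forward(model: WIAF, pyramid: FeaturePyramid,
                  out_size=None) -> np.ndarray:
    feats = [Tensor(np.asarray(f, dtype=DTYPE)[None])
             for f in pyramid.features]
    if out_size is None:
        out_size = tuple(2 * s for s in feats[0].shape[-3:])
    return model.decoder(feats, tuple(out_size)).data[0]


def wiaf_forward(model: WIAF, volume) -> np.ndarray:
    """Forward pass on a (C, H, W, D) array; returns (K, H, W, D) logits."""
    return model(Tensor(_as_batch(volume))).data[0]


def count_params(model: WIAF) -> tuple[int, dict[str, int]]:
    """Trainable-scalar count with a per-component breakdown."""
    groups: dict[str, int] = {}
    for name, p in model.named_parameters():
        comp = name.split(".", 1)[0]
        if comp.startswith("stage"):
            key = comp[:6]
        elif comp in ("stem", "decoder") or comp.startswith("down"):
            key = comp
        else:
            key = comp
        groups[key] = groups.get(key, 0) + p.data.size
    return sum(groups.values()), groups


def count_macs(model_or_cfg, input_shape=(4, 128, 128, 128)
               ) -> tuple[int, dict[str, int]]:
    """Analytic MAC count of one forward pass (see budgets module)."""
    cfg = model_or_cfg.cfg if isinstance(model_or_cfg, WIAF) else model_or_cfg
    bd = budgets.macs_breakdown(cfg, input_shape)
    return sum(bd.values()), bd
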