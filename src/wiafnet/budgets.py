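"""Analytic parameter and multiply-accumulate (MAC) accounting.

The formulas here mirror the module definitions in ``network.py`` exactly;
a unit test asserts that the analytic parameter count equals the count
obtained by walking the instantiated model's arrays.

MAC convention (1 reported FLOP = 1 MAC): convolutions, transposed
convolutions, channel projections, the gating MLP, sub-band recalibration,
the fixed wavelet filter bank, and attention score/value products are
counted; normalizations, activations, softmax normalizers, residual
additions and trilinear interpolation are excluded.  Biases are not counted.
"""

from __future__ import annotations

from .config import ModelConfig

__all__ = ["params_breakdown", "macs_breakdown", "total_params", "total_macs"]


def _iaft_block_params(C: int, mlp_ratio: float) -> int:
    hidden = int(round(mlp_ratio * C))
    attn = 3 * 4 * (C * C + C)            # per-axis Q/K/V/O with bias
    norms = 4 * C                          # two layer norms
    mlp = hidden * C + hidden + C * hidden + C
    return attn + norms + mlp


def _std_block_params(C: int, mlp_ratio: float, kv_reduce: bool) -> int:
    hidden = int(round(mlp_ratio * C))
    attn = 4 * (C * C + C)
    norms = 4 * C
    mlp = hidden * C + hidden + C * hidden + C
    red = (27 * C * C + C) if kv_reduce else 0
    return attn + norms + mlp + red


def params_breakdown(cfg: ModelConfig) -> dict[str, int]:
    """Trainable parameters per component for a given configuration."""
    c = cfg.stage_channels
    b = cfg.blocks_per_stage
    rho = cfg.mlp_ratio
    out: dict[str, int] = {}

    eight_c = 8 * cfg.in_channels
    if cfg.variant == "full":
        h = cfg.resolved_gate_hidden
        gate = h * eight_c + h + eight_c * h + eight_c
        proj = eight_c * c[0] + c[0]
        out["stem"] = gate + proj
    else:
        out["stem"] = 27 * cfg.in_channels * c[0] + c[0]

    use_iaft = cfg.variant in ("full", "B+MSFFD+IAFT")
    for i in range(4):
        if use_iaft:
            blk = _iaft_block_params(c[i], rho)
        else:
            blk = _std_block_params(c[i], rho, kv_reduce=(i == 0))
        out[f"stage{i + 1}"] = b[i] * blk
        if i > 0:
            out[f"down{i + 1}"] = 27 * c[i - 1] * c[i] + c[i]

    use_msffd = cfg.variant != "B"
    dec = cfg.decoder
    K = cfg.num_classes
    if use_msffd:
        w = dec.attn_widths
        f, g = dec.fusion_width, dec.compress_width
        total = 0
        for i in range(4):
            total += c[i] * w[i] + w[i]              # native 1x1 pre-projection
            total += 12 * (w[i] * w[i] + w[i]) + 2 * w[i]   # axial refine + LN
            if i == 0:
                total += w[i] * f + f                # 1x1 align
            else:
                total += 8 * w[i] * f + f            # 2x transposed conv
        total += 4 * f * g + g                       # concat compression
        total += 8 * g * g + g                       # final 2x transposed conv
        total += g * K + K                           # pointwise classifier
        out["decoder"] = total
    else:
        f = dec.fusion_width
        total = 0
        for i in range(4):
            total += c[i] * f + f
            total += i * (8 * f * f + f)             # chain of 2x up-convs
        total += 4 * f * f + f
        total += 8 * f * f + f
        total += f * K + K
        out["decoder"] = total
    return out


def total_params(cfg: ModelConfig) -> int:
    return sum(params_breakdown(cfg).values())


def macs_breakdown(cfg: ModelConfig, input_shape=(4, 128, 128, 128)
                   ) -> dict[str, int]:
    """Analytic MACs of one forward pass (batch 1) under the convention."""
    Cin, H, W, D = input_shape
    if Cin != cfg.in_channels:
        raise ValueError("input channels disagree with the configuration")
    c = cfg.stage_channels
    b = cfg.blocks_per_stage
    rho = cfg.mlp_ratio
    out: dict[str, int] = {}

    n_full = H * W * D
    sides = [(H >> i, W >> i, D >> i) for i in range(1, 5)]   # strides 2..16
    nvox = [s[0] * s[1] * s[2] for s in sides]
    eight_c = 8 * Cin

    if cfg.variant == "full":
        h = cfg.resolved_gate_hidden
        dwt = 6 * Cin * n_full
        gate = 2 * eight_c * h
        recal = eight_c * nvox[0]
        proj = eight_c * c[0] * nvox[0]
        out["stem"] = dwt + gate + recal + proj
    else:
        out["stem"] = 27 * Cin * c[0] * nvox[0]

    use_iaft = cfg.variant in ("full", "B+MSFFD+IAFT")
    for i in range(4):
        N = nvox[i]
        C = c[i]
        hidden = int(round(rho * C))
        mlp = N * C * hidden * 2
        if use_iaft:
            attn_proj = 12 * N * C * C
            score_val = sum(2 * N * L * C for L in sides[i])
        else:
            if i == 0:
                # K/V spatially reduced by a stride-2 3^3 conv
                Nk = N // 8
                attn_proj = (N * C * C            # Q
                             + 2 * Nk * C * C     # K, V
                             + N * C * C          # output
                             + 27 * C * C * Nk)   # reduction conv
                score_val = 2 * N * Nk * C
            else:
                attn_proj = 4 * N * C * C
                score_val = 2 * N * N * C
        out[f"stage{i + 1}"] = b[i] * (attn_proj + score_val + mlp)
        if i > 0:
            out[f"down{i + 1}"] = 27 * c[i - 1] * c[i] * nvox[i]

    dec = cfg.decoder
    K = cfg.num_classes
    if cfg.variant != "B":
        w = dec.attn_widths
        f, g = dec.fusion_width, dec.compress_width
        total = 0
        for i in range(4):
            N = nvox[i]
            total += N * c[i] * w[i]
            total += 12 * N * w[i] * w[i]
            total += sum(2 * N * L * w[i] for L in sides[i])
            if i == 0:
                total += N * w[i] * f
            else:
                total += 8 * N * w[i] * f        # 2x up-conv, output 8N voxels
        total += nvox[0] * 4 * f * g
        total += 8 * nvox[0] * g * g             # final 2x up-conv to full res
        total += g * K * n_full
        out["decoder"] = total
    else:
        f = dec.fusion_width
        total = 0
        for i in range(4):
            total += nvox[i] * c[i] * f
            # chain of 2x up-convs back to stride-2 resolution
            total += sum(8 * nvox[j] * f * f for j in range(1, i + 1))
        total += nvox[0] * 4 * f * f
        total += 8 * nvox[0] * f * f
        total += f * K * n_full
        out["decoder"] = total
    return out


def total_macs(cfg: ModelConfig, input_shape=(4, 128, 128, 128)) -> int:
    return sum(macs_breakdown(cfg, input_shape).values())
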