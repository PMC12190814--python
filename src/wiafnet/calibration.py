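"""One-time calibration of the frozen reference configuration.

The published description fixes the architecture family but not its widths,
depths or decoder dimensions.  This module searches that space once for a
configuration whose analytic budgets simultaneously satisfy

* total trainable parameters of the full model    = 5.23 M (2 d.p.),
* trainable parameters of the MSFFD decoder       = 167,940 exactly,
* total parameters of the B+MSFFD+IAFT variant    = 5.19 M (2 d.p.),
* analytic MACs of the full model at (4, 128^3)   = 9.75 G (2 d.p.),

and writes the winner to ``reference_config.yaml``.  The gating-MLP hidden
width is the final closing knob: it shifts only the full model's parameter
count (the conv-stem variants have no gate) at negligible MAC cost.

The inline vectorized formulas mirror :mod:`wiafnet.budgets`; the chosen
candidate is re-verified through that module before being returned.
"""

from __future__ import annotations

import itertools

import numpy as np

from . import budgets
from .config import DecoderConfig, ModelConfig

P_FULL = (5_225_000, 5_235_000)        # rounds to 5.23 M
P_VARIANT = (5_185_000, 5_195_000)     # rounds to 5.19 M
P_DECODER = 167_940
M_FULL = (9_745_000_000, 9_755_000_000)  # rounds to 9.75 G at (4, 128^3)

_S = 128
_N = [( _S >> (i + 1)) ** 3 for i in range(4)]       # voxels per stage
_SIDE = [_S >> (i + 1) for i in range(4)]
_NFULL = _S ** 3
_K = 4            # classes
_CIN = 4          # modalities


def _iaft_params(C, rho):
    hidden = int(round(rho * C))
    return 12 * C * C + 16 * C + hidden * C + hidden + C * hidden + C


def _enc_params(c, b, rho):
    total = sum(b[i] * _iaft_params(c[i], rho) for i in range(4))
    total += sum(27 * c[i - 1] * c[i] + c[i] for i in (1, 2, 3))
    return total


def _enc_macs_full_stem(c, b, rho):
    """Encoder MACs with the wavelet stem, excluding the gate MLP."""
    total = 6 * _CIN * _NFULL                 # separable Haar analysis
    total += 8 * _CIN * _N[0]                 # recalibration product
    total += 8 * _CIN * c[0] * _N[0]          # 1x1x1 projection
    for i in range(4):
        hidden = int(round(rho * c[i]))
        blk = (12 * _N[i] * c[i] * c[i]
               + 6 * _N[i] * _SIDE[i] * c[i]
               + 2 * _N[i] * c[i] * hidden)
        total += b[i] * blk
    total += sum(27 * c[i - 1] * c[i] * _N[i] for i in (1, 2, 3))
    return total


def _level_params(ci, wi, f, first):
    """Decoder-level parameters: pre-proj + axial refine + alignment."""
    p = ci * wi + wi + 12 * wi * wi + 14 * wi
    p += (wi * f + f) if first else (8 * wi * f + f)
    return p


def _level_macs(i, ci, wi, f):
    m = _N[i] * ci * wi + 12 * _N[i] * wi * wi + 6 * _N[i] * _SIDE[i] * wi
    m += _N[0] * wi * f if i == 0 else 8 * _N[i] * wi * f
    return m


def search(verbose: bool = False) -> list[dict]:
    """Enumerate calibration candidates meeting all four budget targets."""
    heads = (2, 4, 4, 8)
    w2g = np.arange(6, 41, dtype=np.int64)
    w3g = np.arange(8, 113, dtype=np.int64)
    w4g = np.arange(8, 257, dtype=np.int64)
    gg = np.arange(6, 49, dtype=np.int64)
    hits = []
    coarse = itertools.product(
        (8, 16),                      # c1
        (16, 24, 32, 40, 48),         # c2
        range(48, 145, 8),            # c3
        range(128, 513, 8),           # c4
        (1, 2), (1, 2), (1, 2, 3),    # b2, b3, b4
        (1, 2),                       # rho
    )
    for c1, c2, c3, c4, b2, b3, b4, rho in coarse:
        c = (c1, c2, c3, c4)
        if list(c) != sorted(c) or any(ci % h for ci, h in zip(c, heads)):
            continue
        b = (1, b2, b3, b4)
        enc_p = _enc_params(c, b, rho)
        p_v = enc_p + 27 * _CIN * c1 + c1 + P_DECODER   # conv stem variant
        if not (P_VARIANT[0] <= p_v < P_VARIANT[1]):
            continue
        # close the full-model parameter window with the gate hidden width
        base_full = p_v - (27 * _CIN * c1 + c1) + (8 * _CIN * c1 + c1) + 8 * _CIN
        h_gate = -(-(P_FULL[0] - base_full) // 65)      # ceil division
        p_full = base_full + 65 * h_gate
        if h_gate < 8 or not (P_FULL[0] <= p_full < P_FULL[1]):
            continue
        enc_m = _enc_macs_full_stem(c, b, rho) + 2 * 8 * _CIN * h_gate
        for w1 in (8, 12, 16):
            for f in (8, 12, 16, 20, 24, 32):
                # params of levels 2-4 over the (w2, w3, w4) grid
                w2, w3, w4 = np.meshgrid(w2g, w3g, w4g, indexing="ij")
                A = (_level_params(c[1], w2, f, False)
                     + _level_params(c[2], w3, f, False)
                     + _level_params(c[3], w4, f, False))
                flatA = A.ravel()
                order = np.argsort(flatA, kind="stable")
                sortedA = flatA[order]
                p1 = _level_params(c[0], w1, f, True)
                for g in gg:
                    g = int(g)
                    tail = (4 * f * g + g) + (8 * g * g + g) + (g * _K + _K)
                    target = P_DECODER - p1 - tail
                    loi = np.searchsorted(sortedA, target, side="left")
                    hii = np.searchsorted(sortedA, target, side="right")
                    for idx in order[loi:hii]:
                        i2, i3, i4 = np.unravel_index(idx, A.shape)
                        ws = (w1, int(w2g[i2]), int(w3g[i3]), int(w4g[i4]))
                        m_dec = sum(_level_macs(i, c[i], ws[i], f)
                                    for i in range(4))
                        m_dec += (_N[0] * 4 * f * g + 8 * _N[0] * g * g
                                  + g * _K * _NFULL)
                        total_m = enc_m + m_dec
                        if not (M_FULL[0] <= total_m < M_FULL[1]):
                            continue
                        hit = {
                            "stage_channels": c, "blocks": b, "rho": rho,
                            "gate_hidden": int(h_gate),
                            "attn_widths": ws,
                            "fusion_width": f, "compress_width": g,
                            "p_full": int(p_full), "p_variant": int(p_v),
                            "macs_full": int(total_m),
                        }
                        hits.append(hit)
                        if verbose:
                            print(hit)
    return hits


def _to_config(hit: dict) -> ModelConfig:
    return ModelConfig(
        stage_channels=hit["stage_channels"],
        blocks_per_stage=hit["blocks"],
        num_heads=(2, 4, 4, 8),
        mlp_ratio=float(hit["rho"]),
        gate_hidden=hit["gate_hidden"],
        decoder=DecoderConfig(attn_widths=hit["attn_widths"],
                              fusion_width=hit["fusion_width"],
                              compress_width=hit["compress_width"],
                              num_heads=1),
        variant="full",
    )


def calibrate(verbose: bool = False) -> ModelConfig:
    """Run the search and return the first verified configuration.

    Candidates are ordered to prefer shallow stage-4 stacks and small
    decoder widths (the lighter architectures); the winner is re-verified
    against :mod:`wiafnet.budgets` for all four targets.
    """
    hits = search(verbose=verbose)
    if not hits:
        raise RuntimeError("calibration search found no feasible configuration")
    hits.sort(key=lambda h: (h["blocks"][3], sum(h["attn_widths"]),
                             h["stage_channels"][3]))
    for hit in hits:
        cfg = _to_config(hit)
        pb = budgets.params_breakdown(cfg)
        p_full = sum(pb.values())
        m_full = budgets.total_macs(cfg, (4, 128, 128, 128))
        d = cfg.to_dict()
        d["variant"] = "B+MSFFD+IAFT"
        p_var = budgets.total_params(ModelConfig.from_dict(d))
        ok = (round(p_full / 1e6, 2) == 5.23
              and pb["decoder"] == P_DECODER
              and round(p_var / 1e6, 2) == 5.19
              and round(m_full / 1e9, 2) == 9.75)
        if ok:
            return cfg
    raise RuntimeError("no candidate survived budget re-verification")
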