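"""Model configuration: a structured, serializable description of one model.

A :class:`ModelConfig` fully determines the architecture (and, with a seed,
the initialization).  The repository commits one frozen *reference
configuration* (``reference_config.yaml``) calibrated once so that the
analytic parameter/MAC budgets of the full model match the published figures;
all budget accounting runs against that file.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import yaml

VARIANTS = ("full", "B", "B+MSFFD", "B+MSFFD+IAFT")


@dataclass
class DecoderConfig:
    """Multi-scale fusion decoder widths."""

    attn_widths: tuple[int, int, int, int] = (8, 8, 16, 32)
    fusion_width: int = 16
    compress_width: int = 16
    num_heads: int = 2

    def __post_init__(self):
        self.attn_widths = tuple(int(v) for v in self.attn_widths)
        if any(w % self.num_heads for w in self.attn_widths):
            raise ValueError("decoder attention widths must be divisible by num_heads")


@dataclass
class ModelConfig:
    stage_channels: tuple[int, int, int, int] = (8, 16, 32, 64)
    blocks_per_stage: tuple[int, int, int, int] = (1, 1, 1, 1)
    num_heads: tuple[int, int, int, int] = (2, 4, 4, 8)
    in_channels: int = 4
    num_classes: int = 4
    mlp_ratio: float = 2.0
    gate_hidden: int | None = None   # default: 8*in_channels // gate_reduction
    gate_reduction: int = 4
    iterations: int = 1
    aggregation: str = "sequential"
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    variant: str = "full"

    def __post_init__(self):
        self.stage_channels = tuple(int(v) for v in self.stage_channels)
        self.blocks_per_stage = tuple(int(v) for v in self.blocks_per_stage)
        self.num_heads = tuple(int(v) for v in self.num_heads)
        if isinstance(self.decoder, dict):
            self.decoder = DecoderConfig(**self.decoder)
        if list(self.stage_channels) != sorted(self.stage_channels):
            raise ValueError("stage_channels must be nondecreasing")
        for c, h in zip(self.stage_channels, self.num_heads):
            if c % h:
                raise ValueError(f"channels {c} not divisible by heads {h}")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; "
                             f"choose from {VARIANTS}")
        if self.aggregation not in ("sequential", "summed"):
            raise ValueError("aggregation must be sequential|summed")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")

    @property
    def resolved_gate_hidden(self) -> int:
        if self.gate_hidden is not None:
            return int(self.gate_hidden)
        return (8 * self.in_channels) // self.gate_reduction

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["stage_channels"] = list(self.stage_channels)
        d["blocks_per_stage"] = list(self.blocks_per_stage)
        d["num_heads"] = list(self.num_heads)
        d["decoder"]["attn_widths"] = list(self.decoder.attn_widths)
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def reference(cls, variant: str = "full") -> "ModelConfig":
        """The frozen, committed reference configuration."""
        text = resources.files("wiafnet").joinpath(
            "reference_config.yaml").read_text()
        cfg = cls.from_dict(yaml.safe_load(text))
        cfg.variant = variant
        return cfg

    @classmethod
    def desk(cls, variant: str = "full") -> "ModelConfig":
        """Small CPU-trainable preset used for desk-scale runs and tests."""
        return cls(stage_channels=(8, 16, 24, 32),
                   blocks_per_stage=(1, 1, 1, 1),
                   num_heads=(2, 4, 4, 8),
                   mlp_ratio=1.0,
                   decoder=DecoderConfig(attn_widths=(8, 8, 8, 8),
                                         fusion_width=8, compress_width=8,
                                         num_heads=2),
                   variant=variant)
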