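stage_channels:
- 8
- 40
- 120
- 432
blocks_per_stage:
- 1
- 1
- 2
- 1
num_heads:
- 2
- 4
- 4
- 8
in_channels: 4
num_classes: 4
mlp_ratio: 2.0
gate_hidden: 480
gate_reduction: 4
iterations: 1
aggregation: sequential
decoder:
  attn_widths:
  - 8
  - 12
  - 19
  - 89
  fusion_width: 20
  compress_width: 16
  num_heads: 1
variant: full
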