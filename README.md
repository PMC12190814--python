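# wiafnet

Lightweight 3D brain-tumor segmentation from multimodal MRI, built around
three ideas:

* **AWD-FD** — adaptive wavelet-domain feature decoupling: the first encoder
  stage downsamples with a single-level 3D Haar transform instead of a
  strided convolution. Each input channel splits into eight half-resolution
  sub-bands (LLL … HHH); a squeeze-and-excitation-style sigmoid gate
  `w = σ(W₂·ReLU(W₁·GAP(X_sub)))` recalibrates the 8C sub-band channels
  (`X̃ = X_sub ⊙ w`) before a learnable 1×1×1 projection into the stage-1
  width. High-frequency detail that pooling would discard stays available to
  the network, at a cost the gate can modulate per volume.
* **IAFT** — iterative axial factorized attention: instead of full 3D
  self-attention over N = H·W·D voxels (O(N²) score/value cost), attention
  runs along one spatial axis at a time with the other two folded into the
  batch, `Z ← Z + SiLU(Attn_α(Z))` for α ∈ {H, W, D}. On cubes the
  score/value cost drops to O(N^{4/3}).
* **MSFFD** — a multi-scale fusion decoder: each encoder level is refined by
  a lightweight axial-attention pass at its native resolution, aligned to the
  stride-2 grid by transposed convolution + trilinear interpolation,
  concatenated, compressed by 1×1×1 convolution, progressively upsampled,
  and classified pointwise.

Training optimizes `L = λ₁·L_Dice + λ₂·L_CE`; evaluation reports Dice and
the 95th-percentile Hausdorff surface distance (HD95) on the nested BraTS
regions ET ⊆ TC ⊆ WT composed from labels {4}, {1,4}, {1,2,4}.

The package is self-contained on CPU: the network, a compact reverse-mode
autodiff core it trains with, AdamW + cosine warm restarts, a synthetic
multimodal phantom generator (nested ellipsoidal tumors with
modality-specific contrast and BraTS-convention labels), NIfTI I/O, and the
evaluation statistics (95% CIs, paired t-tests). Who it is for: anyone who
wants to study, test or extend this architecture family — including its
ablation variants — without GPUs or challenge-dataset downloads.

## Worked example

Generate 25 phantoms (32³, four modalities), train the desk-scale model for
20 epochs on the first 20, and evaluate on the held-out 5:

```python
import numpy as np
from wiafnet import ModelConfig, TrainConfig, train, predict
from wiafnet import PhantomSpec, generate_phantom, brats_regions, dice_score, hd95

spec = PhantomSpec(grid=32)
seeds = np.random.SeedSequence(0).spawn(25)
cases = [generate_phantom(spec, int(s.generate_state(1)[0] % 2**31)) for s in seeds]

model, log = train(TrainConfig.desk(seed=0), ModelConfig.desk(), cases[:20])
print(f"epoch  0: loss {log[0]['loss']:.3f} (dice {log[0]['dice_loss']:.3f}, ce {log[0]['ce_loss']:.3f})")
print(f"epoch 19: loss {log[-1]['loss']:.3f} (dice {log[-1]['dice_loss']:.3f}, ce {log[-1]['ce_loss']:.3f})")

for i, (vol, lab) in enumerate(cases[20:]):
    pred = predict(model, vol)
    p, g = brats_regions(pred), brats_regions(lab)
    print(f"case {i}: WT dice {dice_score(p.WT, g.WT):.3f}  "
          f"TC dice {dice_score(p.TC, g.TC):.3f}  "
          f"WT hd95 {hd95(p.WT, g.WT):.2f} mm")
```

Output (about a minute on one CPU core):

```
epoch  0: loss 1.814 (dice 0.993, ce 0.821)
epoch 19: loss 0.607 (dice 0.582, ce 0.025)
case 0: WT dice 0.851  TC dice 0.359  WT hd95 1.00 mm
case 1: WT dice 0.862  TC dice 0.691  WT hd95 1.00 mm
case 2: WT dice 0.865  TC dice 0.693  WT hd95 1.00 mm
case 3: WT dice 0.830  TC dice 0.673  WT hd95 1.00 mm
case 4: WT dice 0.845  TC dice 0.739  WT hd95 1.00 mm
```

The combined loss falls from 1.81 to 0.61 over 20 epochs; the cross-entropy
term collapses first (voxelwise classification), the Dice term follows as
the tumor regions localize. On unseen phantoms the model delineates the
whole tumor at Dice ≈ 0.85 with sub-voxel-scale HD95; the small enhancing
core (a few dozen voxels at 32³) is the hard part, as expected with so
little training.

The same flow is available from the shell:

```bash
wiaf generate --n 25 --grid 32 --seed 0 --out cases/
wiaf train --data cases/ --preset desk --seed 0 --checkpoint model.npz
wiaf predict --checkpoint model.npz --case cases/case_0022 --out pred.nii.gz
wiaf evaluate --pred preds/ --gt cases/
wiaf summarize --preset full          # parameter / MAC budget report
```

## Architecture budgets

The repository commits a frozen reference configuration
(`src/wiafnet/reference_config.yaml`), calibrated once by
`wiaf calibrate-config` (`wiafnet/calibration.py`) so that the full model
matches the published budget figures: 5.23 M trainable parameters and
9.75 G MACs for a (4, 128³) forward pass, with the decoder at exactly
167,940 parameters and the conv-stem ablation variant at 5.19 M. The
analytic counting convention (what counts as a MAC) is documented in
`wiafnet/budgets.py` and cross-checked against the instantiated arrays in
the test suite. Ablation variants `B`, `B+MSFFD`, `B+MSFFD+IAFT` and `full`
are all constructible via `build_variant` and share one I/O contract.

## Limitations

The phantoms emulate geometry and contrast, not MRI physics; desk-scale
results demonstrate that the architecture and pipeline learn, not clinical
performance. Reproducing the published BraTS2020/FeTS2022 Dice scores
requires the challenge datasets and GPU-scale training, which are outside
this package's scope. See `docs/methods.md` for the full model description,
parameter choices, and design notes.
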