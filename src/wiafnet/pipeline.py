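"""Training, inference and evaluation pipelines.

Follows the published protocol: AdamW, initial learning rate 2e-4 decaying
to 1e-5 under cosine annealing with warm restarts every 20 epochs, batch
size 2, flips/rotations/noise augmentation, best-on-validation-Dice
checkpointing.  The committed *desk* preset scales this to CPU size
(32-cube phantoms, reduced widths, 20 epochs); the *full* preset keeps the
published values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import stats

from . import autodiff as ad
from . import budgets
from .autodiff import Tensor
from .config import ModelConfig
from .network import WIAF, count_params
from .nn import DTYPE, AdamW, cosine_warm_restart_lr
from .objectives_metrics import (LossWeights, brats_regions, dice_score,
                                 hd95)
from .synthetic_phantoms import MODALITIES, AugmentPolicy, augment
from .wavelet_frontend import MultiChannelVolume

__all__ = [
    "TrainConfig", "EvalReport", "PairedTestResult",
    "load_case", "train", "predict", "evaluate", "evaluate_dirs",
    "paired_ttest", "summarize_model",
    "save_checkpoint", "load_checkpoint", "training_loss",
]

#: internal class index <-> BraTS label value
LABEL_TO_CLASS = {0: 0, 1: 1, 2: 2, 4: 3}
CLASS_TO_LABEL = np.array([0, 1, 2, 4], dtype=np.int16)


@dataclass
class TrainConfig:
    initial_lr: float = 2e-4
    min_lr: float = 1e-5
    cycle_epochs: int = 20
    batch_size: int = 2
    epochs: int = 400
    weight_decay: float = 1e-2
    loss_weights: LossWeights = field(default_factory=LossWeights)
    augment: AugmentPolicy | None = field(default_factory=AugmentPolicy)
    seed: int = 0
    preset: str = "full"

    def __post_init__(self):
        if not (self.initial_lr >= self.min_lr > 0):
            raise ValueError("need initial_lr >= min_lr > 0")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch size and epochs must be >= 1")

    @classmethod
    def desk(cls, seed: int = 0) -> "TrainConfig":
        # the desk preset compresses the schedule into 20 epochs / ~200
        # steps, so it runs a proportionally higher learning rate
        return cls(initial_lr=3e-3, min_lr=1.5e-4, epochs=20, batch_size=2,
                   seed=seed, preset="desk")


# ---------------------------------------------------------------------------
# case I/O and preprocessing
# ---------------------------------------------------------------------------

def _crop_pad(arr: np.ndarray, target: tuple[int, int, int],
              pad_value=0.0) -> np.ndarray:
    """Symmetric center crop and/or pad of the trailing three axes."""
    out = arr
    for ax_off, t in enumerate(target):
        ax = out.ndim - 3 + ax_off
        s = out.shape[ax]
        if s > t:
            start = (s - t) // 2
            out = np.take(out, np.arange(start, start + t), axis=ax)
        elif s < t:
            before = (t - s) // 2
            pad = [(0, 0)] * out.ndim
            pad[ax] = (before, t - s - before)
            out = np.pad(out, pad, constant_values=pad_value)
    return out


def load_case(case_dir: str | Path, target_size: tuple[int, int, int] | None = None
              ) -> tuple[MultiChannelVolume, np.ndarray | None]:
    """Load a 4-modality case (T1, T1ce, T2, FLAIR) plus optional labels.

    Channels are stacked in the fixed modality order and z-scored over their
    nonzero voxels; an optional center crop/pad brings the volume to
    `target_size`.
    """
    case_dir = Path(case_dir)
    case_id = case_dir.name
    channels = []
    shape = None
    for mod in MODALITIES:
        path = case_dir / f"{case_id}_{mod}.nii.gz"
        if not path.exists():
            path = case_dir / f"{case_id}_{mod}.nii"
        if not path.exists():
            raise FileNotFoundError(f"missing modality file {path}")
        data = np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
        if shape is None:
            shape = data.shape
        elif data.shape != shape:
            raise ValueError(f"modality shapes differ in {case_dir}")
        nz = data != 0
        if nz.any():
            mu, sd = data[nz].mean(), data[nz].std()
            data = (data - mu) / (sd if sd > 0 else 1.0)
        channels.append(data)
    vol = np.stack(channels).astype(np.float32)

    labels = None
    for suffix in (".nii.gz", ".nii"):
        lp = case_dir / f"{case_id}_seg{suffix}"
        if lp.exists():
            labels = np.rint(np.asarray(nib.load(str(lp)).dataobj)).astype(np.int16)
            if labels.shape != shape:
                raise ValueError("label shape differs from modalities")
            break
    if target_size is not None:
        vol = _crop_pad(vol, target_size)
        if labels is not None:
            labels = _crop_pad(labels, target_size, pad_value=0)
    return MultiChannelVolume(vol), labels


def _one_hot(labels: np.ndarray, num_classes: int = 4) -> np.ndarray:
    idx = np.zeros(labels.shape, dtype=np.int64)
    for lab, cls in LABEL_TO_CLASS.items():
        idx[labels == lab] = cls
    eye = np.eye(num_classes, dtype=DTYPE)
    return np.moveaxis(eye[idx], -1, 0)          # (K, H, W, D)


# ---------------------------------------------------------------------------
# loss (autodiff path; mirrors objectives_metrics definitions)
# ---------------------------------------------------------------------------

def training_loss(logits: Tensor, onehot: np.ndarray,
                  weights: LossWeights | None = None
                  ) -> tuple[Tensor, float, float]:
    """Combined Dice + CE on (B, K, H, W, D) logits; returns loss and parts."""
    w = weights or LossWeights()
    probs = ad.softmax(logits, axis=1)
    y = Tensor(np.asarray(onehot, dtype=DTYPE))
    red = (0, 2, 3, 4)
    inter = ad.sum_(probs * y, axis=red)
    denom = ad.sum_(probs, axis=red) + ad.sum_(y, axis=red)
    dice_per_class = 1.0 - (2.0 * inter + w.eps) / (denom + w.eps)
    dice = ad.mean(dice_per_class[1:])
    ce = -ad.mean(ad.sum_(y * ad.log(probs + 1e-12), axis=1))
    loss = w.lambda1 * dice + w.lambda2 * ce
    return loss, float(dice.data), float(ce.data)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _val_mean_dice(model: WIAF, cases) -> float:
    scores = []
    for vol, lab in cases:
        pred = predict(model, vol)
        pr = brats_regions(pred)
        gt = brats_regions(lab)
        scores.extend(dice_score(pr.as_dict()[r], gt.as_dict()[r])
                      for r in ("ET", "TC", "WT"))
    return float(np.mean(scores))


def train(train_cfg: TrainConfig, model_cfg: ModelConfig, train_cases,
          val_cases=None, checkpoint_path: str | Path | None = None,
          log_path: str | Path | None = None) -> tuple[WIAF, list[dict]]:
    """Optimize a model on (volume, labelmap) pairs; returns (model, log).

    The checkpointed state is the best-on-validation mean Dice (or the final
    state when no validation cases are given).  Non-finite losses abort.
    """
    if not train_cases:
        raise ValueError("empty training set")
    rng = np.random.default_rng(train_cfg.seed)
    model = WIAF(model_cfg, seed=train_cfg.seed)
    opt = AdamW(model.parameters(), lr=train_cfg.initial_lr,
                weight_decay=train_cfg.weight_decay)
    cases = [(np.asarray(v.data if isinstance(v, MultiChannelVolume) else v,
                         dtype=DTYPE),
              _one_hot(l, model_cfg.num_classes), np.asarray(l))
             for v, l in train_cases]

    log: list[dict] = []
    best = {"dice": -1.0, "state": None, "epoch": -1}
    for epoch in range(train_cfg.epochs):
        lr = cosine_warm_restart_lr(epoch, train_cfg.initial_lr,
                                    train_cfg.min_lr, train_cfg.cycle_epochs)
        opt.lr = lr
        order = rng.permutation(len(cases))
        losses, dices, ces = [], [], []
        for start in range(0, len(order), train_cfg.batch_size):
            idx = order[start:start + train_cfg.batch_size]
            vols, hots = [], []
            for i in idx:
                v, h, lab = cases[i]
                if train_cfg.augment is not None:
                    v, lab_aug = augment(v, lab, train_cfg.augment, rng)
                    h = _one_hot(lab_aug, model_cfg.num_classes)
                vols.append(v)
                hots.append(h)
            xb = Tensor(np.stack(vols))
            yb = np.stack(hots)
            logits = model(xb)
            loss, dval, cval = training_loss(logits, yb,
                                             train_cfg.loss_weights)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"divergence at epoch {epoch}: loss={loss.data!r}, "
                    f"lr={lr:.2e}, dice_part={dval}, ce_part={cval}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            dices.append(dval)
            ces.append(cval)
        rec = {"epoch": epoch, "lr": lr, "loss": float(np.mean(losses)),
               "dice_loss": float(np.mean(dices)),
               "ce_loss": float(np.mean(ces)), "seed": train_cfg.seed}
        if val_cases:
            vd = _val_mean_dice(model, val_cases)
            rec["val_mean_dice"] = vd
            if vd > best["dice"]:
                best = {"dice": vd, "state": model.state_dict(),
                        "epoch": epoch}
        log.append(rec)

    if val_cases and best["state"] is not None:
        model.load_state_dict(best["state"])
    if checkpoint_path is not None:
        save_checkpoint(checkpoint_path, model)
    if log_path is not None:
        Path(log_path).write_text(
            "\n".join(json.dumps(r) for r in log) + "\n")
    return model, log


def save_checkpoint(path: str | Path, model: WIAF) -> None:
    state = {f"param/{k}": v for k, v in model.state_dict().items()}
    state["config_json"] = np.frombuffer(
        json.dumps(model.cfg.to_dict()).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path: str | Path) -> WIAF:
    with np.load(path) as z:
        cfg = ModelConfig.from_dict(
            json.loads(bytes(z["config_json"].tobytes()).decode()))
        state = {k[len("param/"):]: z[k] for k in z.files
                 if k.startswith("param/")}
    model = WIAF(cfg)
    model.load_state_dict(state)
    return model


# ---------------------------------------------------------------------------
# inference and evaluation
# ---------------------------------------------------------------------------

def predict(model: WIAF, volume) -> np.ndarray:
    """Voxelwise argmax segmentation mapped back to BraTS labels."""
    data = volume.data if isinstance(volume, MultiChannelVolume) else np.asarray(volume)
    logits = model(Tensor(data[None].astype(DTYPE)))
    cls = np.argmax(logits.data[0], axis=0)
    return CLASS_TO_LABEL[cls]


@dataclass
class EvalReport:
    per_case: pd.DataFrame
    summary: pd.DataFrame
    flags: list[str] = field(default_factory=list)


def _mean_ci(values: np.ndarray, level: float = 0.95):
    """Student-t confidence interval for the mean; degenerate for n = 1."""
    values = np.asarray(values, dtype=np.float64)
    m = float(values.mean())
    n = len(values)
    if n < 2 or np.allclose(values, values[0]):
        return m, m, m
    half = stats.t.ppf(0.5 + level / 2, n - 1) * values.std(ddof=1) / np.sqrt(n)
    return m, m - half, m + half


def evaluate(pred_labelmaps, gt_labelmaps, spacing=(1.0, 1.0, 1.0),
             case_ids=None) -> EvalReport:
    """Region Dice and HD95 per case, with 95% CIs on the means."""
    if len(pred_labelmaps) != len(gt_labelmaps):
        raise ValueError("unmatched case lists")
    if case_ids is None:
        case_ids = [f"case_{i:04d}" for i in range(len(pred_labelmaps))]
    flags = []
    rows = []
    diag = None
    for cid, pred, gt in zip(case_ids, pred_labelmaps, gt_labelmaps):
        pr = brats_regions(pred).as_dict()
        gr = brats_regions(gt).as_dict()
        row = {"case_id": cid}
        for region in ("ET", "TC", "WT"):
            row[f"dice_{region}"] = dice_score(pr[region], gr[region])
            h = hd95(pr[region], gr[region], spacing)
            diag = float(np.linalg.norm(np.asarray(gt.shape)
                                        * np.asarray(spacing)))
            if not pr[region].any() or not gr[region].any():
                if not (pr[region].any() or gr[region].any()):
                    h = 0.0   # both empty: perfect agreement
                else:
                    flags.append(f"{cid}:{region}: empty mask, HD95 set to "
                                 f"volume diagonal {diag:.2f}")
            row[f"hd95_{region}"] = h
        rows.append(row)
    per_case = pd.DataFrame(rows)

    summary_rows = []
    for metric in ("dice", "hd95"):
        for region in ("ET", "TC", "WT"):
            vals = per_case[f"{metric}_{region}"].to_numpy()
            m, lo, hi = _mean_ci(vals)
            summary_rows.append({"metric": metric, "region": region,
                                 "mean": m, "ci_lower": lo, "ci_upper": hi,
                                 "n": len(vals)})
    if len(per_case) == 1:
        flags.append("single case: confidence intervals degenerate to the "
                     "point estimate")
    return EvalReport(per_case, pd.DataFrame(summary_rows), flags)


def evaluate_dirs(pred_dir: str | Path, gt_dir: str | Path,
                  spacing=(1.0, 1.0, 1.0)) -> EvalReport:
    """Evaluate matched ``<case>.nii.gz`` predictions against ground truth."""
    pred_dir, gt_dir = Path(pred_dir), Path(gt_dir)
    preds = sorted(pred_dir.glob("*.nii.gz"))
    if not preds:
        raise FileNotFoundError(f"no predictions in {pred_dir}")
    ids, pl, gl = [], [], []
    for p in preds:
        cid = p.name.replace(".nii.gz", "")
        g = gt_dir / p.name
        if not g.exists():
            g = gt_dir / cid / f"{cid}_seg.nii.gz"
        if not g.exists():
            raise FileNotFoundError(f"no ground truth for {cid}")
        pl.append(np.rint(np.asarray(nib.load(str(p)).dataobj)).astype(np.int16))
        gl.append(np.rint(np.asarray(nib.load(str(g)).dataobj)).astype(np.int16))
        ids.append(cid)
    return evaluate(pl, gl, spacing, ids)


# ---------------------------------------------------------------------------
# statistics and model summary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedTestResult:
    t: float
    p: float
    n: int
    significant_05: bool
    significant_01: bool
    degenerate: bool = False


def paired_ttest(scores_a, scores_b) -> PairedTestResult:
    """Paired-sample t-test on per-case differences (scipy ttest_rel)."""
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("score vectors must be 1-D and of equal length")
    if len(a) < 2:
        raise ValueError("need at least two paired scores")
    if np.allclose(a, b):
        return PairedTestResult(0.0, 1.0, len(a), False, False,
                                degenerate=True)
    t, p = stats.ttest_rel(a, b)
    return PairedTestResult(float(t), float(p), len(a), p < 0.05, p < 0.01)


def summarize_model(model_cfg: ModelConfig,
                    input_shape=(4, 128, 128, 128)) -> dict:
    """Parameter and MAC budgets per component plus totals."""
    pb = budgets.params_breakdown(model_cfg)
    mb = budgets.macs_breakdown(model_cfg, input_shape)
    total_p = sum(pb.values())
    total_m = sum(mb.values())
    return {
        "variant": model_cfg.variant,
        "input_shape": list(input_shape),
        "params_by_component": pb,
        "macs_by_component": mb,
        "total_params": total_p,
        "total_params_M": round(total_p / 1e6, 2),
        "total_macs": total_m,
        "total_macs_G": round(total_m / 1e9, 2),
    }
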