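"""Reproducible multimodal 3D tumor phantoms with BraTS-convention labels.

Each phantom is a dark background containing a bright brain ellipsoid with a
nested tumor: an enhancing core (label 4), a necrotic/non-enhancing shell
(label 1) and an outer edema shell (label 2), so that the evaluation regions
nest as ET ⊂ TC ⊂ WT.  Four channels emulate the modality-specific contrast
of T1 / T1ce / T2 / FLAIR (edema brightest on FLAIR, the enhancing rim
brightest on T1ce), plus additive Gaussian noise.  Ellipsoid surfaces carry a
low-order angular perturbation so shapes are not trivially separable.

Everything is driven by a master seed; a dataset manifest records per-case
seeds and label statistics.  Phantoms are written as NIfTI files using the
BraTS naming convention (``<case>_t1.nii.gz`` … ``<case>_seg.nii.gz``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = ["PhantomSpec", "generate_phantom", "augment", "AugmentPolicy",
           "generate_dataset", "MODALITIES"]

MODALITIES = ("t1", "t1ce", "t2", "flair")

#: per-modality intensity of each tissue class (background, brain, ED, NCR/NET, ET)
DEFAULT_INTENSITIES = {
    "t1":    {"background": 0.0, "brain": 0.55, "ED": 0.40, "NCR": 0.25, "ET": 0.45},
    "t1ce":  {"background": 0.0, "brain": 0.50, "ED": 0.45, "NCR": 0.20, "ET": 0.95},
    "t2":    {"background": 0.0, "brain": 0.45, "ED": 0.80, "NCR": 0.70, "ET": 0.60},
    "flair": {"background": 0.0, "brain": 0.40, "ED": 0.95, "NCR": 0.60, "ET": 0.65},
}


@dataclass
class PhantomSpec:
    """Geometry, contrast and noise of one synthetic case family.

    Semi-axes are fractions of the grid size.  The whole-tumor semi-axes
    default to ~0.37x the brain's, which puts the whole-tumor volume near 5%
    of the brain volume; TC and ET shrink from there.
    """

    grid: int = 64
    brain_axes: tuple[float, float, float] = (0.42, 0.38, 0.35)
    wt_axes: tuple[float, float, float] = (0.155, 0.145, 0.130)
    tc_axes: tuple[float, float, float] = (0.105, 0.095, 0.085)
    et_axes: tuple[float, float, float] = (0.060, 0.055, 0.050)
    intensities: dict = field(default_factory=lambda: DEFAULT_INTENSITIES)
    noise_sd: float = 0.05
    surface_jitter: float = 0.08
    tumor_offset_frac: float = 0.35   # tumor center offset inside the brain
    seed: int = 0

    def __post_init__(self):
        for a, b in ((self.wt_axes, self.tc_axes), (self.tc_axes, self.et_axes)):
            if not all(x > y for x, y in zip(a, b)):
                raise ValueError("semi-axes must strictly decrease WT > TC > ET")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be nonnegative")
        if self.grid < 16 or self.grid % 2:
            raise ValueError("grid must be even and >= 16")


def _ellipsoid_mask(grid: int, center: np.ndarray, semi_axes: np.ndarray,
                    rng: np.random.Generator, jitter: float) -> np.ndarray:
    """Ellipsoid with a smooth low-order angular radius perturbation."""
    coords = np.stack(np.meshgrid(*[np.arange(grid)] * 3, indexing="ij"))
    rel = (coords - center[:, None, None, None]) / semi_axes[:, None, None, None]
    r = np.sqrt((rel ** 2).sum(axis=0))
    if jitter > 0:
        # low-order trigonometric modulation of the radius threshold
        phase = rng.uniform(0, 2 * np.pi, size=(3, 2))
        amp = rng.uniform(0.3, 1.0, size=(3, 2)) * jitter / 3.0
        u = rel / np.maximum(r, 1e-9)
        bump = np.zeros_like(r)
        for ax in range(3):
            bump += amp[ax, 0] * np.cos(2 * np.pi * u[ax] + phase[ax, 0])
            bump += amp[ax, 1] * np.cos(4 * np.pi * u[ax] + phase[ax, 1])
        thresh = 1.0 + bump
    else:
        thresh = 1.0
    return r <= thresh


def generate_phantom(spec: PhantomSpec, seed: int | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Render one case: a (4, g, g, g) float volume and a {0,1,2,4} labelmap."""
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    g = spec.grid
    center = np.full(3, g / 2.0) + rng.uniform(-0.02 * g, 0.02 * g, 3)
    brain_ax = np.asarray(spec.brain_axes) * g
    brain = _ellipsoid_mask(g, center, brain_ax, rng, spec.surface_jitter / 2)

    # tumor center offset from brain center, kept inside the brain
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    t_center = center + direction * spec.tumor_offset_frac * brain_ax
    wt = _ellipsoid_mask(g, t_center, np.asarray(spec.wt_axes) * g, rng,
                         spec.surface_jitter)
    tc = _ellipsoid_mask(g, t_center, np.asarray(spec.tc_axes) * g, rng,
                         spec.surface_jitter)
    et = _ellipsoid_mask(g, t_center, np.asarray(spec.et_axes) * g, rng,
                         spec.surface_jitter)
    # enforce nesting and containment in the brain
    wt &= brain
    tc &= wt
    et &= tc
    if not (et.any() and (tc & ~et).any() and (wt & ~tc).any()):
        raise ValueError("degenerate geometry: a tumor shell is empty")

    labels = np.zeros((g, g, g), dtype=np.int16)
    labels[wt] = 2            # edema shell
    labels[tc] = 1            # necrotic / non-enhancing core shell
    labels[et] = 4            # enhancing core

    vol = np.zeros((4, g, g, g), dtype=np.float32)
    for ci, mod in enumerate(MODALITIES):
        tab = spec.intensities[mod]
        ch = np.full((g, g, g), tab["background"], dtype=np.float32)
        ch[brain] = tab["brain"]
        ch[labels == 2] = tab["ED"]
        ch[labels == 1] = tab["NCR"]
        ch[labels == 4] = tab["ET"]
        ch += rng.normal(0.0, spec.noise_sd, ch.shape).astype(np.float32)
        vol[ci] = ch
    return vol, labels


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass
class AugmentPolicy:
    """Training-time augmentation: flips, small rotations, additive noise."""

    flip_prob: float = 0.3          # per axis
    rotate_prob: float = 0.5
    rotate_max_deg: float = 30.0
    noise_sd: float = 0.02


def augment(volume: np.ndarray, labels: np.ndarray,
            policy: AugmentPolicy | None = None,
            rng: np.random.Generator | None = None
            ) -> tuple[np.ndarray, np.ndarray]:
    """Apply flip -> rotate -> noise; labels track geometry, noise is image-only.

    The image is interpolated trilinearly, labels nearest-neighbor.
    """
    policy = policy or AugmentPolicy()
    rng = rng or np.random.default_rng(0)
    vol = np.asarray(volume).copy()
    lab = np.asarray(labels).copy()
    for ax in range(3):
        if rng.random() < policy.flip_prob:
            vol = np.flip(vol, axis=ax + 1)
            lab = np.flip(lab, axis=ax)
    if rng.random() < policy.rotate_prob:
        angle = rng.uniform(-policy.rotate_max_deg, policy.rotate_max_deg)
        plane = tuple(rng.choice(3, size=2, replace=False))
        vol = np.stack([
            ndimage.rotate(c, angle, axes=plane, reshape=False, order=1,
                           mode="constant", cval=0.0) for c in vol])
        lab = ndimage.rotate(lab, angle, axes=plane, reshape=False, order=0,
                             mode="constant", cval=0)
    if policy.noise_sd > 0:
        vol = vol + rng.normal(0.0, policy.noise_sd, vol.shape)
    return np.ascontiguousarray(vol, dtype=np.float32), \
        np.ascontiguousarray(lab)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def _write_nifti(path: Path, data: np.ndarray):
    nib.save(nib.Nifti1Image(np.asarray(data), affine=np.eye(4)), str(path))


def generate_dataset(n: int, spec: PhantomSpec, seed: int,
                     out_dir: str | Path, split=(8, 1, 1)) -> dict:
    """Write `n` phantom cases plus a JSON manifest; returns the manifest.

    Per-case seeds derive from the master seed; the optional train/val/test
    split assigns cases in `split` proportions, in case order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    case_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]

    total = sum(split)
    n_train = round(n * split[0] / total)
    n_val = round(n * split[1] / total)
    assignments = (["train"] * n_train + ["val"] * n_val
                   + ["test"] * (n - n_train - n_val))

    cases = []
    for i, (cseed, part) in enumerate(zip(case_seeds, assignments)):
        case_id = f"case_{i:04d}"
        vol, lab = generate_phantom(spec, seed=cseed)
        cdir = out_dir / case_id
        cdir.mkdir(exist_ok=True)
        for ci, mod in enumerate(MODALITIES):
            _write_nifti(cdir / f"{case_id}_{mod}.nii.gz", vol[ci])
        _write_nifti(cdir / f"{case_id}_seg.nii.gz", lab)
        counts = {str(v): int((lab == v).sum()) for v in (1, 2, 4)}
        cases.append({"case_id": case_id, "seed": cseed, "split": part,
                      "label_counts": counts})

    manifest = {"n": n, "master_seed": seed, "grid": spec.grid,
                "split": list(split), "cases": cases}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
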