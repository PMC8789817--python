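"""Synthetic data with known ground truth.

Two generators make the whole pipeline testable offline:

* a procedural *shape world*: small RGB images, each containing one shape
  (triangle, disc, square, cross, ring, diamond) drawn on a noisy background.
  Category identity is carried purely by shape geometry; position, size and
  color vary freely within a class, so nothing but the image covariance ties
  class members together. Every image has one class label and a unique
  instance id, but the self-supervised objective never sees the labels.

* *synthetic subjects*: condition x voxel response matrices in which every
  voxel is a nonnegative random mixture of a chosen layer's units plus
  independent Gaussian noise, emulating the voxel-as-weighted-combination-
  of-model-units assumption of the encoding analysis. The mixture weights
  are shared across subjects (so noise-free subjects have identical
  representational geometry) and are returned for recovery tests.

Neither generator attempts fMRI hemodynamics, spatial smoothness, or GLM
estimation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from matplotlib.colors import hsv_to_rgb
from PIL import Image

from .backbone import LayerActivations
from .errors import ConfigurationError, InputError
from .versa import SubjectVoxelData, noise_ceiling

SHAPE_NAMES = ("triangle", "disc", "square", "cross", "ring", "diamond")


@dataclass
class JitterSpec:
    """Within-class variation: fractional ranges for position, scale, hue.

    Defaults give shapes that fill a substantial part of the frame (radius
    30-45% of the image) with moderate position jitter and a free hue, so
    category identity is carried by geometry while low-level image statistics
    vary richly across instances.
    """

    position: float = 0.12  # max center offset, fraction of image size
    scale: tuple[float, float] = (0.30, 0.45)  # shape radius / image size
    hue: float = 1.0  # 1.0 = any hue; 0 = one fixed hue for all images

    @classmethod
    def none(cls) -> "JitterSpec":
        mid = (0.30 + 0.45) / 2
        return cls(position=0.0, scale=(mid, mid), hue=0.0)


@dataclass
class ShapeWorldSpec:
    n_classes: int = 4
    n_instances_per_class: int = 100
    image_size: int = 32
    background_noise_sd: float = 0.08  # intensity units on [0, 1]
    within_class_jitter: JitterSpec = field(default_factory=JitterSpec)
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.within_class_jitter, (int, float)):
            if self.within_class_jitter == 0:
                self.within_class_jitter = JitterSpec.none()
            else:
                raise ConfigurationError(
                    "within_class_jitter must be a JitterSpec or 0"
                )
        if self.n_classes < 2:
            raise ConfigurationError("n_classes must be >= 2")
        if self.n_classes > len(SHAPE_NAMES):
            raise ConfigurationError(
                f"at most {len(SHAPE_NAMES)} shape classes are available"
            )
        if self.image_size < 32:
            raise ConfigurationError("image_size must be >= 32")
        if self.n_instances_per_class < 1:
            raise ConfigurationError("n_instances_per_class must be >= 1")
        if self.background_noise_sd < 0:
            raise ConfigurationError("background_noise_sd must be nonnegative")


@dataclass
class LabeledImageSet:
    images: np.ndarray  # (N, H, W, 3) uint8
    class_labels: np.ndarray  # (N,) int
    instance_ids: np.ndarray  # (N,) int, unique
    class_names: list[str]

    def __post_init__(self):
        if len(np.unique(self.instance_ids)) != len(self.instance_ids):
            raise InputError("instance_ids must be unique")

    @property
    def n_images(self) -> int:
        return self.images.shape[0]


def _shape_mask(shape: str, size: int, cx: float, cy: float, r: float) -> np.ndarray:
    """Boolean mask of one shape on a size x size grid (coords in [0, 1])."""
    y, x = np.mgrid[0:size, 0:size] / (size - 1)
    dx, dy = x - cx, y - cy
    if shape == "disc":
        return dx**2 + dy**2 <= r**2
    if shape == "square":
        return np.maximum(np.abs(dx), np.abs(dy)) <= r * 0.82
    if shape == "diamond":
        return np.abs(dx) + np.abs(dy) <= r * 1.05
    if shape == "cross":
        arm = 0.34 * r
        return ((np.abs(dx) <= arm) & (np.abs(dy) <= r)) | (
            (np.abs(dy) <= arm) & (np.abs(dx) <= r)
        )
    if shape == "ring":
        d2 = dx**2 + dy**2
        return (d2 <= r**2) & (d2 >= (0.55 * r) ** 2)
    if shape == "triangle":
        dyn = dy / r  # apex up: narrow at top, wide at base
        return (dyn >= -1) & (dyn <= 1) & (np.abs(dx) <= r * 0.95 * (dyn + 1) / 2)
    raise ConfigurationError(f"unknown shape '{shape}'")


def generate_shape_world(spec: ShapeWorldSpec) -> LabeledImageSet:
    """Deterministic (per seed) procedural image set with one shape per image."""
    rng = np.random.default_rng(spec.seed)
    jit = spec.within_class_jitter
    n = spec.n_classes * spec.n_instances_per_class
    size = spec.image_size
    images = np.empty((n, size, size, 3), dtype=np.uint8)
    labels = np.repeat(np.arange(spec.n_classes), spec.n_instances_per_class)
    idx = 0
    for cls in range(spec.n_classes):
        shape = SHAPE_NAMES[cls]
        for _ in range(spec.n_instances_per_class):
            r = rng.uniform(*jit.scale)
            max_off = jit.position
            cx = 0.5 + rng.uniform(-max_off, max_off)
            cy = 0.5 + rng.uniform(-max_off, max_off)
            # keep the shape inside the frame
            cx = float(np.clip(cx, r + 0.02, 0.98 - r))
            cy = float(np.clip(cy, r + 0.02, 0.98 - r))
            hue = (0.6 + rng.uniform(-jit.hue / 2, jit.hue / 2)) % 1.0
            color = hsv_to_rgb([hue, 0.85, 0.9])
            bg = 0.5 + spec.background_noise_sd * rng.standard_normal((size, size, 1))
            img = np.clip(np.repeat(bg, 3, axis=2), 0.0, 1.0)
            mask = _shape_mask(shape, size, cx, cy, r)
            img[mask] = color
            images[idx] = np.round(img * 255).astype(np.uint8)
            idx += 1
    return LabeledImageSet(
        images=images,
        class_labels=labels,
        instance_ids=np.arange(n),
        class_names=list(SHAPE_NAMES[: spec.n_classes]),
    )


def write_image_folder(dataset: LabeledImageSet, path) -> None:
    """Class-per-subdirectory PNG folders (instance id as file name)."""
    root = Path(path)
    for i in range(dataset.n_images):
        cls_dir = root / dataset.class_names[dataset.class_labels[i]]
        cls_dir.mkdir(parents=True, exist_ok=True)
        Image.fromarray(dataset.images[i]).save(
            cls_dir / f"{dataset.instance_ids[i]:06d}.png"
        )


def load_image_folder(path) -> LabeledImageSet:
    root = Path(path)
    class_names = sorted(p.name for p in root.iterdir() if p.is_dir())
    if not class_names:
        raise InputError(f"no class subdirectories under {root}")
    images, labels, ids = [], [], []
    for ci, name in enumerate(class_names):
        for f in sorted((root / name).glob("*.png")):
            images.append(np.asarray(Image.open(f).convert("RGB")))
            labels.append(ci)
            ids.append(int(f.stem) if f.stem.isdigit() else len(ids))
    return LabeledImageSet(
        images=np.stack(images),
        class_labels=np.asarray(labels),
        instance_ids=np.asarray(ids),
        class_names=class_names,
    )


# ---------------------------------------------------------------------------
# synthetic subjects


@dataclass
class SyntheticSubjectSpec:
    generating_features: LayerActivations | np.ndarray = None
    n_subjects: int = 8
    n_voxels_per_subject: int = 60
    weight_distribution: str = "half_normal"
    noise_sd: float = 1.0  # response units; signal per voxel has sd ~ 1
    seed: int = 0
    # optional separate seed for the mixture weights: replicate worlds that
    # share one planted voxel model but draw fresh subject noise
    weight_seed: int | None = None

    def __post_init__(self):
        if self.generating_features is None:
            raise ConfigurationError("generating_features is required")
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be >= 2")
        if self.n_voxels_per_subject < 1:
            raise ConfigurationError("n_voxels_per_subject must be >= 1")
        if self.weight_distribution != "half_normal":
            raise ConfigurationError("only 'half_normal' weights are supported")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")


@dataclass
class SyntheticSubjectsResult:
    subjects: list[SubjectVoxelData]
    weights: np.ndarray  # (n_units, n_voxels) ground-truth mixture weights
    condition_ids: list[str]
    planted_rdm: "RDM" = None  # geometry of the (preprocessed) generating features


def generate_synthetic_subjects(spec: SyntheticSubjectSpec) -> SyntheticSubjectsResult:
    """Voxels = shared nonnegative mixtures of layer units + per-subject noise.

    The generating features are standardized per unit (across conditions)
    and the half-normal weights are scaled by 1/sqrt(n_units), so each
    voxel's noise-free signal has standard deviation of order 1 and
    ``noise_sd`` is directly comparable to the signal scale. Rows are then
    centered across units: this leaves the generating layer's RDM unchanged
    (Pearson is invariant to per-row shifts) but makes the voxel-mixture
    geometry converge to exactly that RDM as the number of voxels grows, so
    the planted geometry is the generating layer's geometry.
    """
    feats = spec.generating_features
    x = feats.matrix if isinstance(feats, LayerActivations) else np.asarray(feats)
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise InputError("generating_features must have at least 3 conditions")
    n_cond, n_units = x.shape
    sd = x.std(axis=0)
    mu = x.mean(axis=0)
    xs = (x - mu) / np.where(sd < 1e-12, 1.0, sd)
    xs = xs - xs.mean(axis=1, keepdims=True)

    rng = np.random.default_rng(spec.seed)
    w_rng = rng if spec.weight_seed is None else np.random.default_rng(spec.weight_seed)
    w = np.abs(w_rng.standard_normal((n_units, spec.n_voxels_per_subject)))
    w /= np.sqrt(n_units)
    signal = xs @ w
    condition_ids = [f"cond_{i:03d}" for i in range(n_cond)]
    subjects = []
    for s in range(spec.n_subjects):
        noise = spec.noise_sd * rng.standard_normal(signal.shape)
        subjects.append(
            SubjectVoxelData(
                subject_id=f"sub-{s + 1:02d}",
                responses=signal + noise,
                condition_ids=list(condition_ids),
            )
        )
    from .rsa import compute_rdm

    return SyntheticSubjectsResult(
        subjects=subjects,
        weights=w,
        condition_ids=condition_ids,
        planted_rdm=compute_rdm(xs, condition_ids=condition_ids),
    )


def calibrate_noise_sd(
    base_spec: SyntheticSubjectSpec,
    target_r: float,
    grid=(0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0),
    n_reps: int = 8,
    seed: int = 0,
) -> float:
    """Pick the noise_sd whose expected split-half ceiling is nearest target_r.

    Monte-Carlo: for each candidate noise level, simulate ``n_reps`` subject
    sets and average the split-half noise ceiling; linearly interpolate r
    against log noise_sd between the bracketing grid points.
    """
    from dataclasses import replace

    if not 0 < target_r < 1:
        raise InputError("target_r must be in (0, 1)")
    rng = np.random.default_rng(seed)
    levels = np.asarray(sorted(grid), dtype=float)
    mean_r = np.empty(levels.size)
    for i, sdv in enumerate(levels):
        rs = []
        for _ in range(n_reps):
            spec = replace(base_spec, noise_sd=float(sdv),
                           seed=int(rng.integers(0, 2**31 - 1)))
            res = generate_synthetic_subjects(spec)
            rs.append(noise_ceiling(res.subjects).mean_r)
        mean_r[i] = np.mean(rs)
    # mean_r decreases with noise; find bracketing pair around target
    if target_r >= mean_r[0]:
        return float(levels[0])
    if target_r <= mean_r[-1]:
        return float(levels[-1])
    hi = int(np.argmax(mean_r < target_r))  # first level below target
    lo = hi - 1
    f = (mean_r[lo] - target_r) / (mean_r[lo] - mean_r[hi])
    return float(np.exp((1 - f) * np.log(levels[lo]) + f * np.log(levels[hi])))


def save_synthetic_subjects(path, result: SyntheticSubjectsResult) -> None:
    """One TSV per subject plus a sidecar ground-truth weights TSV."""
    import pandas as pd

    from .versa import save_subject

    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    for s in result.subjects:
        save_subject(root / f"{s.subject_id}.tsv", s)
    pd.DataFrame(
        result.weights,
        columns=[f"voxel_{i}" for i in range(result.weights.shape[1])],
    ).to_csv(root / "ground_truth_weights.tsv", sep="\t",
             float_format="%.12g", index_label="unit")


def load_synthetic_subjects(path) -> list[SubjectVoxelData]:
    from .versa import load_subject

    root = Path(path)
    files = sorted(root.glob("sub-*.tsv"))
    if not files:
        raise InputError(f"no subject TSVs under {root}")
    return [load_subject(f) for f in files]
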