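"""Stochastic multi-view augmentation.

Each training image is sampled several times (default five) with random
crop/rescale, optional horizontal flip, random grayscale, and random
brightness/contrast/saturation/hue jitter, then resized and channel-
normalized. The shared content across views is what the instance-level
objective must learn to preserve. Rotation is deliberately not part of the
default scheme (orientation is never jittered across samples); an optional
flag exists for ablations.

Pixel values are clamped to the valid range after jitter; normalization is
applied last.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.colors import hsv_to_rgb, rgb_to_hsv
from PIL import Image

from .errors import ConfigurationError, InputError

# ImageNet channel statistics, the conventional default for natural images.
IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_SD = (0.229, 0.224, 0.225)


@dataclass
class AugmentConfig:
    n_views: int = 5
    crop_scale_range: tuple[float, float] = (0.2, 1.0)
    crop_ratio_range: tuple[float, float] = (3.0 / 4.0, 4.0 / 3.0)
    allow_horizontal_flip: bool = True
    grayscale_probability: float = 0.2
    # brightness, contrast, saturation as max fractional change; hue as max
    # shift in fractions of the full hue circle.
    jitter_strengths: tuple[float, float, float, float] = (0.4, 0.4, 0.4, 0.4)
    allow_rotation: bool = False
    rotation_max_degrees: float = 0.0
    output_size: int = 224
    normalization_mean: tuple[float, float, float] = IMAGENET_MEAN
    normalization_sd: tuple[float, float, float] = IMAGENET_SD

    def __post_init__(self):
        if self.n_views < 1:
            raise ConfigurationError("n_views must be >= 1")
        lo, hi = self.crop_scale_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ConfigurationError("crop_scale_range must be within (0, 1]")
        if not 0.0 <= self.grayscale_probability <= 1.0:
            raise ConfigurationError("grayscale_probability must be in [0, 1]")
        if any(s < 0 for s in self.jitter_strengths):
            raise ConfigurationError("jitter strengths must be nonnegative")
        if self.output_size < 1:
            raise ConfigurationError("output_size must be positive")


def identity_config(output_size: int, **kwargs) -> AugmentConfig:
    """An AugmentConfig with every stochastic transform collapsed to identity."""
    return AugmentConfig(
        crop_scale_range=(1.0, 1.0),
        crop_ratio_range=(1.0, 1.0),
        allow_horizontal_flip=False,
        grayscale_probability=0.0,
        jitter_strengths=(0.0, 0.0, 0.0, 0.0),
        output_size=output_size,
        **kwargs,
    )


def _random_resized_crop(img: Image.Image, config: AugmentConfig, rng: np.random.Generator):
    w, h = img.size
    area = w * h
    lo, hi = config.crop_scale_range
    rlo, rhi = config.crop_ratio_range
    for _ in range(10):
        target = rng.uniform(lo, hi) * area
        ratio = np.exp(rng.uniform(np.log(rlo), np.log(rhi)))
        cw = int(round(np.sqrt(target * ratio)))
        ch = int(round(np.sqrt(target / ratio)))
        if 0 < cw <= w and 0 < ch <= h:
            left = int(rng.integers(0, w - cw + 1))
            top = int(rng.integers(0, h - ch + 1))
            return img.crop((left, top, left + cw, top + ch))
    # fallback: central square crop
    side = min(w, h)
    left, top = (w - side) // 2, (h - side) // 2
    return img.crop((left, top, left + side, top + side))


def _color_jitter(x: np.ndarray, strengths, rng: np.random.Generator) -> np.ndarray:
    """Brightness/contrast/saturation/hue jitter on float [0, 1] HxWx3."""
    b, c, s, hmax = strengths
    if b > 0:
        x = x * rng.uniform(max(0.0, 1 - b), 1 + b)
    if c > 0:
        gray_mean = x.mean(axis=2).mean()
        x = gray_mean + (x - gray_mean) * rng.uniform(max(0.0, 1 - c), 1 + c)
    if s > 0:
        gray = x.mean(axis=2, keepdims=True)
        x = gray + (x - gray) * rng.uniform(max(0.0, 1 - s), 1 + s)
    x = np.clip(x, 0.0, 1.0)
    if hmax > 0:
        shift = rng.uniform(-hmax, hmax)
        hsv = rgb_to_hsv(x)
        hsv[..., 0] = (hsv[..., 0] + shift) % 1.0
        x = hsv_to_rgb(hsv)
    return np.clip(x, 0.0, 1.0)


def sample_views(image, config: AugmentConfig, rng: np.random.Generator) -> np.ndarray:
    """Sample ``config.n_views`` augmented views of one image.

    ``image``: HxWx3 uint8 array or PIL image. Returns float32
    ``(n_views, 3, S, S)``, channel-normalized. Reproducible given ``rng``.
    """
    if isinstance(image, np.ndarray):
        if image.size == 0:
            raise InputError("degenerate image with zero area")
        img = Image.fromarray(np.asarray(image, dtype=np.uint8))
    else:
        img = image
    if img.size[0] == 0 or img.size[1] == 0:
        raise InputError("degenerate image with zero area")
    img = img.convert("RGB")

    mean = np.asarray(config.normalization_mean, dtype=np.float32)
    sd = np.asarray(config.normalization_sd, dtype=np.float32)
    views = np.empty((config.n_views, 3, config.output_size, config.output_size),
                     dtype=np.float32)
    for v in range(config.n_views):
        crop = _random_resized_crop(img, config, rng)
        crop = crop.resize((config.output_size, config.output_size), Image.BILINEAR)
        if config.allow_horizontal_flip and rng.random() < 0.5:
            crop = crop.transpose(Image.FLIP_LEFT_RIGHT)
        if config.allow_rotation and config.rotation_max_degrees > 0:
            deg = rng.uniform(-config.rotation_max_degrees, config.rotation_max_degrees)
            crop = crop.rotate(deg, resample=Image.BILINEAR)
        x = np.asarray(crop, dtype=np.float32) / 255.0
        if any(s > 0 for s in config.jitter_strengths):
            x = _color_jitter(x, config.jitter_strengths, rng)
        if config.grayscale_probability > 0 and rng.random() < config.grayscale_probability:
            x = np.repeat(x.mean(axis=2, keepdims=True), 3, axis=2)
        x = (x - mean) / sd
        views[v] = x.transpose(2, 0, 1)
    return views


def resize_normalize(images: np.ndarray, config: AugmentConfig) -> np.ndarray:
    """Deterministic eval-time transform: resize + normalize only."""
    out = np.empty((images.shape[0], 3, config.output_size, config.output_size),
                   dtype=np.float32)
    mean = np.asarray(config.normalization_mean, dtype=np.float32)
    sd = np.asarray(config.normalization_sd, dtype=np.float32)
    for i, im in enumerate(images):
        img = Image.fromarray(np.asarray(im, dtype=np.uint8)).convert("RGB")
        img = img.resize((config.output_size, config.output_size), Image.BILINEAR)
        x = np.asarray(img, dtype=np.float32) / 255.0
        out[i] = ((x - mean) / sd).transpose(2, 0, 1)
    return out
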