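"""Convolutional encoders with group normalization and an L2-normed head.

Two architectures share one contract (named blocks ``conv*``, ``fc6``,
``fc7``, plus either an ``embedding`` head projected to the unit hypersphere
or a ``classifier`` head for the category-supervised comparand):

``alexnet_gn``
    AlexNet with group normalization after every conv and fully connected
    layer, 224x224 input, 128-d embedding by default.
``tiny_gn``
    A three-conv-block / two-fc desk-scale encoder for 32x32 inputs with the
    same naming and extraction contract, small enough to train on a CPU.

Activation extraction flattens convolutional maps channel-major then spatial
row-major, so a ``C x H x W`` map becomes a length ``C*H*W`` unit vector per
image. Downstream encoding/RSA analyses are permutation-invariant over units;
the order is pinned only so caches are reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InputError
from .nn import (
    SGD,  # noqa: F401  (re-exported for training code)
    BatchCenter,
    Conv2d,
    Flatten,
    GroupNorm,
    L2Normalize,
    Linear,
    MaxPool2d,
    Network,
    ReLU,
)

VALID_ARCHITECTURES = ("alexnet_gn", "tiny_gn")


@dataclass
class BackboneConfig:
    architecture: str = "alexnet_gn"
    norm_groups: int = 32
    embedding_dim: int = 128
    l2_norm_output: bool = True
    classifier_classes: int | None = None
    # center the pre-normalization embedding across the batch (running mean
    # at eval). Defaults on for tiny_gn, where it keeps small-scale
    # contrastive training away from its collapsed optimum; off for
    # alexnet_gn, whose head is kept plain.
    embed_batch_center: bool | None = None

    def __post_init__(self):
        if self.architecture not in VALID_ARCHITECTURES:
            raise ConfigurationError(
                f"unknown architecture '{self.architecture}'; valid: {VALID_ARCHITECTURES}"
            )
        if self.embed_batch_center is None:
            self.embed_batch_center = self.architecture == "tiny_gn"
        if self.embedding_dim < 2:
            raise ConfigurationError("embedding_dim must be >= 2")
        if self.norm_groups < 1:
            raise ConfigurationError("norm_groups must be >= 1")


@dataclass
class LayerActivations:
    """Flattened per-layer feature matrix: one row per image/condition."""

    layer_name: str
    matrix: np.ndarray  # (n_conditions, n_units)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2:
            raise InputError("LayerActivations.matrix must be 2-D (conditions x units)")

    @property
    def unit_count(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_conditions(self) -> int:
        return self.matrix.shape[0]


def input_size_for(architecture: str) -> int:
    return {"alexnet_gn": 224, "tiny_gn": 32}[architecture]


def _head(config: BackboneConfig, in_features: int, rng) -> tuple[str, list]:
    if config.classifier_classes is not None:
        if config.classifier_classes < 2:
            raise ConfigurationError("classifier_classes must be >= 2")
        return ("classifier", [Linear(in_features, config.classifier_classes, rng=rng)])
    layers = [Linear(in_features, config.embedding_dim, rng=rng)]
    if config.embed_batch_center:
        layers.append(BatchCenter(config.embedding_dim))
    if config.l2_norm_output:
        layers.append(L2Normalize())
    return ("embedding", layers)


def build_backbone(config: BackboneConfig, seed: int = 0) -> Network:
    """Construct the encoder; weight initialization is seeded and explicit.

    Raises ConfigurationError when ``norm_groups`` does not divide a
    normalized layer's channel count.
    """
    rng = np.random.default_rng(seed)
    g = config.norm_groups
    if config.architecture == "alexnet_gn":
        blocks = [
            ("conv1", [Conv2d(3, 96, 11, 4, 2, rng=rng), GroupNorm(g, 96), ReLU(),
                       MaxPool2d(3, 2)]),
            ("conv2", [Conv2d(96, 256, 5, 1, 2, rng=rng), GroupNorm(g, 256), ReLU(),
                       MaxPool2d(3, 2)]),
            ("conv3", [Conv2d(256, 384, 3, 1, 1, rng=rng), GroupNorm(g, 384), ReLU()]),
            ("conv4", [Conv2d(384, 384, 3, 1, 1, rng=rng), GroupNorm(g, 384), ReLU()]),
            ("conv5", [Conv2d(384, 256, 3, 1, 1, rng=rng), GroupNorm(g, 256), ReLU(),
                       MaxPool2d(3, 2)]),
            ("fc6", [Flatten(), Linear(256 * 6 * 6, 4096, rng=rng), GroupNorm(g, 4096),
                     ReLU()]),
            ("fc7", [Linear(4096, 4096, rng=rng), GroupNorm(g, 4096), ReLU()]),
            _head(config, 4096, rng),
        ]
    else:  # tiny_gn
        blocks = [
            ("conv1", [Conv2d(3, 16, 3, 1, 1, rng=rng), GroupNorm(g, 16), ReLU(),
                       MaxPool2d(2)]),
            ("conv2", [Conv2d(16, 32, 3, 1, 1, rng=rng), GroupNorm(g, 32), ReLU(),
                       MaxPool2d(2)]),
            ("conv3", [Conv2d(32, 64, 3, 1, 1, rng=rng), GroupNorm(g, 64), ReLU(),
                       MaxPool2d(2)]),
            ("fc6", [Flatten(), Linear(64 * 4 * 4, 128, rng=rng), GroupNorm(g, 128),
                     ReLU()]),
            ("fc7", [Linear(128, 128, rng=rng), GroupNorm(g, 128), ReLU()]),
            _head(config, 128, rng),
        ]
    return Network(blocks, architecture=config.architecture)


def forward_embed(model: Network, views: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """Embed a batch of image views; rows are unit vectors.

    ``views``: (N, 3, S, S) float32. Requires the model to have been built
    with an L2-normed embedding head.
    """
    if model.layer_names[-1] != "embedding":
        raise ConfigurationError("model has no embedding head (built with classifier_classes?)")
    views = np.asarray(views, dtype=np.float32)
    if views.ndim != 4:
        raise InputError("views must be (N, C, H, W)")
    outs = []
    for start in range(0, views.shape[0], batch_size):
        out, _ = model.forward(views[start : start + batch_size])
        outs.append(out)
    return np.concatenate(outs, axis=0)


def extract_activations(
    model: Network,
    images: np.ndarray,
    layer_names: list[str],
    batch_size: int = 64,
) -> list[LayerActivations]:
    """Flattened activations for each requested block, rows in image order."""
    unknown = set(layer_names) - set(model.layer_names)
    if unknown:
        raise ConfigurationError(
            f"unknown layer name(s) {sorted(unknown)}; valid: {model.layer_names}"
        )
    images = np.asarray(images, dtype=np.float32)
    chunks: dict[str, list[np.ndarray]] = {name: [] for name in layer_names}
    for start in range(0, images.shape[0], batch_size):
        _, caps = model.forward(images[start : start + batch_size], capture=tuple(layer_names))
        for name in layer_names:
            a = caps[name]
            chunks[name].append(a.reshape(a.shape[0], -1).copy())
    return [
        LayerActivations(layer_name=name, matrix=np.concatenate(chunks[name], axis=0))
        for name in layer_names
    ]


def load_backbone(path, config: BackboneConfig) -> Network:
    """Rebuild a backbone from a saved ``.npz`` checkpoint."""
    model = build_backbone(config)
    with np.load(path, allow_pickle=False) as data:
        arch = str(data["architecture"])
        if arch != config.architecture:
            raise ConfigurationError(
                f"checkpoint architecture '{arch}' != config '{config.architecture}'"
            )
        state = {k: data[k] for k in data.files if k != "architecture"}
    model.load_state_dict(state)
    return model
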