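"""Run configuration: one structured text file drives a full pipeline run."""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .augment import AugmentConfig
from .backbone import BackboneConfig
from .errors import ConfigurationError
from .fixtures import JitterSpec, ShapeWorldSpec
from .ipcl import IPCLConfig
from .readout import ReadoutConfig


@dataclass
class VersaConfig:
    n_conditions: int = 40
    n_subjects: int = 6
    n_voxels_per_subject: int = 50
    noise_sd: float = 0.5
    planted_layer: str = "fc7"
    lambda_grid: tuple = tuple(float(x) for x in
                               (1e-3, 1e-2, 1e-1, 1, 10, 100, 1e3, 1e4, 1e5))
    max_splits: int = 126
    # seeded unit subsampling before encoding; keeping units below the
    # condition count makes the planted layer identifiable by the
    # leave-one-out ridge (with units >> conditions every wide layer
    # interpolates equally well)
    max_units: int | None = 24


@dataclass
class StatsConfig:
    alpha: float = 0.05
    n_family_tests: int = 30


def shape_world_augment() -> AugmentConfig:
    """Augmentation scheme scaled to the 32-px shape world: the same family
    of transforms as the natural-image scheme but with less extreme cropping
    and milder color jitter, so that views of one image reliably share
    content."""
    return AugmentConfig(
        output_size=32,
        crop_scale_range=(0.6, 1.0),
        jitter_strengths=(0.2, 0.2, 0.2, 0.05),
        grayscale_probability=0.1,
    )


def shape_world_training() -> IPCLConfig:
    """Training variation used for the desk-scale shape-world studies.

    Relative to the large-scale defaults: a queue smaller than the dataset,
    a softer temperature, a gentler optimizer, constant learning rate after
    warmup, and within-batch prototype negatives — the combination that
    keeps the tiny encoder out of the collapsed optimum (see the methods
    note)."""
    return IPCLConfig(
        temperature=0.15,
        queue_capacity=256,
        epochs=25,
        lr=0.01,
        momentum=0.5,
        cosine_decay=False,
        batch_negatives=True,
    )


@dataclass
class RunConfig:
    seed: int = 0
    fixtures: ShapeWorldSpec = field(default_factory=lambda: ShapeWorldSpec(
        n_classes=4, n_instances_per_class=50))
    augment: AugmentConfig = field(default_factory=shape_world_augment)
    backbone: BackboneConfig = field(default_factory=lambda: BackboneConfig(
        architecture="tiny_gn", norm_groups=4, embedding_dim=128))
    ipcl: IPCLConfig = field(default_factory=shape_world_training)
    readout: ReadoutConfig = field(default_factory=ReadoutConfig)
    versa: VersaConfig = field(default_factory=VersaConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)


# config fields that are themselves dataclasses (field names are unique
# across the nesting)
_NESTED = {
    "fixtures": ShapeWorldSpec,
    "augment": AugmentConfig,
    "backbone": BackboneConfig,
    "ipcl": IPCLConfig,
    "readout": ReadoutConfig,
    "versa": VersaConfig,
    "stats": StatsConfig,
    "within_class_jitter": JitterSpec,
}


def _from_dict(dc_cls, d: dict):
    if d is None:
        d = {}
    names = {f.name for f in dataclasses.fields(dc_cls)}
    unknown = set(d) - names
    if unknown:
        raise ConfigurationError(
            f"unknown config keys for {dc_cls.__name__}: {sorted(unknown)}"
        )
    kwargs = {}
    for key, value in d.items():
        if key in _NESTED and isinstance(value, dict):
            kwargs[key] = _from_dict(_NESTED[key], value)
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return dc_cls(**kwargs)


def load_run_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return _from_dict(RunConfig, data)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "tolist"):
        return obj.tolist()
    return obj


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(_jsonable(config), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def config_to_dict(config: RunConfig) -> dict:
    return _jsonable(config)
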