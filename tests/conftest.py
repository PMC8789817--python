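"""Shared fixtures. The expensive end-to-end training run is session-scoped
so the self-supervised model is trained once and reused by every test that
needs it."""
from __future__ import annotations

from dataclasses import replace
from types import SimpleNamespace

import numpy as np
import pytest

import ipclbrain as ib
from ipclbrain.augment import resize_normalize
from ipclbrain.config import shape_world_augment, shape_world_training

# study conditions for the desk-scale emergent-category run: 4 shape classes
# x 100 instances, tiny group-norm encoder, 25 epochs
TRAIN_SEED = 3
DATA_SEED = 7
N_CLASSES = 4
N_INSTANCES = 100


@pytest.fixture(scope="session")
def shape_world():
    return ib.generate_shape_world(
        ib.ShapeWorldSpec(n_classes=N_CLASSES, n_instances_per_class=N_INSTANCES,
                          seed=DATA_SEED)
    )


@pytest.fixture(scope="session")
def backbone_config():
    return ib.BackboneConfig(architecture="tiny_gn", norm_groups=4)


@pytest.fixture(scope="session")
def augment_config():
    return shape_world_augment()


@pytest.fixture(scope="session")
def trained_run(shape_world, backbone_config, augment_config):
    """IPCL-train the tiny encoder once; also build the untrained control."""
    ipcl_config = replace(shape_world_training(), seed=TRAIN_SEED)
    model, history = ib.train_ipcl(shape_world, backbone_config, ipcl_config,
                                   augment_config)
    untrained = ib.build_backbone(backbone_config, seed=11)
    eval_images = resize_normalize(shape_world.images, augment_config)
    return SimpleNamespace(
        dataset=shape_world,
        model=model,
        untrained=untrained,
        history=history,
        eval_images=eval_images,
        ipcl_config=ipcl_config,
        backbone_config=backbone_config,
        augment_config=augment_config,
    )


def knn_top1(model, images, labels, k=200) -> float:
    feats = ib.extract_activations(model, images, ["embedding"])[0]
    bank = ib.MemoryBank.from_features(feats, labels)
    return ib.knn_accuracy(bank.embeddings, labels, bank,
                           ib.ReadoutConfig(k=k), exclude_self=True)
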