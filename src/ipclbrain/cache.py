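"""Activation cache: per-layer binary arrays plus a JSON manifest.

A cache directory holds one ``<layer>.npy`` per layer and a ``manifest.json``
recording the model hash, the image id list, and layer shapes. Reads validate
the manifest against what the caller expects so stale caches fail loudly.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .backbone import LayerActivations
from .errors import CacheInvalidError

MANIFEST_NAME = "manifest.json"


def save_activation_cache(
    path,
    activations: list[LayerActivations],
    model_hash: str,
    image_ids: list,
) -> None:
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    manifest = {
        "model_hash": model_hash,
        "image_ids": [str(i) for i in image_ids],
        "layers": {a.layer_name: list(a.matrix.shape) for a in activations},
    }
    for a in activations:
        if a.matrix.shape[0] != len(image_ids):
            raise CacheInvalidError(
                f"layer '{a.layer_name}' row count does not match image list"
            )
        np.save(root / f"{a.layer_name}.npy", a.matrix)
    (root / MANIFEST_NAME).write_text(json.dumps(manifest, indent=1, sort_keys=True))


def load_activation_cache(
    path,
    layers: list[str] | None = None,
    expect_model_hash: str | None = None,
    expect_image_ids: list | None = None,
) -> list[LayerActivations]:
    root = Path(path)
    manifest_path = root / MANIFEST_NAME
    if not manifest_path.exists():
        raise CacheInvalidError(f"no manifest at {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    if expect_model_hash is not None and manifest["model_hash"] != expect_model_hash:
        raise CacheInvalidError(
            f"cache model hash {manifest['model_hash']} != expected {expect_model_hash}"
        )
    if expect_image_ids is not None:
        if [str(i) for i in expect_image_ids] != manifest["image_ids"]:
            raise CacheInvalidError("cache image list does not match expected images")
    layers = layers or list(manifest["layers"])
    out = []
    for name in layers:
        if name not in manifest["layers"]:
            raise CacheInvalidError(f"layer '{name}' missing from cache manifest")
        f = root / f"{name}.npy"
        if not f.exists():
            raise CacheInvalidError(f"layer '{name}' array file missing from cache")
        matrix = np.load(f)
        if list(matrix.shape) != manifest["layers"][name]:
            raise CacheInvalidError(f"layer '{name}' shape disagrees with manifest")
        out.append(LayerActivations(layer_name=name, matrix=matrix))
    return out
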