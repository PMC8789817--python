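"""Named-block feed-forward network and a plain SGD optimizer.

A :class:`Network` is an ordered sequence of named blocks, each a list of
layers. Block names (``conv1`` ... ``fc7``, ``embedding``) are the units of
activation extraction: a block's output is what downstream analyses see.
"""
from __future__ import annotations

import hashlib

import numpy as np

from ..errors import ConfigurationError, NumericError
from .layers import Layer, Parameter


class Network:
    def __init__(self, blocks: list[tuple[str, list[Layer]]], architecture: str = "custom"):
        names = [name for name, _ in blocks]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate block names: {names}")
        self.blocks = blocks
        self.architecture = architecture

    @property
    def layer_names(self) -> list[str]:
        return [name for name, _ in self.blocks]

    def forward(
        self,
        x: np.ndarray,
        capture: tuple[str, ...] = (),
        train: bool = False,
        check_finite: bool = True,
    ):
        """Run the network; returns (output, {block_name: activation})."""
        unknown = set(capture) - set(self.layer_names)
        if unknown:
            raise ConfigurationError(
                f"unknown layer name(s) {sorted(unknown)}; valid: {self.layer_names}"
            )
        captured: dict[str, np.ndarray] = {}
        out = np.asarray(x, dtype=np.float32)
        for name, layers in self.blocks:
            for layer in layers:
                out = layer.forward(out, train=train)
            if check_finite and not np.isfinite(out).all():
                raise NumericError(f"non-finite activations in layer '{name}'")
            if name in capture:
                captured[name] = out
        return out, captured

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        g = np.asarray(grad_out, dtype=np.float32)
        for _, layers in reversed(self.blocks):
            for layer in reversed(layers):
                g = layer.backward(g)
        return g

    def parameters(self) -> list[Parameter]:
        params = []
        for _, layers in self.blocks:
            for layer in layers:
                params.extend(layer.parameters())
        return params

    # -- state -------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for name, layers in self.blocks:
            for li, layer in enumerate(layers):
                for p in layer.parameters():
                    state[f"{name}.{li}.{p.name}"] = p.data.copy()
                for bname, buf in layer.buffers().items():
                    state[f"{name}.{li}.buffer.{bname}"] = np.asarray(buf).copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own_params = {}
        buffered_layers = {}
        for name, layers in self.blocks:
            for li, layer in enumerate(layers):
                for p in layer.parameters():
                    own_params[f"{name}.{li}.{p.name}"] = p
                if layer.buffers():
                    buffered_layers[f"{name}.{li}"] = layer
        expected = set(own_params) | {
            f"{prefix}.buffer.{bname}"
            for prefix, layer in buffered_layers.items()
            for bname in layer.buffers()
        }
        if expected != set(state):
            raise ConfigurationError("state dict keys do not match architecture")
        for key, p in own_params.items():
            arr = np.asarray(state[key], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ConfigurationError(f"shape mismatch for '{key}'")
            p.data[...] = arr
        for prefix, layer in buffered_layers.items():
            layer.load_buffers({
                bname: np.asarray(state[f"{prefix}.buffer.{bname}"])
                for bname in layer.buffers()
            })

    def state_hash(self) -> str:
        """Short content hash over architecture and parameter values."""
        h = hashlib.sha256()
        h.update(self.architecture.encode())
        for key in sorted(self.state_dict()):
            h.update(key.encode())
        for key, arr in sorted(self.state_dict().items()):
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()[:16]

    def save(self, path) -> None:
        np.savez(path, architecture=self.architecture, **self.state_dict())


class SGD:
    """SGD with classical momentum and optional weight decay."""

    def __init__(self, params: list[Parameter], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        if lr <= 0:
            raise ConfigurationError("learning rate must be positive")
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v


def cosine_lr(base_lr: float, step: int, total_steps: int) -> float:
    """Cosine-annealed learning rate from base_lr to 0 over total_steps."""
    if total_steps <= 1:
        return base_lr
    frac = min(step / (total_steps - 1), 1.0)
    return 0.5 * base_lr * (1.0 + np.cos(np.pi * frac))
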