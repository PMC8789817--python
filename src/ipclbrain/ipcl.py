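"""Instance-prototype contrastive learning (IPCL).

Each image is sampled with ``n_views`` augmentations and embedded on the unit
hypersphere. The *instance prototype* is the renormalized mean of one image's
view embeddings. Per view v of instance i with prototype p_i and memory queue
Q of recently encountered items (one slot per image, holding its prototype),
the loss is the non-parametric softmax

    l = -log[ exp(v.p_i / tau) / (exp(v.p_i / tau) + sum_q exp(v.q / tau)) ]

averaged over all views and instances. The positive term pulls views toward
their prototype (alignment); the queue term pushes them away from recent
items (uniformity over the hypersphere). With an empty queue the ratio is 1
and the loss is exactly 0.

Gradients flow through both the view embedding and the prototype (the
prototype is a function of the same batch); a flag stops the prototype path
for ablations. Queue entries are stored detached and never receive gradient.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp, softmax

from .augment import AugmentConfig, sample_views
from .backbone import BackboneConfig, build_backbone, input_size_for
from .errors import (
    ConfigurationError,
    DegeneratePrototypeError,
    InputError,
    TrainingError,
)
from .fixtures import LabeledImageSet
from .nn import SGD, Network, cosine_lr

_UNIT_TOL = 1e-4


@dataclass
class IPCLConfig:
    temperature: float = 0.07
    n_views: int = 5
    queue_capacity: int = 4096
    epochs: int = 30
    batch_size: int = 32
    lr: float = 0.03
    momentum: float = 0.9
    weight_decay: float = 1e-4
    cosine_decay: bool = True
    # ramp the learning rate linearly over the first epochs; protects the
    # early transient in which view alignment can erase feature variance
    # before the contrastive term has hard negatives to push against
    lr_warmup_epochs: int = 3
    # fill the queue with prototypes from a forward pass before the first
    # update, so negatives exist from step 0
    queue_warmup: bool = True
    prototype_gradient: bool = True
    batch_negatives: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ConfigurationError("temperature must be positive")
        if self.n_views < 1:
            raise ConfigurationError("n_views must be >= 1")
        if self.queue_capacity < 1:
            raise ConfigurationError("queue_capacity must be >= 1")


class MemoryQueue:
    """FIFO store of unit vectors; strictly oldest-first eviction."""

    def __init__(self, capacity: int = 4096, dim: int | None = None):
        if capacity < 1:
            raise ConfigurationError("queue capacity must be >= 1")
        self.capacity = capacity
        self.dim = dim
        self._items: list[np.ndarray] = []

    @property
    def current_size(self) -> int:
        return len(self._items)

    def __len__(self) -> int:
        return self.current_size

    def push(self, vectors: np.ndarray) -> None:
        vectors = np.atleast_2d(np.asarray(vectors, dtype=np.float32))
        _check_unit(vectors, "queue entries")
        if self.dim is None:
            self.dim = vectors.shape[1]
        elif vectors.shape[1] != self.dim:
            raise InputError("queue dimension mismatch")
        for v in vectors:
            self._items.append(v.copy())
        overflow = len(self._items) - self.capacity
        if overflow > 0:
            del self._items[:overflow]

    def as_array(self) -> np.ndarray:
        """Entries oldest (head) to newest (tail); empty -> (0, dim)."""
        if not self._items:
            return np.zeros((0, self.dim or 0), dtype=np.float32)
        return np.stack(self._items)


def queue_push(queue: MemoryQueue, embeddings: np.ndarray) -> MemoryQueue:
    """FIFO append (one slot per image); returns the mutated queue."""
    queue.push(embeddings)
    return queue


def _check_unit(vectors: np.ndarray, what: str) -> None:
    norms = np.linalg.norm(vectors, axis=-1)
    if not np.allclose(norms, 1.0, atol=_UNIT_TOL):
        raise InputError(f"{what} must be unit-norm (max deviation "
                         f"{np.abs(norms - 1).max():.2e})")


def compute_prototype(views: np.ndarray) -> np.ndarray:
    """Unit-renormalized mean of one instance's view embeddings."""
    views = np.atleast_2d(np.asarray(views, dtype=float))
    if views.shape[0] < 1:
        raise InputError("need at least one view")
    mean = views.mean(axis=0)
    norm = np.linalg.norm(mean)
    if norm < 1e-8:
        raise DegeneratePrototypeError("views cancel: prototype norm < 1e-8")
    return mean / norm


def compute_prototypes(embeddings: np.ndarray) -> np.ndarray:
    """Prototypes for a (n_instances, n_views, dim) embedding array."""
    z = np.asarray(embeddings, dtype=float)
    if z.ndim != 3:
        raise InputError("embeddings must be (instances, views, dim)")
    mean = z.mean(axis=1)
    norms = np.linalg.norm(mean, axis=1)
    if np.any(norms < 1e-8):
        raise DegeneratePrototypeError("views cancel: prototype norm < 1e-8")
    return mean / norms[:, None]


def ipcl_loss(
    embeddings: np.ndarray,
    prototypes: np.ndarray,
    queue: MemoryQueue,
    temperature: float = 0.07,
) -> float:
    """Mean instance-prototype contrastive loss over all views and instances."""
    if temperature <= 0:
        raise ConfigurationError("temperature must be positive")
    z = np.asarray(embeddings, dtype=float)
    p = np.asarray(prototypes, dtype=float)
    if z.ndim != 3 or p.ndim != 2 or z.shape[0] != p.shape[0] or z.shape[2] != p.shape[1]:
        raise InputError("embeddings (N, V, d) and prototypes (N, d) must align")
    _check_unit(z, "view embeddings")
    _check_unit(p, "prototypes")
    q = queue.as_array().astype(float)
    if q.shape[0] == 0:
        return 0.0
    pos = np.einsum("nvd,nd->nv", z, p) / temperature  # (N, V)
    neg = z @ q.T / temperature  # (N, V, K)
    logits = np.concatenate([pos[..., None], neg], axis=-1)
    return float(np.mean(logsumexp(logits, axis=-1) - pos))


def ipcl_loss_and_grad(
    embeddings: np.ndarray,
    queue: MemoryQueue,
    temperature: float = 0.07,
    prototype_gradient: bool = True,
    batch_negatives: bool = False,
):
    """Loss and d(loss)/d(embeddings) with prototypes recomputed internally.

    ``embeddings`` (N, V, d) need not be exactly unit here (useful for
    finite-difference checks); the prototype is the renormalized view mean.
    With ``batch_negatives`` the other instances' prototypes join the
    negative set and (when ``prototype_gradient``) receive gradient, so
    instances in a batch mutually repel.
    """
    if temperature <= 0:
        raise ConfigurationError("temperature must be positive")
    z = np.asarray(embeddings, dtype=float)
    n, v, d = z.shape
    mean = z.mean(axis=1)
    norms = np.linalg.norm(mean, axis=1)
    if np.any(norms < 1e-8):
        raise DegeneratePrototypeError("views cancel: prototype norm < 1e-8")
    p = mean / norms[:, None]

    q = queue.as_array().astype(float)
    k1 = q.shape[0]
    use_batch = batch_negatives and n > 1
    if k1 == 0 and not use_batch:
        return 0.0, np.zeros_like(z)

    tau = temperature
    pos = np.einsum("nvd,nd->nv", z, p) / tau  # (N, V)
    parts = [pos[..., None]]
    if k1:
        parts.append((z @ q.T) / tau)  # (N, V, K)
    if use_batch:
        blog = np.einsum("nvd,jd->nvj", z, p) / tau  # (N, V, N)
        blog[np.arange(n), :, np.arange(n)] = -np.inf  # own prototype is the positive
        parts.append(blog)
    logits = np.concatenate(parts, axis=-1)
    s = softmax(logits, axis=-1)
    loss = float(np.mean(logsumexp(logits, axis=-1) - pos))

    s0 = s[..., 0]
    grad = (s0 - 1.0)[..., None] * p[:, None, :]
    if k1:
        grad = grad + s[..., 1 : 1 + k1] @ q
    if use_batch:
        s_b = s[..., 1 + k1 :]  # (N, V, N); masked entries are exactly 0
        grad = grad + np.einsum("nvj,jd->nvd", s_b, p)
    if prototype_gradient:
        # chain through p_j = mean(z_j) / ||mean(z_j)||: the positive path
        # for j's own views, plus (with batch negatives) the repulsion path
        # from every other instance's views
        c = np.einsum("nv,nvd->nd", s0 - 1.0, z)
        if use_batch:
            c = c + np.einsum("nvj,nvd->jd", s_b, z)
        c = c - np.einsum("nd,nd->n", c, p)[:, None] * p
        grad = grad + (c / (v * norms[:, None]))[:, None, :]
    return loss, grad / (n * v * tau)


@dataclass
class TrainingHistory:
    records: pd.DataFrame  # columns: step, epoch, loss, queue_size, lr

    def epoch_losses(self) -> pd.Series:
        return self.records.groupby("epoch")["loss"].mean()

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False, float_format="%.8g")


def train_ipcl(
    dataset: LabeledImageSet,
    backbone_config: BackboneConfig,
    ipcl_config: IPCLConfig,
    augment_config: AugmentConfig | None = None,
) -> tuple[Network, TrainingHistory]:
    """Self-supervised training; class labels are never used.

    Per step: sample views -> embed -> prototype -> loss -> gradient step ->
    push prototypes onto the queue. Deterministic given the config seed
    (single-threaded).
    """
    if dataset.n_images == 0:
        raise InputError("dataset is empty")
    if not backbone_config.l2_norm_output or backbone_config.classifier_classes:
        raise ConfigurationError("IPCL training requires an L2-normed embedding head")
    size = input_size_for(backbone_config.architecture)
    if augment_config is None:
        augment_config = AugmentConfig(output_size=size, n_views=ipcl_config.n_views)
    if augment_config.n_views != ipcl_config.n_views:
        raise ConfigurationError("augment n_views must match ipcl n_views")

    rng = np.random.default_rng(ipcl_config.seed)
    model = build_backbone(backbone_config, seed=int(rng.integers(0, 2**31 - 1)))
    queue = MemoryQueue(capacity=ipcl_config.queue_capacity)
    opt = SGD(
        model.parameters(),
        lr=ipcl_config.lr,
        momentum=ipcl_config.momentum,
        weight_decay=ipcl_config.weight_decay,
    )
    n, v = dataset.n_images, ipcl_config.n_views
    steps_per_epoch = int(np.ceil(n / ipcl_config.batch_size))
    total_steps = max(steps_per_epoch * ipcl_config.epochs, 1)
    warmup_steps = steps_per_epoch * ipcl_config.lr_warmup_epochs

    def lr_at(step: int) -> float:
        if warmup_steps and step < warmup_steps:
            return ipcl_config.lr * (step + 1) / warmup_steps
        if ipcl_config.cosine_decay:
            return cosine_lr(ipcl_config.lr, step - warmup_steps,
                             max(total_steps - warmup_steps, 1))
        return ipcl_config.lr

    if ipcl_config.queue_warmup and ipcl_config.epochs > 0:
        for start in range(0, n, ipcl_config.batch_size):
            batch_idx = np.arange(start, min(start + ipcl_config.batch_size, n))
            views = np.stack([
                sample_views(dataset.images[i], augment_config, rng)
                for i in batch_idx
            ])
            z_flat, _ = model.forward(
                views.reshape(batch_idx.size * v, *views.shape[2:]), train=True)
            protos = compute_prototypes(z_flat.astype(float)
                                        .reshape(batch_idx.size, v, -1))
            queue_push(queue, protos.astype(np.float32))

    rows = []
    step = 0
    for epoch in range(ipcl_config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, ipcl_config.batch_size):
            batch_idx = order[start : start + ipcl_config.batch_size]
            b = batch_idx.size
            views = np.empty(
                (b, v, 3, augment_config.output_size, augment_config.output_size),
                dtype=np.float32,
            )
            for i, img_i in enumerate(batch_idx):
                views[i] = sample_views(dataset.images[img_i], augment_config, rng)
            flat = views.reshape(b * v, *views.shape[2:])
            z_flat, _ = model.forward(flat, train=True)
            z = z_flat.astype(float).reshape(b, v, -1)

            loss, dz = ipcl_loss_and_grad(
                z,
                queue,
                temperature=ipcl_config.temperature,
                prototype_gradient=ipcl_config.prototype_gradient,
                batch_negatives=ipcl_config.batch_negatives,
            )
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at step {step}")
            opt.lr = lr_at(step)
            opt.zero_grad()
            model.backward(dz.reshape(b * v, -1).astype(np.float32))
            opt.step()

            queue_push(queue, compute_prototypes(z).astype(np.float32))
            rows.append(
                {"step": step, "epoch": epoch, "loss": loss,
                 "queue_size": queue.current_size, "lr": opt.lr}
            )
            step += 1
    history = TrainingHistory(records=pd.DataFrame(
        rows, columns=["step", "epoch", "loss", "queue_size", "lr"]))
    return model, history
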