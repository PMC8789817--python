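"""Emergent-category readouts: similarity-weighted kNN and a linear probe.

Neither readout changes the learned features; both measure how much category
structure is implicitly present. The kNN readout finds the k (default 200)
nearest neighbors by cosine similarity and weights each neighbor's class by
exp(similarity / tau); the linear probe trains a new softmax classification
layer over frozen features. Ties in class score break toward the lowest
class index (pinned for reproducibility).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backbone import LayerActivations
from .errors import ConfigurationError, InputError


@dataclass
class ReadoutConfig:
    k: int = 200
    knn_temperature: float = 0.07
    probe_epochs: int = 300
    probe_lr: float = 0.5
    probe_weight_decay: float = 1e-4

    def __post_init__(self):
        if self.k < 1:
            raise ConfigurationError("k must be >= 1")
        if self.knn_temperature <= 0:
            raise ConfigurationError("knn_temperature must be positive")
        if self.probe_epochs < 0:
            raise ConfigurationError("probe_epochs must be nonnegative")


@dataclass
class MemoryBank:
    embeddings: np.ndarray  # (n_items, dim), unit rows
    labels: np.ndarray  # (n_items,) integer class ids

    def __post_init__(self):
        self.embeddings = np.asarray(self.embeddings, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.embeddings.ndim != 2:
            raise InputError("bank embeddings must be 2-D")
        if self.labels.shape[0] != self.embeddings.shape[0]:
            raise InputError("labels must align with embeddings")
        norms = np.linalg.norm(self.embeddings, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-3):
            raise InputError("bank rows must be unit-norm (use from_features)")

    @classmethod
    def from_features(cls, matrix, labels) -> "MemoryBank":
        """Build a bank from arbitrary features by L2-normalizing rows."""
        if isinstance(matrix, LayerActivations):
            matrix = matrix.matrix
        x = np.asarray(matrix, dtype=float)
        norms = np.linalg.norm(x, axis=1, keepdims=True)
        if np.any(norms < 1e-12):
            raise InputError("zero feature row cannot be normalized")
        return cls(embeddings=x / norms, labels=np.asarray(labels))

    @property
    def n_items(self) -> int:
        return self.embeddings.shape[0]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)


def _class_scores(sim_rows: np.ndarray, bank: MemoryBank, k: int, tau: float):
    """Similarity-weighted class scores for each query row of similarities."""
    classes = bank.classes
    k_eff = min(k, bank.n_items - np.isneginf(sim_rows).sum(axis=1).max())
    k_eff = max(int(k_eff), 1)
    nbr = np.argpartition(-sim_rows, kth=k_eff - 1, axis=1)[:, :k_eff]
    rows = np.arange(sim_rows.shape[0])[:, None]
    sims = sim_rows[rows, nbr]
    weights = np.exp(sims / tau)
    weights[np.isneginf(sims)] = 0.0
    nbr_labels = bank.labels[nbr]
    scores = np.zeros((sim_rows.shape[0], classes.size))
    for ci, c in enumerate(classes):
        scores[:, ci] = np.where(nbr_labels == c, weights, 0.0).sum(axis=1)
    return classes, scores


def knn_predict(query: np.ndarray, bank: MemoryBank, config: ReadoutConfig):
    """Class scores and the top-weighted label for one unit-norm query.

    Neighbors are the top-k by cosine similarity (the whole bank when
    k exceeds its size); each neighbor contributes exp(sim/tau) to its
    class. Returns (classes, scores, predicted_label).
    """
    if bank.n_items == 0:
        raise InputError("empty memory bank")
    q = np.asarray(query, dtype=float).reshape(1, -1)
    sim = q @ bank.embeddings.T
    classes, scores = _class_scores(sim, bank, config.k, config.knn_temperature)
    return classes, scores[0], classes[int(np.argmax(scores[0]))]


def knn_accuracy(
    query_embeddings,
    query_labels,
    bank: MemoryBank,
    config: ReadoutConfig | None = None,
    exclude_self: bool = False,
) -> float:
    """Top-1 weighted-kNN accuracy in percent.

    ``exclude_self=True`` removes the i-th bank item from the i-th query's
    neighbor set (queries must then be the bank items in order); disjointness
    of query and bank is otherwise the caller's responsibility.
    """
    config = config or ReadoutConfig()
    q = np.asarray(query_embeddings, dtype=float)
    labels = np.asarray(query_labels)
    if q.ndim != 2 or q.shape[0] == 0:
        raise InputError("need at least one query")
    if labels.shape[0] != q.shape[0]:
        raise InputError("query labels must align with query embeddings")
    sim = q @ bank.embeddings.T
    if exclude_self:
        if q.shape[0] != bank.n_items:
            raise InputError("exclude_self requires queries aligned with the bank")
        np.fill_diagonal(sim, -np.inf)
    classes, scores = _class_scores(sim, bank, config.k, config.knn_temperature)
    pred = classes[np.argmax(scores, axis=1)]
    return float(100.0 * np.mean(pred == labels))


def _softmax_rows(a: np.ndarray) -> np.ndarray:
    a = a - a.max(axis=1, keepdims=True)
    e = np.exp(a)
    return e / e.sum(axis=1, keepdims=True)


def linear_probe(
    train_features,
    train_labels,
    test_features,
    test_labels,
    config: ReadoutConfig | None = None,
) -> float:
    """Held-out top-1 percent of a softmax classifier on frozen features.

    Full-batch gradient descent from zero-initialized weights on features
    standardized with training-set statistics. With ``probe_epochs = 0`` the
    classifier stays at zero weights, every class ties, and the argmax policy
    (lowest class index) decides every prediction.
    """
    config = config or ReadoutConfig()
    xtr = train_features.matrix if isinstance(train_features, LayerActivations) else train_features
    xte = test_features.matrix if isinstance(test_features, LayerActivations) else test_features
    xtr = np.asarray(xtr, dtype=float)
    xte = np.asarray(xte, dtype=float)
    if xtr.shape[1] != xte.shape[1]:
        raise InputError("train/test feature dimensions differ")
    ytr = np.asarray(train_labels)
    yte = np.asarray(test_labels)
    classes = np.unique(ytr)
    if classes.size < 2:
        raise InputError("training labels must cover at least 2 classes")
    mu, sd = xtr.mean(axis=0), xtr.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    xtr = (xtr - mu) / sd
    xte = (xte - mu) / sd

    y_idx = np.searchsorted(classes, ytr)
    onehot = np.eye(classes.size)[y_idx]
    w = np.zeros((xtr.shape[1], classes.size))
    b = np.zeros(classes.size)
    n = xtr.shape[0]
    for _ in range(config.probe_epochs):
        probs = _softmax_rows(xtr @ w + b)
        g = (probs - onehot) / n
        w -= config.probe_lr * (xtr.T @ g + config.probe_weight_decay * w)
        b -= config.probe_lr * g.sum(axis=0)
    pred = classes[np.argmax(xte @ w + b, axis=1)]
    return float(100.0 * np.mean(pred == yte))
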