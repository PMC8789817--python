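"""Instance-prototype contrastive objective: prototypes, queue, loss, training."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ipclbrain as ib
from ipclbrain.errors import (
    ConfigurationError,
    DegeneratePrototypeError,
    InputError,
)
from ipclbrain.ipcl import MemoryQueue, ipcl_loss_and_grad


def unit_rows(x):
    return x / np.linalg.norm(x, axis=-1, keepdims=True)


def random_embeddings(n, v, d, seed):
    return unit_rows(np.random.default_rng(seed).normal(size=(n, v, d)))


def filled_queue(k, d, seed, capacity=None):
    q = MemoryQueue(capacity or max(k, 1), dim=d)
    if k:
        q.push(unit_rows(np.random.default_rng(seed).normal(size=(k, d))))
    return q


def loss_oracle(z, queue_vectors, tau):
    """Element-wise scalar-loop reference, written independently of the
    vectorized implementation."""
    n, v, _ = z.shape
    total = 0.0
    for i in range(n):
        mean = z[i].mean(axis=0)
        p = mean / np.linalg.norm(mean)
        for k in range(v):
            pos = math.exp(float(np.dot(z[i, k], p)) / tau)
            denom = pos
            for q in queue_vectors:
                denom += math.exp(float(np.dot(z[i, k], q)) / tau)
            total += -math.log(pos / denom)
    return total / (n * v)


class TestPrototype:
    def test_mean_of_copies_is_the_copy(self):
        v = unit_rows(np.random.default_rng(0).normal(size=(1, 7)))[0]
        np.testing.assert_allclose(ib.compute_prototype(np.stack([v, v, v])), v,
                                   atol=1e-12)

    def test_two_orthonormal_views_closed_form(self):
        e1, e2 = np.eye(4)[0], np.eye(4)[1]
        np.testing.assert_allclose(ib.compute_prototype(np.stack([e1, e2])),
                                   (e1 + e2) / np.sqrt(2), atol=1e-12)

    def test_cancelling_views_raise(self):
        v = unit_rows(np.random.default_rng(1).normal(size=(1, 5)))[0]
        with pytest.raises(DegeneratePrototypeError):
            ib.compute_prototype(np.stack([v, -v]))

    def test_batch_prototypes_match_per_instance(self):
        z = random_embeddings(4, 5, 8, seed=2)
        batch = ib.compute_prototypes(z)
        for i in range(4):
            np.testing.assert_allclose(batch[i], ib.compute_prototype(z[i]),
                                       atol=1e-12)


class TestMemoryQueue:
    def test_push_one_onto_empty(self):
        q = MemoryQueue(4096)
        ib.queue_push(q, unit_rows(np.random.default_rng(0).normal(size=(1, 8))))
        assert q.current_size == 1

    def test_capacity_evicts_oldest_first(self):
        q = MemoryQueue(4096, dim=4)
        first = np.eye(4)[0]
        q.push(first)
        vecs = unit_rows(np.random.default_rng(1).normal(size=(4096, 4)))
        q.push(vecs)
        assert q.current_size == 4096
        arr = q.as_array()
        assert not any(np.allclose(row, first) for row in arr[:5])
        np.testing.assert_allclose(arr[-1], vecs[-1], atol=1e-7)

    def test_fifo_order_head_oldest_tail_newest(self):
        q = MemoryQueue(8, dim=3)
        a, b = np.eye(3)[0], np.eye(3)[1]
        q.push(a)
        q.push(b)
        arr = q.as_array()
        np.testing.assert_array_equal(arr[0], a)
        np.testing.assert_array_equal(arr[1], b)

    def test_non_unit_vectors_rejected(self):
        q = MemoryQueue(4)
        with pytest.raises(InputError):
            q.push(np.array([[2.0, 0.0]]))


class TestIpclLoss:
    def test_empty_queue_gives_zero_loss(self):
        z = random_embeddings(3, 5, 8, seed=0)
        assert ib.ipcl_loss(z, ib.compute_prototypes(z), MemoryQueue(64, dim=8),
                            0.07) == 0.0

    @pytest.mark.parametrize("tau", [0.05, 0.07, 0.2])
    def test_single_equal_logit_negative_gives_ln2(self, tau):
        """One negative whose similarity to the view equals the prototype
        similarity: the softmax has two equal logits, loss = ln 2."""
        d = 6
        v = np.eye(d)[0]
        z = np.stack([[v, v]])  # one instance, two identical views -> p = v
        q = MemoryQueue(4, dim=d)
        q.push(v)  # negative identical to prototype: equal logits
        loss = ib.ipcl_loss(z, ib.compute_prototypes(z), q, tau)
        assert loss == pytest.approx(math.log(2.0), abs=1e-9)

    def test_matches_scalar_oracle_on_spec_size(self):
        z = random_embeddings(8, 5, 16, seed=3)
        qv = unit_rows(np.random.default_rng(4).normal(size=(64, 16)))
        q = MemoryQueue(64, dim=16)
        q.push(qv)
        vec = ib.ipcl_loss(z, ib.compute_prototypes(z), q, 0.07)
        assert vec == pytest.approx(loss_oracle(z, qv, 0.07), abs=1e-6)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_loss_oracle_equivalence_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 9))
        v = int(rng.integers(1, 6))
        d = int(rng.integers(3, 17))
        k = int(rng.integers(0, 65))
        tau = float(rng.uniform(0.03, 0.5))
        z = unit_rows(rng.normal(size=(n, v, d)))
        qv = unit_rows(rng.normal(size=(k, d))) if k else np.zeros((0, d))
        q = MemoryQueue(max(k, 1), dim=d)
        if k:
            q.push(qv)
        vec = ib.ipcl_loss(z, ib.compute_prototypes(z), q, tau)
        assert vec == pytest.approx(loss_oracle(z, qv, tau), abs=1e-6)

    def test_gradient_matches_finite_differences(self):
        z = random_embeddings(2, 3, 5, seed=5)
        q = filled_queue(6, 5, seed=6)
        _, grad = ipcl_loss_and_grad(z, q, 0.07)
        eps = 1e-6
        for idx in np.ndindex(z.shape):
            zp, zm = z.copy(), z.copy()
            zp[idx] += eps
            zm[idx] -= eps
            fd = (ipcl_loss_and_grad(zp, q, 0.07)[0]
                  - ipcl_loss_and_grad(zm, q, 0.07)[0]) / (2 * eps)
            assert grad[idx] == pytest.approx(fd, abs=1e-4)

    def test_prototype_stop_gradient_changes_gradient_not_loss(self):
        z = random_embeddings(2, 3, 5, seed=7)
        q = filled_queue(6, 5, seed=8)
        l1, g1 = ipcl_loss_and_grad(z, q, 0.07, prototype_gradient=True)
        l2, g2 = ipcl_loss_and_grad(z, q, 0.07, prototype_gradient=False)
        assert l1 == l2
        assert not np.allclose(g1, g2)

    def test_aligned_negative_raises_loss_more_than_orthogonal(self):
        """Softmax monotonicity: a negative equal to the prototype is a much
        harder distractor than an orthogonal one."""
        d = 8
        z = random_embeddings(1, 4, d, seed=9)
        p = ib.compute_prototypes(z)[0]
        base_q = filled_queue(4, d, seed=10)
        base = ib.ipcl_loss(z, p[None], base_q, 0.07)

        ortho = np.random.default_rng(11).normal(size=d)
        ortho -= (ortho @ p) * p
        ortho /= np.linalg.norm(ortho)

        q_aligned = filled_queue(4, d, seed=10)
        q_aligned.push(p)
        q_ortho = filled_queue(4, d, seed=10)
        q_ortho.push(ortho)
        hard = ib.ipcl_loss(z, p[None], q_aligned, 0.07)
        easy = ib.ipcl_loss(z, p[None], q_ortho, 0.07)
        assert hard > easy > base

    def test_invalid_inputs(self):
        z = random_embeddings(2, 3, 4, seed=12)
        q = filled_queue(3, 4, seed=13)
        with pytest.raises(ConfigurationError):
            ib.ipcl_loss(z, ib.compute_prototypes(z), q, temperature=-1.0)
        with pytest.raises(InputError):
            ib.ipcl_loss(2.0 * z, ib.compute_prototypes(z), q, 0.07)


class TestTraining:
    def test_zero_epochs_returns_initialization(self, shape_world, backbone_config,
                                                augment_config):
        cfg = ib.IPCLConfig(epochs=0, seed=21)
        model, history = ib.train_ipcl(shape_world, backbone_config, cfg,
                                       augment_config)
        reference = ib.build_backbone(
            backbone_config,
            seed=int(np.random.default_rng(21).integers(0, 2**31 - 1)),
        )
        for key, val in model.state_dict().items():
            np.testing.assert_array_equal(val, reference.state_dict()[key])
        assert len(history.records) == 0

    def test_training_is_deterministic_given_seed(self, backbone_config,
                                                  augment_config):
        small = ib.generate_shape_world(
            ib.ShapeWorldSpec(n_classes=2, n_instances_per_class=8, seed=1))
        cfg = ib.IPCLConfig(epochs=2, batch_size=8, seed=5, queue_capacity=64)
        _, h1 = ib.train_ipcl(small, backbone_config, cfg, augment_config)
        _, h2 = ib.train_ipcl(small, backbone_config, cfg, augment_config)
        assert h1.records.equals(h2.records)

    def test_history_schema_and_queue_growth(self, trained_run):
        rec = trained_run.history.records
        assert list(rec.columns) == ["step", "epoch", "loss", "queue_size", "lr"]
        assert rec["queue_size"].is_monotonic_increasing
        assert np.isfinite(rec["loss"]).all()

    def test_final_epoch_loss_below_first_stable_epoch(self, trained_run):
        """Once the queue has saturated, continued training reduces the loss."""
        el = trained_run.history.epoch_losses()
        full_queue_epochs = el[trained_run.history.records.groupby("epoch")
                               ["queue_size"].min() >= trained_run.ipcl_config
                               .queue_capacity]
        assert el.iloc[-1] < full_queue_epochs.iloc[0]

    def test_alignment_margin_improves_and_space_does_not_collapse(self, trained_run):
        """Views of one image end up near their prototype *and distinct from
        other images*: the within-instance vs cross-instance similarity
        margin grows with training, while cross-instance similarity does not
        increase (no collapse)."""
        ds = trained_run.dataset
        cfg = trained_run.augment_config
        rng = np.random.default_rng(5)
        idx = rng.choice(ds.n_images, size=30, replace=False)

        def stats(model):
            within, protos = [], []
            for i in idx:
                views = ib.sample_views(ds.images[i], cfg,
                                        np.random.default_rng(900 + int(i)))
                z = ib.forward_embed(model, views)
                within.append((z @ z.T)[np.triu_indices(len(z), 1)].mean())
                protos.append(ib.compute_prototype(z))
            p = np.stack(protos)
            cross = (p @ p.T)[np.triu_indices(len(p), 1)].mean()
            return float(np.mean(within)), float(cross)

        w_before, c_before = stats(trained_run.untrained)
        w_after, c_after = stats(trained_run.model)
        assert (w_after - c_after) > (w_before - c_before)
        assert c_after <= c_before + 0.05
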