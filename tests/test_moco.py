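import numpy as np
import pytest

from ecgssl.augment import AugmentationPolicy
from ecgssl.moco import (MoCoConfig, _batch_loss_and_grads, contrastive_loss,
                         divergence_loss, enqueue, init_moco, l2_normalize,
                         momentum_update, pretrain, softmax_distribution,
                         total_pretrain_loss)
from ecgssl.msdnn import MsdnnConfig
from ecgssl.synthetic import desk_spec, generate_dataset


def _unit(rng, d=8):
    v = rng.standard_normal(d)
    return v / np.linalg.norm(v)


class TestSoftmaxDistribution:
    def test_equal_similarities_give_uniform(self):
        q = np.zeros(4)
        q[0] = 1.0
        k_pos = np.zeros(4)
        k_pos[1] = 1.0                      # q.k+ = 0
        queue = np.stack([np.eye(4)[2], np.eye(4)[3]])  # q.k- = 0
        dist = softmax_distribution(q, k_pos, queue, tau=0.5)
        np.testing.assert_allclose(dist, 1 / 3)

    def test_worked_example_two_negatives(self):
        """tau=1, q.k+=2, two zero-similarity negatives -> e^2/(e^2+2)."""
        # direct evaluation through the loss path with synthetic dot products
        q = np.array([1.0, 0.0])
        k_pos = np.array([2.0, 0.0])        # dot = 2 (norm not required here)
        queue = np.array([[0.0, 1.0], [0.0, -1.0]])
        dist = softmax_distribution(q, k_pos, queue, tau=1.0)
        expected = np.exp(2) / (np.exp(2) + 2)
        assert dist[0] == pytest.approx(expected, abs=1e-4)
        assert dist[0] == pytest.approx(0.7870, abs=1e-4)
        assert contrastive_loss(dist) == pytest.approx(0.2395, abs=1e-4)

    def test_sums_to_one_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            dist = softmax_distribution(_unit(rng), _unit(rng),
                                        np.stack([_unit(rng)
                                                  for _ in range(6)]))
            assert dist.sum() == pytest.approx(1.0)
            assert (dist > 0).all()

    def test_nonpositive_temperature_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            softmax_distribution(_unit(rng), _unit(rng),
                                 np.stack([_unit(rng)]), tau=0.0)


class TestContrastiveLoss:
    @pytest.mark.parametrize("k", [1, 3, 7, 64, 511, 1024])
    def test_uniform_distribution_gives_log_k_plus_1(self, k):
        dist = np.full(k + 1, 1.0 / (k + 1))
        assert contrastive_loss(dist) == pytest.approx(np.log(k + 1),
                                                       rel=1e-12)

    def test_monotone_decreasing_in_positive_probability(self):
        losses = [contrastive_loss(np.array([p, 1 - p]))
                  for p in (0.2, 0.5, 0.9, 0.999)]
        assert losses == sorted(losses, reverse=True)
        assert losses[-1] < 1e-2


class TestDivergenceLoss:
    def test_identical_views_give_zero(self):
        d = np.array([0.5, 0.3, 0.2])
        assert divergence_loss(d, [d, d, d]) == 0.0

    def test_hand_computed_kl(self):
        anchor = np.array([0.8, 0.2])
        view = np.array([0.5, 0.5])
        expected = 0.8 * np.log(1.6) + 0.2 * np.log(0.4)
        assert divergence_loss(anchor, [view]) == pytest.approx(expected,
                                                                rel=1e-12)
        assert expected == pytest.approx(0.1927, abs=1e-4)

    def test_nonnegative_on_random_pairs(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.dirichlet(np.ones(5))
            b = rng.dirichlet(np.ones(5))
            assert divergence_loss(a, [b]) >= -1e-12

    def test_mismatched_support_rejected(self):
        with pytest.raises(ValueError):
            divergence_loss(np.array([0.5, 0.5]), [np.array([1.0])])


class TestTotalLossAndMomentum:
    def test_total_loss_arithmetic(self):
        assert total_pretrain_loss(1.0, 0.2, 0.15) == pytest.approx(1.03)
        assert total_pretrain_loss(1.0, 5.0, 0.0) == 1.0

    @pytest.mark.parametrize("m,expected", [(1.0, 1.0), (0.0, 0.0),
                                            (0.9, 0.9)])
    def test_momentum_endpoints(self, m, expected):
        out = momentum_update([np.ones(3)], [np.zeros(3)], m)
        np.testing.assert_allclose(out[0], expected)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            momentum_update([np.ones(3)], [np.ones(4)], 0.5)


class TestQueue:
    def _state(self, k=8, d=4, seed=0):
        enc = MsdnnConfig.desk(n_classes=2, input_samples=32, input_leads=2,
                               base_channels=8, growth=4, residual_units=1,
                               se_ratio=2, proj_dim=d)
        return init_moco(enc, MoCoConfig(queue_size=k, dim=d, batch_size=2),
                         seed=seed)

    def test_fifo_keeps_last_k_keys_in_order(self):
        """Ring-buffer oracle: enqueue 3 batches of 4 into K=8; queue holds
        the last 8 keys with the pointer wrapped."""
        state = self._state()
        rng = np.random.default_rng(2)
        batches = [np.stack([_unit(rng, 4) for _ in range(4)])
                   for _ in range(3)]
        for b in batches:
            enqueue(state, b)
        expected = np.concatenate([batches[2], batches[1]])  # after wrap
        np.testing.assert_allclose(state.queue[:4], batches[2])
        np.testing.assert_allclose(state.queue[4:], batches[1])
        assert state.ptr == 4
        assert state.queue.shape == (8, 4)

    def test_non_normalized_keys_rejected(self):
        state = self._state()
        with pytest.raises(ValueError):
            enqueue(state, np.ones((2, 4)))

    def test_oversized_batch_rejected(self):
        state = self._state()
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            enqueue(state, np.stack([_unit(rng, 4) for _ in range(9)]))


class TestLossGradients:
    def test_gradient_matches_finite_differences_on_toy_problem(self):
        """5-key toy: d(total loss)/d(embeddings) vs central differences."""
        rng = np.random.default_rng(4)
        v, b, d, k = 3, 2, 6, 4
        z = l2_normalize(rng.standard_normal((v, b, d)))
        k_pos = l2_normalize(rng.standard_normal((b, d)))
        queue = l2_normalize(rng.standard_normal((k, d)))
        tau, beta = 0.2, 0.15

        def total(zz):
            lc, ld, _ = _batch_loss_and_grads(zz, k_pos, queue, tau, beta)
            return lc + beta * ld

        _, _, dz = _batch_loss_and_grads(z, k_pos, queue, tau, beta)
        eps = 1e-6
        for _ in range(12):
            idx = tuple(rng.integers(0, s) for s in z.shape)
            zp, zm = z.copy(), z.copy()
            zp[idx] += eps
            zm[idx] -= eps
            num = (total(zp) - total(zm)) / (2 * eps)
            assert dz[idx] == pytest.approx(num, rel=1e-4, abs=1e-9)

    def test_uniform_logits_contrastive_equals_log_k_plus_1(self):
        for k in (1, 5, 32):
            z = np.zeros((1, 1, 3))
            z[0, 0, 0] = 1.0
            k_pos = np.zeros((1, 3))
            k_pos[0, 1] = 1.0
            queue = np.tile(k_pos, (k, 1))       # all similarities equal 0
            lc, _, _ = _batch_loss_and_grads(z, k_pos, queue, 0.07, 0.0)
            assert lc == pytest.approx(np.log(k + 1), rel=1e-12)


@pytest.fixture(scope="module")
def tiny_bench():
    spec = desk_spec(n_records=24, seed=5, duration_s=3.0)
    _, records, _ = generate_dataset(spec)
    return np.stack([r.signal for r in records]), spec.fs


class TestPretrainLoop:
    def _cfg(self, beta=0.15):
        enc = MsdnnConfig.desk(n_classes=7, input_samples=300,
                               base_channels=8, growth=4, residual_units=1,
                               se_ratio=2, proj_dim=8)
        moco = MoCoConfig(queue_size=32, batch_size=8, dim=8, n_views=2,
                          beta=beta)
        return enc, moco

    def test_trace_finite_and_deterministic(self, tiny_bench):
        """Replaying the seed reproduces the run bit for bit; losses stay
        finite and both components are reported per epoch."""
        x, fs = tiny_bench
        enc, moco = self._cfg()
        state, trace = pretrain(x, AugmentationPolicy(), enc, moco,
                                epochs=3, seed=1, fs=fs)
        assert all(np.isfinite(t["loss_total"]) for t in trace)
        assert all(t["loss_divergence"] >= 0 for t in trace)
        state2, trace2 = pretrain(x, AugmentationPolicy(), enc, moco,
                                  epochs=3, seed=1, fs=fs)
        assert trace == trace2
        for a, b in zip(state.query_params(), state2.query_params()):
            np.testing.assert_array_equal(a.data, b.data)

    def test_beta_zero_reduces_to_plain_contrastive(self, tiny_bench):
        """With beta=0 the divergence term never influences the run: the
        contrastive trace equals a reference run sharing seeds."""
        x, fs = tiny_bench
        enc, moco0 = self._cfg(beta=0.0)
        _, t0 = pretrain(x, AugmentationPolicy(), enc, moco0, epochs=2,
                         seed=2, fs=fs)
        for entry in t0:
            assert entry["loss_total"] == entry["loss_contrastive"]

    def test_queue_never_optimized_and_key_params_momentum_only(self,
                                                                tiny_bench):
        x, fs = tiny_bench
        enc, moco = self._cfg()
        state, _ = pretrain(x, AugmentationPolicy(), enc, moco, epochs=1,
                            seed=3, fs=fs)
        # key-encoder parameters carry no gradient buffers from the optimizer
        assert all(np.all(p.grad == 0) for p in state.key_params())
        np.testing.assert_allclose(np.linalg.norm(state.queue, axis=1), 1.0,
                                   atol=1e-6)
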