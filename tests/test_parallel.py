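"""Parallel-training algebra: shard plans, weighted aggregation vs the
closed-form full-batch gradient, and exact serial equivalence of the
data-, model- and hybrid-parallel step functions."""

import numpy as np
import pytest

from gapcnn.network import (
    GradientSet,
    init_params,
    tiny_spec,
)
from gapcnn.optim import make_optimizer
from gapcnn.parallel import (
    HybridConfig,
    aggregate_gradients,
    data_parallel_step,
    hybrid_step,
    make_shard_plan,
    model_parallel_dense,
    model_parallel_dense_backward,
    model_parallel_step,
    partition_fc,
    serial_step,
)


def params_rel_diff(p1, p2):
    worst = 0.0
    for k in p1:
        denom = np.maximum(np.abs(p1[k]), 1e-12)
        worst = max(worst, float(np.max(np.abs(p1[k] - p2[k]) / denom)))
    return worst


class TestShardPlan:
    @pytest.mark.parametrize(
        "n,k,sizes",
        [(10, 2, (5, 5)), (10, 4, (3, 3, 2, 2)), (4, 1, (4,)), (7, 3, (3, 2, 2))],
    )
    def test_near_equal_sizes(self, n, k, sizes):
        plan = make_shard_plan(n, k, seed=0)
        assert plan.shard_sizes == sizes
        assert sorted(np.concatenate(plan.shard_indices)) == list(range(n))

    def test_single_worker_identity_permutation(self):
        plan = make_shard_plan(4, 1, seed=123)
        assert np.array_equal(plan.shard_indices[0], np.arange(4))

    def test_deterministic_given_seed(self):
        p1 = make_shard_plan(20, 3, seed=5)
        p2 = make_shard_plan(20, 3, seed=5)
        for a, b in zip(p1.shard_indices, p2.shard_indices):
            assert np.array_equal(a, b)

    def test_invalid_worker_counts_rejected(self):
        with pytest.raises(ValueError):
            make_shard_plan(3, 4)
        with pytest.raises(ValueError):
            make_shard_plan(3, 0)


class TestAggregation:
    def g(self, v):
        return GradientSet({"w": np.array([float(v)])})

    def test_single_shard_identity(self):
        out = aggregate_gradients([self.g(2.5)], [7])
        assert out["w"][0] == 2.5

    def test_equal_shards_reduce_to_mean(self):
        out = aggregate_gradients([self.g(2.0), self.g(4.0)], [5, 5])
        assert out["w"][0] == 3.0

    def test_weighted_combination_equals_full_batch_gradient(self):
        # 1-parameter quadratic loss L(w) = (1/n) sum_i (w - t_i)^2 at w=0:
        # full-batch grad = -(2/n) sum t_i; shard grads computed per shard.
        targets = np.array([1.0, 2.0, 3.0, -5.0])
        shards = [targets[:3], targets[3:]]
        shard_grads = [self.g(-2.0 * s.mean()) for s in shards]
        agg = aggregate_gradients(shard_grads, [3, 1])
        assert agg["w"][0] == pytest.approx(-2.0 * targets.mean(), abs=1e-15)
        # the spec'd scalar stand-in: sizes (3,1), g=(2,6) -> 3
        out = aggregate_gradients([self.g(2.0), self.g(6.0)], [3, 1])
        assert out["w"][0] == 3.0

    def test_permutation_invariance(self, rng):
        grads = [GradientSet({"w": rng.standard_normal(4)}) for _ in range(5)]
        sizes = [3, 1, 4, 2, 2]
        a = aggregate_gradients(grads, sizes)
        order = [4, 2, 0, 3, 1]
        b = aggregate_gradients([grads[i] for i in order], [sizes[i] for i in order])
        assert np.allclose(a["w"], b["w"], atol=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            aggregate_gradients([self.g(1.0)], [1, 2])


class TestFcPartition:
    def test_identity_partition(self):
        p = partition_fc(10, 1)
        assert p.ranges == ((0, 10),)

    def test_even_split_of_4096(self):
        p = partition_fc(4096, 2)
        assert p.ranges == ((0, 2048), (2048, 4096))

    def test_more_workers_than_units_rejected(self):
        with pytest.raises(ValueError):
            partition_fc(3, 4)

    def test_forward_equals_unpartitioned(self, rng):
        x = rng.standard_normal((5, 32))
        w = rng.standard_normal((32, 12))
        b = rng.standard_normal(12)
        for k in (1, 2, 3, 5):
            out, _ = model_parallel_dense(x, w, b, partition_fc(12, k))
            assert np.allclose(out, x @ w + b, atol=1e-12)

    def test_backward_equals_unpartitioned(self, rng):
        x = rng.standard_normal((5, 8))
        w = rng.standard_normal((8, 6))
        b = rng.standard_normal(6)
        up = rng.standard_normal((5, 6))
        _, cache = model_parallel_dense(x, w, b, partition_fc(6, 3))
        dx, dw, db = model_parallel_dense_backward(up, cache)
        assert np.allclose(dw, x.T @ up, atol=1e-10)
        assert np.allclose(db, up.sum(axis=0), atol=1e-10)
        assert np.allclose(dx, up @ w.T, atol=1e-10)


@pytest.fixture
def training_setup(rng):
    spec = tiny_spec(input_size=16, channels=1, dropout_rate=0.25, widths=(4, 6))
    params = init_params(spec, seed=3)
    x = rng.random((8, 16, 16, 1))
    y = rng.integers(0, 3, 8)
    return spec, params, x, y


class TestSerialEquivalence:
    @pytest.mark.parametrize("k", [1, 2, 4])
    def test_data_parallel_step_matches_serial(self, training_setup, k):
        spec, params, x, y = training_setup
        ps, ls = serial_step(spec, params, x, y, make_optimizer("adam", 1e-3), 9)
        plan = make_shard_plan(8, k)
        pp, lp = data_parallel_step(
            spec, params, x, y, plan, make_optimizer("adam", 1e-3), 9
        )
        assert params_rel_diff(ps, pp) < 1e-6
        assert ls == pytest.approx(lp, abs=1e-12)

    def test_single_worker_bitwise_identical(self, training_setup):
        spec, params, x, y = training_setup
        ps, _ = serial_step(spec, params, x, y, make_optimizer("sgd", 0.1), 9)
        pp, _ = data_parallel_step(
            spec, params, x, y, make_shard_plan(8, 1), make_optimizer("sgd", 0.1), 9
        )
        assert all(np.array_equal(ps[k], pp[k]) for k in ps)

    def test_uneven_shards_match_serial(self, training_setup):
        spec, params, x, y = training_setup
        from gapcnn.parallel import ShardPlan

        plan = ShardPlan(
            k=4,
            n=8,
            shard_indices=(
                np.arange(0, 3),
                np.arange(3, 6),
                np.arange(6, 7),
                np.arange(7, 8),
            ),
        )
        ps, _ = serial_step(spec, params, x, y, make_optimizer("adam", 1e-3), 9)
        pp, _ = data_parallel_step(
            spec, params, x, y, plan, make_optimizer("adam", 1e-3), 9
        )
        assert params_rel_diff(ps, pp) < 1e-6

    @pytest.mark.parametrize("k", [1, 2, 4])
    def test_model_parallel_step_matches_serial(self, training_setup, k):
        spec, params, x, y = training_setup
        ps, _ = serial_step(spec, params, x, y, make_optimizer("adam", 1e-3), 9)
        pp, _ = model_parallel_step(spec, params, x, y, k, make_optimizer("adam", 1e-3), 9)
        assert params_rel_diff(ps, pp) < 1e-6

    @pytest.mark.parametrize("k", [1, 2, 4])
    @pytest.mark.parametrize("m,nfc", [(8, 8), (4, 8)])
    def test_hybrid_step_matches_serial(self, training_setup, k, m, nfc):
        spec, params, x, y = training_setup
        cfg = HybridConfig(k=k, conv_batch=m, fc_batch=nfc)
        ps, ls = serial_step(spec, params, x, y, make_optimizer("adam", 1e-3), 9)
        pp, lp = hybrid_step(spec, params, x, y, cfg, make_optimizer("adam", 1e-3), 9)
        assert params_rel_diff(ps, pp) < 1e-6
        assert ls == pytest.approx(lp, abs=1e-9)

    def test_micro_batch_accumulation_loss_matches_serial(self, training_setup):
        # conv micro-batches smaller than the fc batch: two conv batches
        # buffered before one dense pass
        spec, params, x, y = training_setup
        cfg = HybridConfig(k=2, conv_batch=4, fc_batch=8)
        _, ls = serial_step(spec, params, x, y, make_optimizer("sgd", 0.1), 9)
        _, lh = hybrid_step(spec, params, x, y, cfg, make_optimizer("sgd", 0.1), 9)
        assert lh == pytest.approx(ls, abs=1e-9)

    @pytest.mark.parametrize("mode_kwargs", [
        dict(kind="data", k=2), dict(kind="data", k=4),
        dict(kind="model", k=2),
        dict(kind="hybrid", k=2, m=8, nfc=8), dict(kind="hybrid", k=4, m=4, nfc=8),
    ])
    def test_three_step_training_stays_equivalent(self, training_setup, mode_kwargs):
        spec, params, x, y = training_setup
        opt_s = make_optimizer("adam", 1e-3)
        opt_p = make_optimizer("adam", 1e-3)
        ps = pp = params
        for step_i in range(3):
            ps, _ = serial_step(spec, ps, x, y, opt_s, 100 + step_i)
            kind = mode_kwargs["kind"]
            if kind == "data":
                plan = make_shard_plan(8, mode_kwargs["k"])
                pp, _ = data_parallel_step(spec, pp, x, y, plan, opt_p, 100 + step_i)
            elif kind == "model":
                pp, _ = model_parallel_step(spec, pp, x, y, mode_kwargs["k"], opt_p, 100 + step_i)
            else:
                cfg = HybridConfig(
                    k=mode_kwargs["k"],
                    conv_batch=mode_kwargs["m"],
                    fc_batch=mode_kwargs["nfc"],
                )
                pp, _ = hybrid_step(spec, pp, x, y, cfg, opt_p, 100 + step_i)
        assert params_rel_diff(ps, pp) < 1e-5
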