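"""Layer primitives: forward values on hand-computable cases and analytic
backward vs central finite differences."""

import numpy as np
import pytest

from gapcnn import layers as L

from conftest import central_diff, max_rel_err


class TestConv:
    def test_sum_of_ones_valid(self):
        x = np.ones((1, 3, 3, 1))
        w = np.ones((3, 3, 1, 1))
        b = np.array([0.25])
        out, _ = L.conv_forward(x, w, b, stride=1, padding="valid")
        assert out.shape == (1, 1, 1, 1)
        assert out[0, 0, 0, 0] == pytest.approx(9.25)

    def test_identity_kernel_same_padding(self, rng):
        x = rng.random((2, 5, 5, 1))
        w = np.zeros((3, 3, 1, 1))
        w[1, 1, 0, 0] = 1.0
        out, _ = L.conv_forward(x, w, np.zeros(1), stride=1, padding="same")
        assert np.allclose(out, x)

    def test_channel_mismatch_reports_both_shapes(self, rng):
        x = rng.random((1, 4, 4, 2))
        w = rng.random((3, 3, 3, 1))
        with pytest.raises(ValueError, match=r"\(1, 4, 4, 2\).*\(3, 3, 3, 1\)"):
            L.conv_forward(x, w, np.zeros(1))

    @pytest.mark.parametrize("stride,padding", [(1, "same"), (1, "valid"), (2, "same")])
    def test_backward_matches_finite_differences(self, rng, stride, padding):
        x = rng.standard_normal((2, 8, 8, 3))
        w = rng.standard_normal((3, 3, 3, 4)) * 0.3
        b = rng.standard_normal(4) * 0.1
        up = rng.standard_normal(
            L.conv_forward(x, w, b, stride, padding)[0].shape
        )

        def loss_of(x_, w_, b_):
            out, _ = L.conv_forward(x_, w_, b_, stride, padding)
            return float((out * up).sum())

        out, cache = L.conv_forward(x, w, b, stride, padding)
        dx, dw, db = L.conv_backward(up, cache)
        assert max_rel_err(dx, central_diff(lambda v: loss_of(v, w, b), x), 1e-5) < 1e-5
        assert max_rel_err(dw, central_diff(lambda v: loss_of(x, v, b), w), 1e-5) < 1e-5
        assert max_rel_err(db, central_diff(lambda v: loss_of(x, w, v), b), 1e-5) < 1e-5


class TestMaxPool:
    def test_single_window(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]]).reshape(1, 2, 2, 1)
        out, _ = L.maxpool_forward(x, 2, 2)
        assert out.reshape(()) == 4.0

    def test_constant_input_ties_to_first_index(self):
        x = np.full((1, 4, 4, 1), 7.0)
        out, cache = L.maxpool_forward(x, 2, 2)
        assert np.all(out == 7.0)
        dx = L.maxpool_backward(np.ones_like(out), cache)
        # gradient lands on the first (row-major) element of each window
        expect = np.zeros((4, 4))
        expect[::2, ::2] = 1.0
        assert np.array_equal(dx[0, :, :, 0], expect)

    def test_backward_matches_finite_differences(self, rng):
        # distinct values so the argmax is stable under the fd perturbation
        x = rng.permutation(64).astype(float).reshape(1, 8, 8, 1)
        out, cache = L.maxpool_forward(x, 3, 2)
        up = rng.standard_normal(out.shape)
        dx = L.maxpool_backward(up, cache)

        def loss_of(x_):
            o, _ = L.maxpool_forward(x_, 3, 2)
            return float((o * up).sum())

        assert max_rel_err(dx, central_diff(loss_of, x, h=1e-4), 1e-5) < 1e-5

    def test_oversized_window_rejected(self):
        with pytest.raises(ValueError, match="larger than"):
            L.maxpool_forward(np.ones((1, 2, 2, 1)), 5, 1, padding="valid")


class TestLRN:
    def test_radius_zero_collapses_to_formula(self, rng):
        x = rng.standard_normal((1, 3, 3, 1))
        out, _ = L.lrn_forward(x, depth_radius=0, k0=2.0, a=1e-2, b=0.75)
        assert np.allclose(out, x / (2.0 + 1e-2 * x**2) ** 0.75)

    def test_zero_input_zero_output(self):
        out, _ = L.lrn_forward(np.zeros((1, 2, 2, 5)))
        assert np.all(out == 0.0)

    def test_nonpositive_k0_rejected(self):
        with pytest.raises(ValueError):
            L.lrn_forward(np.ones((1, 2, 2, 1)), k0=0.0)

    def test_backward_matches_finite_differences(self, rng):
        x = rng.standard_normal((2, 3, 3, 6))
        out, cache = L.lrn_forward(x, depth_radius=2, k0=2.0, a=1e-2, b=0.75)
        up = rng.standard_normal(out.shape)
        dx = L.lrn_backward(up, cache)

        def loss_of(x_):
            o, _ = L.lrn_forward(x_, depth_radius=2, k0=2.0, a=1e-2, b=0.75)
            return float((o * up).sum())

        assert max_rel_err(dx, central_diff(loss_of, x, h=1e-5), 1e-5) < 1e-4


class TestGAP:
    def test_mean_of_known_map(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]]).reshape(1, 2, 2, 1)
        out, _ = L.gap_forward(x)
        assert out[0, 0] == 2.5

    def test_constant_map(self):
        x = np.full((3, 5, 7, 2), 0.4)
        out, _ = L.gap_forward(x)
        assert np.allclose(out, 0.4)

    def test_backward_matches_finite_differences(self, rng):
        x = rng.standard_normal((2, 3, 4, 2))
        out, shape = L.gap_forward(x)
        up = rng.standard_normal(out.shape)
        dx = L.gap_backward(up, shape)

        def loss_of(x_):
            o, _ = L.gap_forward(x_)
            return float((o * up).sum())

        assert max_rel_err(dx, central_diff(loss_of, x), 1e-6) < 1e-6


class TestDense:
    def test_backward_matches_finite_differences(self, rng):
        x = rng.standard_normal((4, 6))
        w = rng.standard_normal((6, 3))
        b = rng.standard_normal(3)
        out, cache = L.dense_forward(x, w, b)
        up = rng.standard_normal(out.shape)
        dx, dw, db = L.dense_backward(up, cache)
        assert max_rel_err(
            dw, central_diff(lambda v: float((L.dense_forward(x, v, b)[0] * up).sum()), w),
            1e-6,
        ) < 1e-6
        assert np.allclose(dx, up @ w.T)
        assert np.allclose(db, up.sum(axis=0))

    def test_flattens_4d_input(self, rng):
        x = rng.random((2, 3, 3, 2))
        w = rng.random((18, 5))
        out, _ = L.dense_forward(x, w, np.zeros(5))
        assert out.shape == (2, 5)


class TestDropout:
    def test_rate_zero_identity(self, rng):
        x = rng.random((10, 10))
        out, mask = L.dropout_apply(x, 0.0, True, 0)
        assert np.array_equal(out, x)
        assert np.all(mask == 1.0)

    def test_inference_identity(self, rng):
        x = rng.random((10, 10))
        out, _ = L.dropout_apply(x, 0.9, False, 0)
        assert np.array_equal(out, x)

    def test_half_rate_zeroes_half(self):
        x = np.ones(10**6)
        out, _ = L.dropout_apply(x, 0.5, True, 42)
        frac = float((out == 0).mean())
        assert abs(frac - 0.5) <= 0.002

    def test_survivors_rescaled_and_unbiased(self):
        x = np.ones(10**6)
        out, _ = L.dropout_apply(x, 0.25, True, 3)
        nz = out[out != 0]
        assert np.allclose(nz, 1.0 / 0.75)
        assert out.mean() == pytest.approx(1.0, abs=0.01)

    def test_fixed_seed_reproducible(self, rng):
        x = rng.random((50, 50))
        out1, m1 = L.dropout_apply(x, 0.5, True, 9)
        out2, m2 = L.dropout_apply(x, 0.5, True, 9)
        assert np.array_equal(m1, m2) and np.array_equal(out1, out2)

    def test_rate_one_rejected(self):
        with pytest.raises(ValueError):
            L.dropout_apply(np.ones(3), 1.0, True, 0)


class TestSoftmaxXent:
    def test_uniform_logits_loss_is_log3(self):
        loss, probs, _ = L.softmax_xent(np.zeros((5, 3)), np.array([0, 1, 2, 0, 1]))
        assert loss == pytest.approx(np.log(3.0), abs=1e-12)
        assert np.allclose(probs, 1.0 / 3.0)

    def test_dominant_logit_limit(self):
        logits = np.array([[500.0, 0.0, 0.0]])
        loss, probs, _ = L.softmax_xent(logits, np.array([0]))
        assert probs[0, 0] == pytest.approx(1.0)
        assert loss == pytest.approx(0.0, abs=1e-12)

    def test_rows_sum_to_one(self, rng):
        logits = rng.standard_normal((20, 3)) * 10
        _, probs, _ = L.softmax_xent(logits, rng.integers(0, 3, 20))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_label_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="labels"):
            L.softmax_xent(np.zeros((2, 3)), np.array([0, 3]))

    def test_gradient_matches_finite_differences(self, rng):
        logits = rng.standard_normal((4, 3))
        labels = rng.integers(0, 3, 4)
        _, _, dlogits = L.softmax_xent(logits, labels)
        fd = central_diff(lambda z: L.softmax_xent(z, labels)[0], logits)
        assert max_rel_err(dlogits, fd, 1e-6) < 1e-6
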