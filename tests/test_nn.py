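"""Gradient and mechanics checks for the numpy autodiff engine.

Every differentiable primitive is verified against central finite
differences on small tensors; float32 arithmetic limits the agreement, so
tolerances are loose but diagnostic (a wrong gradient is off by orders of
magnitude, not percent).
"""

import numpy as np
import pytest

from fpnseg.nn import Adam, BatchNorm2d, Conv2d, ConvBNReLU, Tensor
from fpnseg.nn import functional as F


def numeric_grad(fn, arr, eps=1e-2):
    """Central-difference gradient of scalar fn w.r.t. a float32 array."""
    g = np.zeros_like(arr, dtype=np.float64)
    flat = arr.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = fn()
        flat[i] = orig - eps
        lo = fn()
        flat[i] = orig
        g.reshape(-1)[i] = (hi - lo) / (2 * eps)
    return g


def weighted_sum(t: Tensor, w: np.ndarray) -> Tensor:
    """Scalar projection so any-shaped output reduces to one number."""
    val = float((t.data * w).sum())

    def backward(gy):
        t.accumulate(float(gy) * w)

    return Tensor(val, parents=(t,), backward=backward)


def check_op(op, shapes, seed=0, atol=2e-2, rtol=5e-2):
    rng = np.random.default_rng(seed)
    arrays = [rng.normal(0, 1, s).astype(np.float32) for s in shapes]
    tensors = [Tensor(a.copy(), requires_grad=True) for a in arrays]
    out = op(*tensors)
    w = rng.normal(0, 1, out.data.shape).astype(np.float32)
    loss = weighted_sum(out, w)
    loss.backward()
    for arr, t in zip(arrays, tensors):
        # numeric_grad perturbs `arr` in place; f() rebuilds the graph from
        # the (partially perturbed) arrays each call
        def f():
            ts = [Tensor(x) for x in arrays]
            return float((op(*ts).data * w).sum())

        num = numeric_grad(f, arr)
        assert t.grad is not None
        np.testing.assert_allclose(t.grad, num, atol=atol, rtol=rtol)


class TestPrimitiveGradients:
    def test_conv3x3(self):
        check_op(lambda x, w, b: F.conv2d(x, w, b, pad=1), [(2, 3, 5, 5), (4, 3, 3, 3), (4,)])

    def test_conv1x1(self):
        check_op(lambda x, w, b: F.conv2d(x, w, b, pad=0), [(2, 3, 4, 4), (2, 3, 1, 1), (2,)])

    def test_relu(self):
        check_op(F.relu, [(3, 2, 4, 4)], seed=3)

    def test_sigmoid(self):
        check_op(F.sigmoid, [(2, 1, 4, 4)])

    def test_maxpool(self):
        # well-separated values so finite differences cannot flip the argmax
        rng = np.random.default_rng(5)
        x = rng.permutation(64).astype(np.float32).reshape(1, 1, 8, 8)
        xt = Tensor(x.copy(), requires_grad=True)
        out = F.maxpool2x2(xt)
        w = rng.normal(0, 1, out.data.shape).astype(np.float32)
        weighted_sum(out, w).backward()
        num = numeric_grad(
            lambda: float((F.maxpool2x2(Tensor(x)).data * w).sum()), x, eps=0.25
        )
        np.testing.assert_allclose(xt.grad, num, atol=1e-3)

    def test_upsample_nearest(self):
        check_op(lambda x: F.upsample_nearest2d(x, 2), [(2, 3, 4, 4)])

    def test_upsample_bilinear(self):
        check_op(lambda x: F.upsample_bilinear2d(x, (7, 9)), [(2, 2, 4, 5)])

    def test_concat_and_add(self):
        check_op(lambda a, b: F.concat_channels([a, b]), [(2, 2, 3, 3), (2, 4, 3, 3)])
        check_op(F.add, [(2, 2, 3, 3), (2, 2, 3, 3)])

    def test_batchnorm_training_mode(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 2, (4, 3, 5, 5)).astype(np.float32)
        gamma = rng.normal(1, 0.2, 3).astype(np.float32)
        beta = rng.normal(0, 0.2, 3).astype(np.float32)

        def op(xt, gt, bt):
            return F.batchnorm2d(
                xt, gt, bt, np.zeros(3, np.float32), np.ones(3, np.float32), training=True
            )

        tensors = [Tensor(a.copy(), requires_grad=True) for a in (x, gamma, beta)]
        out = op(*tensors)
        w = rng.normal(0, 1, out.data.shape).astype(np.float32)
        weighted_sum(out, w).backward()
        for i, arr in enumerate((x, gamma, beta)):
            def f():
                ts = [Tensor(a) for a in (x, gamma, beta)]
                return float((op(*ts).data * w).sum())

            num = numeric_grad(f, arr)
            np.testing.assert_allclose(tensors[i].grad, num, atol=3e-2, rtol=8e-2)

    def test_soft_dice_loss_gradient(self):
        rng = np.random.default_rng(11)
        p = rng.random((2, 1, 6, 6)).astype(np.float32)
        g = (rng.random((2, 1, 6, 6)) < 0.3).astype(np.float32)
        for per_image in (False, True):
            pt = Tensor(p.copy(), requires_grad=True)
            loss = F.soft_dice_loss(pt, g, xi=5.0, per_image=per_image)
            loss.backward()
            num = numeric_grad(
                lambda: float(F.soft_dice_loss(Tensor(p), g, xi=5.0, per_image=per_image).data),
                p,
                eps=1e-2,
            )
            np.testing.assert_allclose(pt.grad, num, atol=1e-3, rtol=5e-2)

    def test_bce_loss_gradient(self):
        rng = np.random.default_rng(13)
        p = (0.2 + 0.6 * rng.random((1, 1, 5, 5))).astype(np.float32)
        g = (rng.random((1, 1, 5, 5)) < 0.5).astype(np.float32)
        pt = Tensor(p.copy(), requires_grad=True)
        F.bce_loss(pt, g).backward()
        num = numeric_grad(lambda: float(F.bce_loss(Tensor(p), g).data), p, eps=1e-3)
        np.testing.assert_allclose(pt.grad, num, atol=1e-2, rtol=5e-2)


class TestMechanics:
    def test_backward_through_composite_graph(self):
        rng = np.random.default_rng(0)
        block = ConvBNReLU(3, 4, rng)
        x = Tensor(rng.normal(0, 1, (2, 3, 8, 8)).astype(np.float32), requires_grad=True)
        out = F.soft_dice_loss(F.sigmoid(block(x)), np.zeros((2, 4, 8, 8), np.float32), xi=1.0)
        out.backward()
        for p in block.parameters():
            assert p.grad is not None and np.isfinite(p.grad).all()
        assert x.grad is not None and np.isfinite(x.grad).all()

    def test_adam_reduces_quadratic(self):
        w = Tensor(np.array([5.0, -3.0], np.float32), requires_grad=True)
        opt = Adam([w], lr=0.1)
        for _ in range(300):
            loss = weighted_sum(
                Tensor(w.data**2, parents=(w,), backward=lambda g: w.accumulate(2 * w.data * g)),
                np.ones(2, np.float32),
            )
            opt.zero_grad()
            loss.backward()
            opt.step()
        assert np.abs(w.data).max() < 0.1

    def test_batchnorm_running_stats_track_batch(self):
        rng = np.random.default_rng(2)
        bn = BatchNorm2d(2, momentum=0.5)
        x = rng.normal(3.0, 2.0, (8, 2, 6, 6)).astype(np.float32)
        for _ in range(30):
            bn(Tensor(x))
        np.testing.assert_allclose(bn.running_mean, x.mean(axis=(0, 2, 3)), atol=1e-3)

    def test_eval_mode_is_deterministic(self):
        rng = np.random.default_rng(4)
        conv = Conv2d(3, 2, 3, rng)
        x = Tensor(rng.normal(0, 1, (1, 3, 6, 6)).astype(np.float32))
        a = conv(x).data
        b = conv(x).data
        np.testing.assert_array_equal(a, b)

    def test_maxpool_rejects_odd_sizes(self):
        with pytest.raises(ValueError):
            F.maxpool2x2(Tensor(np.zeros((1, 1, 5, 6), np.float32)))
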