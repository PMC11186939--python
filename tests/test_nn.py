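"""Numerical verification of the neural-network backend.

Every layer's analytic gradient is checked against central finite
differences; the optimizer and loss have closed-form oracle checks.
"""

import numpy as np
import pytest

from neoecho import nn


def _fd_grad(f, x, eps=1e-5):
    """Central finite-difference gradient of scalar f at x."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        old = x[i]
        x[i] = old + eps
        fp = f()
        x[i] = old - eps
        fm = f()
        x[i] = old
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g


def _check_module(mod, x_shape, seed=0, tol=1e-6):
    """Compare input and parameter gradients to finite differences for the
    scalar loss 0.5·||module(x)||²."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, x_shape)

    def loss():
        y = mod(x)
        return 0.5 * float((y**2).sum())

    y = mod(x)
    gin = mod.backward(y.copy())
    gx = _fd_grad(loss, x)
    assert np.abs(gin - gx).max() < tol, "input gradient mismatch"

    for p in mod.parameters():
        p.zero_grad()
    y = mod(x)
    mod.backward(y.copy())
    for j, p in enumerate(mod.parameters()):
        gp = _fd_grad(loss, p.data)
        assert np.abs(p.grad - gp).max() < tol, f"parameter {j} gradient mismatch"


class TestLayerGradients:
    def test_conv3d(self):
        rng = np.random.default_rng(0)
        mod = nn.Conv3d(2, 3, (2, 3, 3), stride=(1, 2, 2), padding=(0, 1, 1), rng=rng, dtype=np.float64)
        _check_module(mod, (2, 2, 3, 6, 6))

    def test_conv3d_stride_one_no_pad(self):
        rng = np.random.default_rng(1)
        mod = nn.Conv3d(1, 2, (1, 2, 2), stride=1, padding=0, rng=rng, dtype=np.float64)
        _check_module(mod, (1, 1, 2, 5, 5))

    def test_batchnorm_train(self):
        mod = nn.BatchNorm(3, dtype=np.float64)
        mod.set_training(True)
        _check_module(mod, (4, 3, 2, 3, 3), tol=1e-5)

    def test_batchnorm_eval(self):
        mod = nn.BatchNorm(3, dtype=np.float64)
        mod.set_training(True)
        rng = np.random.default_rng(2)
        mod(rng.normal(0, 2, (4, 3, 2, 3, 3)))  # accumulate running stats
        mod.set_training(False)
        _check_module(mod, (2, 3, 2, 3, 3), seed=3)

    def test_relu(self):
        _check_module(nn.ReLU(), (2, 3, 2, 4, 4))

    def test_global_avg_pool(self):
        _check_module(nn.GlobalAvgPool(), (2, 3, 2, 4, 4))

    def test_linear(self):
        rng = np.random.default_rng(4)
        _check_module(nn.Linear(5, 3, rng=rng, dtype=np.float64), (4, 5))

    def test_sequential(self):
        rng = np.random.default_rng(5)
        mod = nn.Sequential(
            nn.Conv3d(1, 2, (1, 3, 3), stride=1, padding=(0, 1, 1), rng=rng, dtype=np.float64),
            nn.BatchNorm(2, dtype=np.float64),
            nn.ReLU(),
        )
        mod.set_training(True)
        _check_module(mod, (2, 1, 2, 4, 4), tol=1e-5)

    def test_residual_block(self):
        rng = np.random.default_rng(6)
        mod = nn.ResidualBlock3d(2, 3, stride=(1, 2, 2), rng=rng, dtype=np.float64)
        mod.set_training(True)
        _check_module(mod, (2, 2, 2, 4, 4), tol=1e-5)

    def test_residual_block_identity_shortcut(self):
        rng = np.random.default_rng(7)
        mod = nn.ResidualBlock3d(2, 2, stride=1, rng=rng, dtype=np.float64)
        mod.set_training(True)
        _check_module(mod, (2, 2, 2, 4, 4), tol=1e-5)


class TestShapes:
    def test_conv_output_shape(self):
        rng = np.random.default_rng(0)
        mod = nn.Conv3d(1, 4, (3, 5, 5), stride=(1, 2, 2), padding=(1, 2, 2), rng=rng, dtype=np.float64)
        y = mod(np.zeros((2, 1, 12, 32, 32)))
        assert y.shape == (2, 4, 12, 16, 16)

    def test_pool_and_linear(self):
        y = nn.GlobalAvgPool()(np.ones((2, 8, 3, 4, 4)))
        assert y.shape == (2, 8)
        assert np.allclose(y, 1.0)


class TestLossAndOptimizer:
    def test_softmax_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        p = nn.softmax(rng.normal(0, 5, (6, 3)))
        assert np.allclose(p.sum(axis=1), 1.0)
        assert (p > 0).all()
        # invariant to a per-row shift
        z = rng.normal(0, 3, (4, 3))
        assert np.allclose(nn.softmax(z), nn.softmax(z + 7.0))

    def test_cross_entropy_oracle(self):
        logits = np.log(np.array([[0.7, 0.2, 0.1]]))
        y = np.array([0])
        loss, grad = nn.softmax_cross_entropy(logits, y)
        assert loss == pytest.approx(-np.log(0.7), abs=1e-12)
        assert np.allclose(grad, (np.array([[0.7, 0.2, 0.1]]) - [[1, 0, 0]]) / 1)

    def test_cross_entropy_gradient_fd(self):
        rng = np.random.default_rng(1)
        z = rng.normal(0, 1, (3, 4))
        y = np.array([0, 2, 3])

        def loss():
            return nn.softmax_cross_entropy(z, y)[0]

        _, g = nn.softmax_cross_entropy(z, y)
        assert np.abs(g - _fd_grad(loss, z)).max() < 1e-7

    def test_adam_first_step_size(self):
        # with a constant gradient the first Adam step is ≈ -lr regardless
        # of gradient magnitude
        p = nn.Parameter(np.array([1.0]))
        opt = nn.Adam([p], lr=0.01, weight_decay=0.0)
        p.grad = np.array([123.0])
        opt.step()
        assert p.data[0] == pytest.approx(1.0 - 0.01, abs=1e-6)

    def test_adam_weight_decay_l2(self):
        # zero loss gradient: step reduces to decoupled-from-loss L2 pull
        p = nn.Parameter(np.array([2.0]), decay=True)
        q = nn.Parameter(np.array([2.0]), decay=False)
        opt = nn.Adam([p, q], lr=0.01, weight_decay=0.1)
        p.grad = np.array([0.0])
        q.grad = np.array([0.0])
        opt.step()
        assert p.data[0] < 2.0          # decayed
        assert q.data[0] == 2.0         # bias/BN parameters exempt

    def test_adam_minimizes_quadratic(self):
        p = nn.Parameter(np.array([5.0, -3.0]))
        opt = nn.Adam([p], lr=0.1, weight_decay=0.0)
        for _ in range(500):
            p.grad = 2 * p.data
            opt.step()
        assert np.abs(p.data).max() < 1e-2


class TestModel:
    def _model(self, seed=0):
        rng = np.random.default_rng(seed)
        stages = [
            ("stem", nn.Sequential(
                nn.Conv3d(1, 2, (1, 3, 3), stride=1, padding=(0, 1, 1), rng=rng, dtype=np.float64),
                nn.BatchNorm(2, dtype=np.float64), nn.ReLU())),
            ("gap", nn.GlobalAvgPool()),
            ("fc", nn.Linear(2, 3, rng=rng, dtype=np.float64)),
        ]
        return nn.Model(stages)

    def test_end_to_end_gradcheck(self):
        m = self._model()
        m.set_training(True)
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, (2, 1, 2, 4, 4))
        y = np.array([0, 2])

        def loss():
            return nn.softmax_cross_entropy(m(x), y)[0]

        for p in m.parameters():
            p.zero_grad()
        _, gl = nn.softmax_cross_entropy(m(x), y)
        m.backward(gl)
        for j, p in enumerate(m.parameters()):
            fd = _fd_grad(loss, p.data)
            assert np.abs(p.grad - fd).max() < 1e-5, f"param {j}"

    def test_capture_records_activation_and_gradient(self):
        m = self._model()
        m.set_training(False)
        m.capture("stem")
        x = np.random.default_rng(2).normal(0, 1, (1, 1, 2, 4, 4))
        out = m(x)
        m.backward(np.ones_like(out))
        assert m.activations["stem"].shape == (1, 2, 2, 4, 4)
        assert m.gradients["stem"].shape == (1, 2, 2, 4, 4)

    def test_parameters_found(self):
        # conv W(+b), BN gamma/beta, linear W/b
        assert len(self._model().parameters()) >= 5
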