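"""Contracts of the invertible layers: standardization, exact inverses,
and log-determinants validated against a brute-force Jacobian oracle."""

import numpy as np
import pytest

from conftest import numerical_jacobian_logdet
from volflow.autodiff import Tensor
from volflow.errors import (DegenerateChannelError, InitializationRequiredError,
                            NonInvertibleWeightError, NumericalOverflowError)
from volflow.layers import (ActNorm, AffineCoupling, FlowStep,
                            Invertible1x1Conv, random_rotation)
from volflow.phantom import PhantomSpec, make_dataset


# ---------------------------------------------------------------------------
# actnorm
# ---------------------------------------------------------------------------

class TestActNorm:
    def test_initialization_standardizes_known_moments(self):
        """A channel with mean 5, std 2 gets scale 0.5 and mean-0 output."""
        rng = np.random.default_rng(0)
        batch = 5.0 + 2.0 * rng.standard_normal((4096, 2, 2, 2, 1))
        layer = ActNorm(1, dtype=np.float64)
        layer.initialize(batch)
        np.testing.assert_allclose(layer.scale.data, 1 / batch.std(axis=(0, 1, 2, 3)))
        out = layer.forward(Tensor(batch)).output.data
        np.testing.assert_allclose(out.mean(), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.std(), 1.0, atol=1e-10)

    def test_already_standardized_batch_gives_identity(self, rng):
        batch = rng.standard_normal((64, 4, 4, 4, 2))
        batch = (batch - batch.mean(axis=(0, 1, 2, 3))) / batch.std(axis=(0, 1, 2, 3))
        layer = ActNorm(2, dtype=np.float64)
        layer.initialize(batch)
        np.testing.assert_allclose(layer.scale.data, 1.0, atol=1e-12)
        np.testing.assert_allclose(layer.bias.data, 0.0, atol=1e-12)

    def test_phantom_batch_standardized_within_tolerance(self):
        """Initialization on 64 noisy phantom VOIs standardizes to 1e-4."""
        vois = make_dataset(32, 32, PhantomSpec(shape=(8, 8, 8),
                                                polyp_radius_range=(1.5, 3.0),
                                                seed=3))
        batch = np.stack([v.volume for v in vois]).astype(np.float64)[..., None]
        layer = ActNorm(1, dtype=np.float64)
        layer.initialize(batch)
        out = layer.forward(Tensor(batch)).output.data
        assert abs(out.mean()) < 1e-4
        assert abs(out.std() - 1.0) < 1e-4

    def test_degenerate_channel_raises(self):
        layer = ActNorm(2)
        batch = np.zeros((4, 2, 2, 2, 2))
        batch[..., 0] = np.random.default_rng(0).standard_normal((4, 2, 2, 2))
        with pytest.raises(DegenerateChannelError):
            layer.initialize(batch)

    def test_uninitialized_forward_raises(self):
        layer = ActNorm(1)
        with pytest.raises(InitializationRequiredError):
            layer.forward(Tensor(np.zeros((1, 2, 2, 2, 1))))

    def test_logdet_closed_form_and_input_independence(self, rng):
        """scale=2 on a 2x2x2x1 volume: logdet = 8*log(2), for any input."""
        layer = ActNorm(1, dtype=np.float64)
        layer.scale.data = np.array([2.0])
        layer.bias.data = np.array([0.3])
        layer.initialized = True
        for _ in range(3):
            x = rng.standard_normal((1, 2, 2, 2, 1))
            res = layer.forward(Tensor(x))
            np.testing.assert_allclose(float(res.logdet.data), 8 * np.log(2.0))

    def test_inverse_round_trip(self, rng):
        layer = ActNorm(3, dtype=np.float32)
        layer.initialize(rng.standard_normal((8, 4, 4, 4, 3)).astype(np.float32))
        x = rng.standard_normal((2, 4, 4, 4, 3)).astype(np.float32)
        y = layer.forward(Tensor(x)).output.data
        np.testing.assert_allclose(layer.inverse(y), x, atol=1e-5)

    def test_constant_bias_inverse(self):
        layer = ActNorm(1, dtype=np.float64)
        layer.initialized = True
        layer.bias.data = np.array([3.0])
        y = np.full((1, 2, 2, 2, 1), 3.0)
        np.testing.assert_allclose(layer.inverse(y), 0.0, atol=1e-12)


# ---------------------------------------------------------------------------
# invertible 1x1x1 convolution
# ---------------------------------------------------------------------------

class TestInvertibleConv:
    def test_rotation_init_is_orthogonal_with_unit_det(self):
        w = random_rotation(8, np.random.default_rng(5))
        np.testing.assert_allclose(w.T @ w, np.eye(8), atol=1e-10)
        np.testing.assert_allclose(np.linalg.det(w), 1.0, atol=1e-10)

    def test_single_channel_init_is_plus_one(self):
        w = random_rotation(1, np.random.default_rng(0))
        np.testing.assert_allclose(w, [[1.0]])

    def test_seed_determinism(self):
        a = Invertible1x1Conv(6, np.random.default_rng(9)).weight.data
        b = Invertible1x1Conv(6, np.random.default_rng(9)).weight.data
        np.testing.assert_array_equal(a, b)

    def test_identity_weight_is_identity_map(self, rng):
        layer = Invertible1x1Conv(3, rng, dtype=np.float64)
        layer.weight.data = np.eye(3)
        x = rng.standard_normal((2, 2, 2, 2, 3))
        res = layer.forward(Tensor(x))
        np.testing.assert_allclose(res.output.data, x)
        np.testing.assert_allclose(float(res.logdet.data), 0.0, atol=1e-12)

    def test_diagonal_weight_logdet(self, rng):
        """W=diag(2,1) on 2x2x2x2: logdet = 8*log(2) (matches brute force)."""
        layer = Invertible1x1Conv(2, rng, dtype=np.float64)
        layer.weight.data = np.diag([2.0, 1.0])
        x = rng.standard_normal((1, 2, 2, 2, 2))
        res = layer.forward(Tensor(x))
        np.testing.assert_allclose(float(res.logdet.data), 8 * np.log(2.0))

        def fn(flat):
            out = layer.forward(Tensor(flat.reshape(1, 2, 2, 2, 2)))
            return out.output.data.ravel()

        np.testing.assert_allclose(
            numerical_jacobian_logdet(fn, x), 8 * np.log(2.0), atol=1e-6)

    def test_reverse_mode_initializes_to_channel_reversal(self, rng):
        layer = Invertible1x1Conv(4, rng, mode="reverse", dtype=np.float64)
        x = rng.standard_normal((1, 2, 2, 2, 4))
        out = layer.forward(Tensor(x)).output.data
        np.testing.assert_allclose(out, x[..., ::-1])

    def test_round_trip(self, rng):
        layer = Invertible1x1Conv(5, rng, dtype=np.float32)
        x = rng.standard_normal((2, 4, 4, 4, 5)).astype(np.float32)
        y = layer.forward(Tensor(x)).output.data
        np.testing.assert_allclose(layer.inverse(y), x, atol=1e-4)

    def test_singular_weight_raises(self, rng):
        layer = Invertible1x1Conv(2, rng, dtype=np.float64)
        layer.weight.data = np.ones((2, 2))
        with pytest.raises(NonInvertibleWeightError):
            layer.forward(Tensor(np.zeros((1, 2, 2, 2, 2))))


# ---------------------------------------------------------------------------
# affine coupling
# ---------------------------------------------------------------------------

class TestAffineCoupling:
    def test_zero_init_is_identity(self, rng):
        layer = AffineCoupling(4, hidden=6, rng=rng, dtype=np.float64)
        x = rng.standard_normal((2, 2, 2, 2, 4))
        res = layer.forward(Tensor(x))
        np.testing.assert_allclose(res.output.data, x)
        np.testing.assert_allclose(res.logdet.data, 0.0, atol=1e-12)

    def test_first_part_bit_identical(self, rng):
        layer = AffineCoupling(4, hidden=6, rng=rng, dtype=np.float64)
        layer.net.w3.data = 0.1 * rng.standard_normal(layer.net.w3.data.shape)
        x = rng.standard_normal((2, 2, 2, 2, 4))
        out = layer.forward(Tensor(x)).output.data
        assert np.array_equal(out[..., :2], x[..., :2])

    def test_constant_scale_doubles_second_part(self, rng):
        """s = log 2, t = 0: second part doubled, logdet = 8*log(2)."""
        layer = AffineCoupling(2, hidden=4, rng=rng,
                               scale_activation="identity", dtype=np.float64)
        layer.net.b3.data = np.array([np.log(2.0), 0.0])  # s=log2, t=0
        x = rng.standard_normal((1, 2, 2, 2, 2))
        res = layer.forward(Tensor(x))
        np.testing.assert_allclose(res.output.data[..., 1], 2 * x[..., 1])
        np.testing.assert_allclose(res.logdet.data, [8 * np.log(2.0)])
        # inverse halves it back
        np.testing.assert_allclose(layer.inverse(res.output.data), x, atol=1e-12)

    def test_logdet_matches_jacobian_oracle(self, rng):
        layer = AffineCoupling(2, hidden=4, rng=rng, dtype=np.float64)
        layer.net.w3.data = 0.2 * rng.standard_normal(layer.net.w3.data.shape)
        layer.net.b3.data = 0.1 * rng.standard_normal(2)
        x = rng.standard_normal((1, 2, 2, 2, 2))
        res = layer.forward(Tensor(x))

        def fn(flat):
            return layer.forward(Tensor(flat.reshape(1, 2, 2, 2, 2))).output.data.ravel()

        oracle = numerical_jacobian_logdet(fn, x)
        np.testing.assert_allclose(float(res.logdet.data[0]), oracle, atol=1e-3)

    def test_round_trip_with_random_nets(self, rng):
        layer = AffineCoupling(4, hidden=8, rng=rng, dtype=np.float32)
        layer.net.w3.data = (0.3 * rng.standard_normal(
            layer.net.w3.data.shape)).astype(np.float32)
        x = rng.standard_normal((2, 4, 4, 4, 4)).astype(np.float32)
        y = layer.forward(Tensor(x)).output.data
        np.testing.assert_allclose(layer.inverse(y), x, atol=1e-4)

    def test_non_finite_scale_raises(self, rng):
        layer = AffineCoupling(2, hidden=4, rng=rng, dtype=np.float64)
        layer.net.b3.data = np.array([np.nan, 0.0])
        with pytest.raises(NumericalOverflowError):
            layer.forward(Tensor(np.zeros((1, 2, 2, 2, 2))))


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

class TestFlowStep:
    def test_step_logdet_matches_composed_jacobian(self, rng):
        """Sum of layer logdets equals the composed map's brute-force logdet."""
        step = FlowStep(2, hidden=4, rng=rng, dtype=np.float64)
        step.coupling.net.w3.data = 0.2 * rng.standard_normal(
            step.coupling.net.w3.data.shape)
        batch = rng.standard_normal((16, 2, 2, 2, 2))
        step.actnorm.initialize(batch)
        x = rng.standard_normal((1, 2, 2, 2, 2))
        res = step.forward(Tensor(x))

        def fn(flat):
            return step.forward(Tensor(flat.reshape(1, 2, 2, 2, 2))).output.data.ravel()

        oracle = numerical_jacobian_logdet(fn, x)
        total = float(np.asarray(res.logdet.data).ravel()[0])
        np.testing.assert_allclose(total, oracle, atol=1e-3)

    def test_step_round_trip(self, rng):
        step = FlowStep(8, hidden=8, rng=rng, dtype=np.float32)
        batch = rng.standard_normal((8, 4, 4, 4, 8)).astype(np.float32)
        step.actnorm.initialize(batch)
        y = step.forward(Tensor(batch)).output.data
        np.testing.assert_allclose(step.inverse(y), batch, atol=1e-4)
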