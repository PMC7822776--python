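"""Shared fixtures and independent numerical oracles."""

import numpy as np
import pytest

from volflow.model import Glow3D, ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def numerical_jacobian_logdet(fn, x, eps=1e-5):
    """log|det| of the full Jacobian of ``fn`` by central differences.

    ``fn`` maps a flat float64 vector to a flat vector of the same size.
    Independent of any log-det bookkeeping inside the layers.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    n = x.size
    jac = np.empty((n, n))
    for i in range(n):
        xp, xm = x.copy(), x.copy()
        xp[i] += eps
        xm[i] -= eps
        jac[:, i] = (fn(xp) - fn(xm)) / (2 * eps)
    sign, logdet = np.linalg.slogdet(jac)
    assert sign != 0, "numerically singular Jacobian"
    return logdet


def make_gaussian_volumes(n, shape, seed):
    """Factorized Gaussian volumes with a period-2 mean/std pattern.

    The per-voxel mean and std depend only on the voxel's 2x2x2 parity
    offset, so the analytic differential entropy per dimension is the mean
    over the eight offsets of 0.5*ln(2*pi*e*sigma^2).  Returns
    ``(volumes (n, w, h, d, 1) float32, entropy_per_dim)``.
    """
    rng = np.random.default_rng(seed)
    mu = rng.uniform(-0.5, 0.5, size=(2, 2, 2))
    sigma = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=(2, 2, 2)))
    w, h, d = shape
    mean = np.tile(mu, (w // 2, h // 2, d // 2))
    std = np.tile(sigma, (w // 2, h // 2, d // 2))
    x = mean + std * rng.standard_normal((n,) + tuple(shape))
    entropy_per_dim = float(np.mean(0.5 * np.log(2 * np.pi * np.e * sigma ** 2)))
    return x[..., None].astype(np.float32), entropy_per_dim


@pytest.fixture
def tiny_model(rng):
    """Initialized float64 K=1, L=1 model on 2x2x2x1 volumes (8 dims)."""
    cfg = ModelConfig(input_shape=(2, 2, 2, 1), levels=1, steps_per_level=1,
                      hidden_width=4, seed=7, dtype="float64")
    model = Glow3D(cfg)
    batch = rng.standard_normal((32, 2, 2, 2, 1))
    model.initialize_actnorm(batch)
    return model, batch


@pytest.fixture
def small_model(rng):
    """Initialized float32 K=2, L=2 model on 8^3 volumes."""
    cfg = ModelConfig(input_shape=(8, 8, 8, 1), levels=2, steps_per_level=2,
                      hidden_width=8, seed=11)
    model = Glow3D(cfg)
    batch = rng.standard_normal((16, 8, 8, 8, 1)).astype(np.float32)
    model.initialize_actnorm(batch)
    return model, batch
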