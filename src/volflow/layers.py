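"""Invertible layers making up one flow step.

A flow step applies, in order: activation normalization (actnorm), an
invertible 1x1x1 convolution (a trainable channel-mixing matrix applied at
every voxel), and an affine coupling layer.  Each layer exposes

* ``forward(x) -> LayerResult`` on a batched tensor ``(N, w, h, d, c)``,
  returning the transformed tensor together with its per-sample
  log |det Jacobian| contribution, and
* ``inverse(y) -> ndarray``, the exact algebraic inverse on plain arrays.

The log-determinants are what make exact likelihood evaluation possible via
the change-of-variables formula: summed over layers they correct the base
(Gaussian) density for the volume change of the learned bijection.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from . import autodiff as ad
from .autodiff import Module, Parameter, Tensor
from .errors import (
    DegenerateChannelError,
    InitializationRequiredError,
    NonInvertibleWeightError,
    NumericalOverflowError,
)

_SINGULAR_DET_THRESHOLD = 1e-12


class LayerResult(NamedTuple):
    """Output of a layer's forward pass."""

    output: Tensor
    logdet: Tensor  # scalar or per-sample (N,)


def random_rotation(c: int, rng: np.random.Generator) -> np.ndarray:
    """A uniformly random rotation matrix (orthogonal, det = +1)."""
    if c == 1:
        return np.ones((1, 1))
    q, r = np.linalg.qr(rng.standard_normal((c, c)))
    # fix the QR sign ambiguity, then force det = +1
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


class ActNorm(Module):
    """Per-channel affine layer with data-dependent initialization.

    Scale and bias are set from the first mini-batch so that each channel of
    the transformed batch has mean 0 and standard deviation 1; thereafter both
    are ordinary trainable parameters.
    """

    def __init__(self, channels: int, dtype=np.float32):
        self.scale = Parameter(np.ones(channels, dtype=dtype))
        self.bias = Parameter(np.zeros(channels, dtype=dtype))
        self.initialized = False

    def initialize(self, batch: np.ndarray) -> None:
        """Data-dependent init on a batch shaped (N, w, h, d, c)."""
        if batch.size == 0:
            raise ValueError("empty initialization batch")
        mean = batch.mean(axis=(0, 1, 2, 3))
        std = batch.std(axis=(0, 1, 2, 3))
        if np.any(std == 0):
            bad = np.flatnonzero(std == 0).tolist()
            raise DegenerateChannelError(
                f"constant input channel(s) {bad}: zero standard deviation")
        dtype = self.scale.data.dtype
        self.scale.data = (1.0 / std).astype(dtype)
        self.bias.data = (-mean / std).astype(dtype)
        self.initialized = True

    def forward(self, x: Tensor) -> LayerResult:
        if not self.initialized:
            raise InitializationRequiredError(
                "actnorm applied before data-dependent initialization")
        y = x * self.scale + self.bias
        spatial = float(np.prod(x.shape[1:4]))
        logdet = spatial * ad.tsum(ad.log_abs(self.scale))
        return LayerResult(y, logdet)

    def inverse(self, y: np.ndarray) -> np.ndarray:
        if not self.initialized:
            raise InitializationRequiredError(
                "actnorm applied before data-dependent initialization")
        return (y - self.bias.data) / self.scale.data


class Invertible1x1Conv(Module):
    """Trainable channel-mixing linear map applied at every voxel.

    ``mode='rotation'`` initializes the weight as a random rotation (log-det
    exactly 0 at init); ``mode='reverse'`` initializes it as the fixed
    channel-reversal permutation.  Either way the matrix trains freely.
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 mode: str = "rotation", dtype=np.float32):
        if mode == "rotation":
            w = random_rotation(channels, rng)
        elif mode == "reverse":
            w = np.eye(channels)[::-1].copy()
        else:
            raise ValueError(f"unknown invconv mode {mode!r}")
        self.weight = Parameter(w.astype(dtype))

    def _check_invertible(self) -> None:
        det = np.linalg.det(self.weight.data.astype(np.float64))
        if abs(det) < _SINGULAR_DET_THRESHOLD:
            raise NonInvertibleWeightError(
                f"|det W| = {abs(det):.3e} below invertibility threshold")

    def forward(self, x: Tensor) -> LayerResult:
        if x.shape[-1] != self.weight.data.shape[0]:
            raise ValueError("channel count does not match weight matrix")
        self._check_invertible()
        y = ad.linear(x, ad.transpose(self.weight, (1, 0)))
        spatial = float(np.prod(x.shape[1:4]))
        logdet = spatial * ad.slogdet_abs(self.weight)
        return LayerResult(y, logdet)

    def inverse(self, y: np.ndarray) -> np.ndarray:
        self._check_invertible()
        w_inv = np.linalg.inv(self.weight.data.astype(np.float64))
        return (y @ w_inv.T).astype(y.dtype)


class CouplingNet(Module):
    """Small 3D convolutional network producing coupling scale and shift.

    Three convolutions (kernel 3, 1, 3) with ReLU in between; the last layer
    is zero-initialized so the coupling starts as the identity map.
    """

    def __init__(self, c_in: int, c_out: int, hidden: int,
                 rng: np.random.Generator, dtype=np.float32):
        def w(shape):
            return Parameter((0.05 * rng.standard_normal(shape)).astype(dtype))

        self.w1 = w((3, 3, 3, c_in, hidden))
        self.b1 = Parameter(np.zeros(hidden, dtype=dtype))
        self.w2 = w((1, 1, 1, hidden, hidden))
        self.b2 = Parameter(np.zeros(hidden, dtype=dtype))
        self.w3 = Parameter(np.zeros((3, 3, 3, hidden, c_out), dtype=dtype))
        self.b3 = Parameter(np.zeros(c_out, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        h = ad.relu(ad.conv3d(x, self.w1, self.b1))
        h = ad.relu(ad.conv3d(h, self.w2, self.b2))
        return ad.conv3d(h, self.w3, self.b3)


class AffineCoupling(Module):
    """Affine coupling layer.

    Channels 1..d pass through unchanged; channels d+1..D are scaled and
    shifted elementwise by functions of the first part:

        y2 = x2 * exp(s(x1)) + t(x1)

    with per-sample log-det = sum of the s field.  The split index is
    d = floor(c/2) along channels.  ``scale_activation='tanh'`` bounds s to
    (-s_cap, s_cap) via ``s = s_cap * tanh(raw / s_cap)`` — the raw affine
    form is recovered in the small-s limit — which prevents exp overflow
    during training; ``'identity'`` uses raw s.
    """

    def __init__(self, channels: int, hidden: int, rng: np.random.Generator,
                 s_cap: float = 2.0, scale_activation: str = "tanh",
                 dtype=np.float32):
        if channels < 2:
            raise ValueError("coupling requires at least 2 channels")
        if scale_activation not in ("tanh", "identity"):
            raise ValueError(f"unknown scale_activation {scale_activation!r}")
        self.channels = channels
        self.d = channels // 2
        self.s_cap = float(s_cap)
        self.scale_activation = scale_activation
        self.net = CouplingNet(self.d, 2 * (channels - self.d), hidden, rng,
                               dtype=dtype)

    def _scale_shift(self, x1: Tensor) -> tuple[Tensor, Tensor]:
        h = self.net.forward(x1)
        half = self.channels - self.d
        s_raw = ad.narrow(h, 0, half)
        t = ad.narrow(h, half, 2 * half)
        if self.scale_activation == "tanh":
            s = self.s_cap * ad.tanh(s_raw * (1.0 / self.s_cap))
        else:
            s = s_raw
        return s, t

    def forward(self, x: Tensor) -> LayerResult:
        x1 = ad.narrow(x, 0, self.d)
        x2 = ad.narrow(x, self.d, self.channels)
        s, t = self._scale_shift(x1)
        if not np.all(np.isfinite(s.data)) or not np.all(np.isfinite(t.data)):
            raise NumericalOverflowError("coupling network produced non-finite values")
        y2 = x2 * ad.exp(s) + t
        y = ad.concat([x1, y2])
        logdet = ad.tsum(s, axis=(1, 2, 3, 4))
        return LayerResult(y, logdet)

    def inverse(self, y: np.ndarray) -> np.ndarray:
        y1 = y[..., : self.d]
        y2 = y[..., self.d:]
        with ad.no_grad():
            s, t = self._scale_shift(Tensor(y1))
        if not np.all(np.isfinite(s.data)) or not np.all(np.isfinite(t.data)):
            raise NumericalOverflowError("coupling network produced non-finite values")
        x2 = (y2 - t.data) * np.exp(-s.data)
        return np.concatenate([y1, x2], axis=-1).astype(y.dtype)


class FlowStep(Module):
    """One step of flow: actnorm -> invertible 1x1x1 conv -> affine coupling."""

    def __init__(self, channels: int, hidden: int, rng: np.random.Generator,
                 invconv_mode: str = "rotation", s_cap: float = 2.0,
                 scale_activation: str = "tanh", dtype=np.float32):
        self.actnorm = ActNorm(channels, dtype=dtype)
        self.invconv = Invertible1x1Conv(channels, rng, mode=invconv_mode,
                                         dtype=dtype)
        self.coupling = AffineCoupling(channels, hidden, rng, s_cap=s_cap,
                                       scale_activation=scale_activation,
                                       dtype=dtype)

    def forward(self, x: Tensor, init_actnorm: bool = False) -> LayerResult:
        if init_actnorm and not self.actnorm.initialized:
            self.actnorm.initialize(x.data)
        r1 = self.actnorm.forward(x)
        r2 = self.invconv.forward(r1.output)
        r3 = self.coupling.forward(r2.output)
        return LayerResult(r3.output, r1.logdet + r2.logdet + r3.logdet)

    def inverse(self, y: np.ndarray) -> np.ndarray:
        x = self.coupling.inverse(y)
        x = self.invconv.inverse(x)
        return self.actnorm.inverse(x)
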