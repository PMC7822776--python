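"""Multi-scale invertible flow over 3D volumes.

The model is a 3D Glow-style architecture: ``K`` levels, each consisting of a
Squeeze (trading a 2x2x2 spatial block for 8 channels), ``L`` flow steps
(actnorm, invertible 1x1x1 convolution, affine coupling), and — at every level
but the last — a Split that factors half the channels out to the Gaussian
prior.  The result is a hierarchical latent code whose total dimensionality
equals that of the input volume, and an exact log-likelihood

    log p(x) = log p_prior(z) + sum of per-layer log |det Jacobian|.

Volumes are channel-last: a single volume is ``(w, h, d, c)``, batches are
``(N, w, h, d, c)``.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Module, Parameter, Tensor
from .errors import ShapeError
from .layers import FlowStep

_LOG_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# squeeze / unsqueeze
# ---------------------------------------------------------------------------

def _squeeze_t(x: Tensor) -> Tensor:
    n, w, h, d, c = x.shape
    if w % 2 or h % 2 or d % 2:
        raise ShapeError(f"squeeze needs even spatial dims, got {(w, h, d)}")
    x = ad.reshape(x, (n, w // 2, 2, h // 2, 2, d // 2, 2, c))
    x = ad.transpose(x, (0, 1, 3, 5, 2, 4, 6, 7))
    return ad.reshape(x, (n, w // 2, h // 2, d // 2, 8 * c))


def _unsqueeze_t(x: Tensor) -> Tensor:
    n, w, h, d, c = x.shape
    if c % 8:
        raise ShapeError(f"unsqueeze needs channels divisible by 8, got {c}")
    x = ad.reshape(x, (n, w, h, d, 2, 2, 2, c // 8))
    x = ad.transpose(x, (0, 1, 4, 2, 5, 3, 6, 7))
    return ad.reshape(x, (n, 2 * w, 2 * h, 2 * d, c // 8))


def _apply_np(fn, x: np.ndarray) -> np.ndarray:
    if x.ndim == 4:
        return fn(Tensor(x[None])).data[0]
    if x.ndim == 5:
        return fn(Tensor(x)).data
    raise ShapeError(f"expected 4D volume or 5D batch, got ndim={x.ndim}")


def squeeze(x: np.ndarray) -> np.ndarray:
    """Rearrange ``(w, h, d, c)`` into ``(w/2, h/2, d/2, 8c)``.

    Each 2x2x2 spatial block becomes 8 channels; output channel index is
    ``((i*2 + j)*2 + k)*c + ch`` for block offset ``(i, j, k)``.  A pure
    permutation of elements: the Jacobian log-determinant is 0.
    """
    return _apply_np(_squeeze_t, x)


def unsqueeze(x: np.ndarray) -> np.ndarray:
    """Exact inverse rearrangement of :func:`squeeze`."""
    return _apply_np(_unsqueeze_t, x)


# ---------------------------------------------------------------------------
# Gaussian priors
# ---------------------------------------------------------------------------

def _gaussian_logp(z: Tensor, mean, logsd) -> Tensor:
    """Per-sample Gaussian log density, summed over non-batch axes."""
    u = (z - mean) * ad.exp(-1.0 * logsd)
    terms = -0.5 * _LOG_2PI - logsd - 0.5 * ad.square(u)
    axes = tuple(range(1, len(z.shape)))
    return ad.tsum(terms, axis=axes)


class Split(Module):
    """Channel split factoring half the channels out to a Gaussian prior.

    With ``conditional=True`` the prior mean/log-std of the factored half are
    produced from the retained half by a zero-initialized 3D convolution, so
    at initialization the prior is exactly standard normal.
    """

    def __init__(self, channels: int, conditional: bool, dtype=np.float32):
        if channels % 2:
            raise ShapeError(f"split needs an even channel count, got {channels}")
        self.half = channels // 2
        self.conditional = conditional
        if conditional:
            self.w = Parameter(np.zeros((3, 3, 3, self.half, channels), dtype=dtype))
            self.b = Parameter(np.zeros(channels, dtype=dtype))

    def _prior(self, retained: Tensor) -> tuple:
        if self.conditional:
            h = ad.conv3d(retained, self.w, self.b)
            return ad.narrow(h, 0, self.half), ad.narrow(h, self.half, 2 * self.half)
        zero = np.zeros(1, dtype=retained.data.dtype)
        return Tensor(zero), Tensor(zero)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        retained = ad.narrow(x, 0, self.half)
        factored = ad.narrow(x, self.half, 2 * self.half)
        mean, logsd = self._prior(retained)
        return retained, factored, _gaussian_logp(factored, mean, logsd)

    def sample(self, retained: np.ndarray, temperature: float,
               rng: np.random.Generator) -> np.ndarray:
        with ad.no_grad():
            mean, logsd = self._prior(Tensor(retained))
        shape = retained.shape[:-1] + (self.half,)
        eps = rng.standard_normal(shape).astype(retained.dtype)
        mean = np.broadcast_to(mean.data, shape)
        sd = np.broadcast_to(np.exp(logsd.data), shape)
        return mean + temperature * sd * eps


class FinalPrior(Module):
    """Prior over the last level's output: learned or standard Gaussian."""

    def __init__(self, shape: tuple, learned: bool, dtype=np.float32):
        self.shape = tuple(shape)
        self.learned = learned
        if learned:
            self.mean = Parameter(np.zeros(shape, dtype=dtype))
            self.logsd = Parameter(np.zeros(shape, dtype=dtype))

    def logp(self, z: Tensor) -> Tensor:
        if self.learned:
            return _gaussian_logp(z, self.mean, self.logsd)
        zero = np.zeros(1, dtype=z.data.dtype)
        return _gaussian_logp(z, Tensor(zero), Tensor(zero))

    def sample(self, n: int, temperature: float,
               rng: np.random.Generator, dtype) -> np.ndarray:
        eps = rng.standard_normal((n,) + self.shape).astype(dtype)
        if self.learned:
            return self.mean.data + temperature * np.exp(self.logsd.data) * eps
        return temperature * eps


# ---------------------------------------------------------------------------
# config / results
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``input_shape`` is ``(w, h, d, c)``; spatial dims must be divisible by
    ``2**levels``.  ``prior`` is ``'conditional'`` (learned Gaussian, zero
    initialized to standard normal) or ``'standard'``.  ``invconv`` selects
    the 1x1x1 convolution init: ``'rotation'`` (random rotation matrix) or
    ``'reverse'`` (channel-reversal permutation).
    """

    input_shape: tuple = (32, 32, 32, 1)
    levels: int = 3
    steps_per_level: int = 4
    hidden_width: int = 64
    prior: str = "conditional"
    invconv: str = "rotation"
    scale_activation: str = "tanh"
    s_cap: float = 2.0
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self):
        self.input_shape = tuple(int(v) for v in self.input_shape)
        if len(self.input_shape) != 4:
            raise ShapeError("input_shape must be (w, h, d, c)")
        if self.levels < 1 or self.steps_per_level < 1:
            raise ValueError("levels and steps_per_level must be >= 1")
        w, h, d, _ = self.input_shape
        f = 2 ** self.levels
        if w % f or h % f or d % f:
            raise ShapeError(
                f"spatial dims {self.input_shape[:3]} not divisible by 2^K={f}")
        if self.prior not in ("conditional", "standard"):
            raise ValueError(f"unknown prior {self.prior!r}")

    @property
    def n_dims(self) -> int:
        return int(np.prod(self.input_shape))

    def to_dict(self) -> dict:
        return {
            "input_shape": list(self.input_shape), "levels": self.levels,
            "steps_per_level": self.steps_per_level,
            "hidden_width": self.hidden_width, "prior": self.prior,
            "invconv": self.invconv, "scale_activation": self.scale_activation,
            "s_cap": self.s_cap, "seed": self.seed, "dtype": self.dtype,
        }


@dataclass
class LatentCode:
    """Hierarchical latent: one array per Split plus the final level."""

    parts: list = field(default_factory=list)

    @property
    def n_elements(self) -> int:
        return int(sum(p.size for p in self.parts))

    @property
    def shapes(self) -> list:
        return [p.shape for p in self.parts]

    def copy(self) -> "LatentCode":
        return LatentCode([p.copy() for p in self.parts])


@dataclass
class DensityResult:
    """Exact-likelihood evaluation of one volume."""

    latent: LatentCode
    logdet: float
    prior_logp: float
    log_likelihood: float
    bits_per_dim: float


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class Glow3D(Module):
    """K-level, L-step invertible flow with exact likelihood."""

    def __init__(self, config: ModelConfig):
        self.config = config
        dtype = np.dtype(config.dtype).type
        self.dtype = dtype
        rng = np.random.default_rng(config.seed)
        w, h, d, c = config.input_shape
        self.flows: list[list[FlowStep]] = []
        self.splits: list[Split] = []
        self._flow_steps_flat: list[FlowStep] = []   # for Module.parameters()
        for k in range(config.levels):
            w, h, d, c = w // 2, h // 2, d // 2, 8 * c
            steps = [
                FlowStep(c, config.hidden_width, rng,
                         invconv_mode=config.invconv, s_cap=config.s_cap,
                         scale_activation=config.scale_activation, dtype=dtype)
                for _ in range(config.steps_per_level)
            ]
            self.flows.append(steps)
            self._flow_steps_flat.extend(steps)
            if k < config.levels - 1:
                self.splits.append(Split(c, config.prior == "conditional",
                                         dtype=dtype))
                c //= 2
        self.final_prior = FinalPrior((w, h, d, c),
                                      learned=config.prior == "conditional",
                                      dtype=dtype)

    # -- bookkeeping -------------------------------------------------------
    @property
    def latent_shapes(self) -> list:
        shapes = []
        w, h, d, c = self.config.input_shape
        for k in range(self.config.levels):
            w, h, d, c = w // 2, h // 2, d // 2, 8 * c
            if k < self.config.levels - 1:
                c //= 2
                shapes.append((w, h, d, c))
        shapes.append(self.final_prior.shape)
        return shapes

    @property
    def actnorm_initialized(self) -> bool:
        return all(s.actnorm.initialized for s in self._flow_steps_flat)

    def _check_input(self, x: np.ndarray) -> None:
        if x.shape[-4:] != self.config.input_shape:
            raise ShapeError(
                f"volume shape {x.shape} does not match model input "
                f"{self.config.input_shape}")

    # -- core passes -------------------------------------------------------
    def _forward(self, x: Tensor, init_actnorm: bool = False):
        """Batched forward: returns (latent part Tensors, prior logp, logdet)."""
        n = x.shape[0]
        zero = np.zeros(n, dtype=x.data.dtype)
        logdet, logp = Tensor(zero), Tensor(zero)
        h_t = x
        parts = []
        for k in range(self.config.levels):
            h_t = _squeeze_t(h_t)
            for step in self.flows[k]:
                res = step.forward(h_t, init_actnorm=init_actnorm)
                h_t, logdet = res.output, logdet + res.logdet
            if k < self.config.levels - 1:
                h_t, factored, lp = self.splits[k].forward(h_t)
                parts.append(factored)
                logp = logp + lp
        parts.append(h_t)
        logp = logp + self.final_prior.logp(h_t)
        return parts, logp, logdet

    def initialize_actnorm(self, batch: np.ndarray) -> None:
        """Data-dependent actnorm init on a batch (run exactly once)."""
        self._check_input(batch)
        with ad.no_grad():
            self._forward(Tensor(batch.astype(self.dtype)), init_actnorm=True)

    def encode_batch(self, x: np.ndarray):
        """Encode a batch; returns (list of part arrays, prior_logp, logdet)."""
        self._check_input(x)
        with ad.no_grad():
            parts, logp, logdet = self._forward(Tensor(x.astype(self.dtype)))
        return [p.data for p in parts], logp.data, logdet.data

    def decode_batch(self, parts: Sequence[np.ndarray]) -> np.ndarray:
        expected = self.latent_shapes
        if len(parts) != len(expected):
            raise ShapeError(f"latent has {len(parts)} parts, expected {len(expected)}")
        for p, s in zip(parts, expected):
            if p.shape[-4:] != s:
                raise ShapeError(f"latent part shape {p.shape} != expected {s}")
        h = np.asarray(parts[-1], dtype=self.dtype)
        for k in reversed(range(self.config.levels)):
            if k < self.config.levels - 1:
                h = np.concatenate(
                    [h, np.asarray(parts[k], dtype=self.dtype)], axis=-1)
            for step in reversed(self.flows[k]):
                h = step.inverse(h)
            h = unsqueeze(h)
        return h

    # -- public single-volume API -------------------------------------------
    def encode(self, x: np.ndarray) -> DensityResult:
        """Map one volume to its latent code and exact log-likelihood."""
        x = np.asarray(x)
        single = x.ndim == 4
        parts, logp, logdet = self.encode_batch(x[None] if single else x)
        lp, ld = float(logp[0]), float(logdet[0])
        ll = lp + ld
        bpd = -ll / (self.config.n_dims * np.log(2.0))
        return DensityResult(LatentCode([p[0] for p in parts]), ld, lp, ll, bpd)

    def decode(self, latent: LatentCode) -> np.ndarray:
        """Exact inverse of :meth:`encode` (up to float roundoff)."""
        return self.decode_batch([p[None] for p in latent.parts])[0]

    def log_likelihood(self, x: np.ndarray) -> DensityResult:
        """Alias of :meth:`encode`; the latent comes along for free."""
        return self.encode(x)

    def sample(self, temperature: float = 1.0,
               rng: np.random.Generator | None = None,
               n: int = 1) -> np.ndarray:
        """Draw volumes from the model (temperature 0 = prior-mean decode)."""
        if temperature < 0:
            raise ValueError("temperature must be >= 0")
        rng = np.random.default_rng() if rng is None else rng
        h = self.final_prior.sample(n, temperature, rng, self.dtype)
        for k in reversed(range(self.config.levels)):
            if k < self.config.levels - 1:
                factored = self.splits[k].sample(h, temperature, rng)
                h = np.concatenate([h, factored], axis=-1)
            for step in reversed(self.flows[k]):
                h = step.inverse(h)
            h = unsqueeze(h)
        return h[0] if n == 1 else h

    # -- persistence ---------------------------------------------------------
    def _actnorms(self):
        return [s.actnorm for s in self._flow_steps_flat]

    def save(self, path) -> None:
        """Single-file checkpoint: config JSON + parameters + actnorm flags."""
        arrays = {f"param_{i:04d}": p.data for i, p in enumerate(self.parameters())}
        arrays["actnorm_initialized"] = np.array(
            [a.initialized for a in self._actnorms()], dtype=np.uint8)
        arrays["config_json"] = np.frombuffer(
            json.dumps(self.config.to_dict()).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "Glow3D":
        with np.load(path) as data:
            cfg = ModelConfig(**json.loads(bytes(data["config_json"]).decode()))
            model = cls(cfg)
            params = model.parameters()
            for i, p in enumerate(params):
                loaded = data[f"param_{i:04d}"]
                if loaded.shape != p.data.shape:
                    raise ShapeError("checkpoint parameter shape mismatch")
                p.data = loaded
            for a, flag in zip(model._actnorms(), data["actnorm_initialized"]):
                a.initialized = bool(flag)
        return model
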