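"""Preprocessing, the negative-log-likelihood objective, and the training loop.

CT volumes arrive as quantized integer intensities (HU).  For continuous
density modeling they are clamped to an intensity window, affinely mapped to
``[-1, 1]``, and uniformly dequantized (noise of one quantization step wide,
mapped through the same affine scale).  The constant log-Jacobian of the
affine map is returned so that likelihoods can be reported in raw-intensity
units (bits per dim of the original HU data, the standard convention for
density models of quantized data).

Training minimizes the mean negative log-likelihood over the dataset with
Adam, linear learning-rate warmup, and global-norm gradient clipping.  A
fixed seed makes the whole run reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .errors import NumericalOverflowError, TrainingDivergedError
from .model import Glow3D, ModelConfig

_LN2 = float(np.log(2.0))


@dataclass
class PreprocessSpec:
    """Raw-intensity window and dequantization settings.

    ``intensity_window`` default (-1024, 1023) HU covers air through bone;
    ``quantization_step`` is the granularity of the raw data (1 HU for CT).
    """

    intensity_window: tuple = (-1024.0, 1023.0)
    quantization_step: float = 1.0
    dequantize: bool = True

    def __post_init__(self):
        low, high = self.intensity_window
        if not low < high:
            raise ValueError("intensity window must satisfy low < high")
        if self.quantization_step <= 0:
            raise ValueError("quantization_step must be positive")

    @property
    def scale(self) -> float:
        """d(model units)/d(raw units) of the affine map."""
        low, high = self.intensity_window
        return 2.0 / (high - low)


def preprocess(raw: np.ndarray, spec: PreprocessSpec,
               rng: np.random.Generator | None = None):
    """Map raw-intensity volume(s) to model space ``[-1, 1]``.

    Returns ``(volume, logdet_correction)`` where the correction is the
    per-volume log-Jacobian ``n * log(2 / (high - low))`` of the affine map,
    to be added to model-space log-likelihoods to express them per raw unit.
    """
    raw = np.asarray(raw, dtype=np.float64)
    low, high = spec.intensity_window
    x = np.clip(raw, low, high)
    if spec.dequantize:
        if rng is None:
            rng = np.random.default_rng()
        x = x + spec.quantization_step * rng.uniform(size=x.shape)
    y = (x - low) * spec.scale - 1.0
    n = int(np.prod(raw.shape[-4:])) if raw.ndim >= 4 else raw.size
    logdet_correction = n * float(np.log(spec.scale))
    return y.astype(np.float32), logdet_correction


def unpreprocess(y: np.ndarray, spec: PreprocessSpec) -> np.ndarray:
    """Affine map back from model space to raw intensity units."""
    low, high = spec.intensity_window
    return (np.asarray(y) + 1.0) / spec.scale + low


def bits_per_dim(result, preprocess_logdet: float = 0.0) -> float:
    """Negative log2-likelihood per dimension, in raw-intensity units.

    ``preprocess_logdet`` is the affine correction returned by
    :func:`preprocess` (0 if the data was already in model space).
    """
    n = result.latent.n_elements
    return -(result.log_likelihood + preprocess_logdet) / (n * _LN2)


def _batch_tensor(batch) -> np.ndarray:
    arr = np.asarray(batch, dtype=np.float32)
    if arr.ndim == 4:
        arr = arr[None]
    return arr


def nll_loss(batch: Sequence[np.ndarray], model: Glow3D) -> float:
    """Mean negative log-likelihood (nats/volume) of a batch, no gradients."""
    arr = _batch_tensor(batch)
    with ad.no_grad():
        loss = _nll(Tensor(arr), model)
    return float(loss.data)


def _nll(x: Tensor, model: Glow3D, init_actnorm: bool = False) -> Tensor:
    _, logp, logdet = model._forward(x, init_actnorm=init_actnorm)
    return -1.0 * ad.tmean(logp + logdet)


class Adam:
    """Adam optimizer over the model's parameter list."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                p.data.dtype)


def clip_grad_norm(params, max_norm: float) -> float:
    """Scale gradients so their global L2 norm is at most ``max_norm``."""
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad.astype(np.float64) ** 2).sum())
    norm = np.sqrt(total)
    if norm > max_norm and norm > 0:
        factor = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad *= factor
    return norm


@dataclass
class TrainConfig:
    batch_size: int = 32
    max_steps: int = 2000
    learning_rate: float = 1e-3
    warmup_steps: int = 100
    gradient_clip_norm: float = 50.0
    seed: int = 0
    checkpoint_interval: int = 500
    log_interval: int = 25

    def __post_init__(self):
        for name in ("batch_size", "max_steps", "learning_rate",
                     "warmup_steps", "gradient_clip_norm",
                     "checkpoint_interval", "log_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TrainReport:
    """Loss trajectory and the trained model.

    ``loss_trajectory`` entries are ``(step, nll_nats_per_volume, bits_per_dim)``
    in model-space units.
    """

    loss_trajectory: list = field(default_factory=list)
    final_model: Glow3D | None = None


def train(dataset: Sequence[np.ndarray], model_config: ModelConfig,
          train_config: TrainConfig,
          callback=None) -> TrainReport:
    """Maximum-likelihood training of a flow on model-space volumes.

    ``dataset``: array ``(N, w, h, d, c)`` or sequence of ``(w, h, d, c)``
    volumes already mapped to model space.  Actnorm is data-dependently
    initialized on the first batch, exactly once.  Deterministic given
    ``train_config.seed`` (which also drives batch shuffling).
    """
    data = np.stack([np.asarray(v, dtype=np.float32) for v in dataset])
    n = data.shape[0]
    tc = train_config
    if n < tc.batch_size:
        raise ValueError(f"dataset size {n} < batch_size {tc.batch_size}")
    model = Glow3D(model_config)
    rng = np.random.default_rng(tc.seed)
    n_dims = model.config.n_dims
    report = TrainReport()

    order = rng.permutation(n)
    first_batch = data[order[: tc.batch_size]]
    try:
        model.initialize_actnorm(first_batch)
    except NumericalOverflowError as err:
        raise TrainingDivergedError(
            f"non-finite activations during initialization: {err}",
            report=report, step=0) from err

    opt = Adam(model.parameters(), lr=tc.learning_rate)
    step = 0
    pos = 0
    while step < tc.max_steps:
        if pos + tc.batch_size > n:
            order = rng.permutation(n)
            pos = 0
        batch = data[order[pos: pos + tc.batch_size]]
        pos += tc.batch_size

        model.zero_grad()
        try:
            loss = _nll(Tensor(batch), model)
        except NumericalOverflowError as err:
            raise TrainingDivergedError(
                f"non-finite activations at step {step}: {err}",
                report=report, step=step) from err
        loss_val = float(loss.data)
        if not np.isfinite(loss_val):
            raise TrainingDivergedError(
                f"non-finite loss at step {step}", report=report, step=step)
        loss.backward()
        clip_grad_norm(opt.params, tc.gradient_clip_norm)
        lr = tc.learning_rate * min(1.0, (step + 1) / tc.warmup_steps)
        opt.step(lr=lr)

        if step % tc.log_interval == 0 or step == tc.max_steps - 1:
            report.loss_trajectory.append(
                (step, loss_val, loss_val / (n_dims * _LN2)))
            if callback is not None:
                callback(step, loss_val)
        step += 1

    report.final_model = model
    return report
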