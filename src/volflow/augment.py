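"""Data-augmentation strategies for volumetric training sets.

Two families are provided:

* **Flow-based latent interpolation** — encode two real volumes to latent
  codes ``z_a``, ``z_b``, draw ``alpha`` uniformly and map it linearly into
  ``[0.4, 0.6]``, form ``z = z_a + alpha * (z_b - z_a)`` with one shared
  alpha across all latent parts, and decode.  The restricted alpha range
  keeps the synthetic volume from being nearly identical to either parent.

* **Classical operators** — the comparator augmentations: *baseline* is
  random axis flips and/or central 1-3x zoom (trilinear resampling back to
  the original grid); *nonlinear* adds integer-voxel 3D shifts (edge
  padding), 3D rotation (right-angle by default, free-angle optional) and
  additive Gaussian intensity noise.

Classical operators act on raw-unit volumes ``(w, h, d)``; the flow strategy
acts on model-space volumes shaped like the model input.  Every strategy is
fully reproducible from (spec, seed, inputs, model).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .errors import InitializationRequiredError, ShapeError
from .model import Glow3D, LatentCode

_STRATEGIES = ("flow", "baseline", "nonlinear", "flow_plus_nonlinear")


@dataclass
class AugmentationSpec:
    """Knobs of all augmentation strategies.

    ``alpha_range`` is the latent-interpolation coefficient window;
    ``noise_sigma`` is in the same intensity units as the input volumes.
    ``rotation`` is ``'right_angle'`` (exact, no resampling), ``'free'``
    (trilinear rotation up to ``rotation_max_degrees``), or ``'none'``.
    """

    strategy: str = "flow"
    alpha_range: tuple = (0.4, 0.6)
    zoom_range: tuple = (1.0, 3.0)
    flip_probability: float = 0.5
    shift_max_voxels: int = 4
    rotation: str = "right_angle"
    rotation_max_degrees: float = 180.0
    noise_sigma: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.strategy not in _STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        lo, hi = self.alpha_range
        if not (0 <= lo < hi <= 1):
            raise ValueError("alpha_range must satisfy 0 <= low < high <= 1")
        zlo, zhi = self.zoom_range
        if not (1.0 <= zlo <= zhi):
            raise ValueError("zoom_range must lie within [1, inf), low <= high")
        if self.rotation not in ("right_angle", "free", "none"):
            raise ValueError(f"unknown rotation mode {self.rotation!r}")


@dataclass
class SyntheticVOI:
    """A generated volume plus the record that reproduces it."""

    volume: np.ndarray
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# flow-based interpolation
# ---------------------------------------------------------------------------

def interpolate_latent(z_a: LatentCode, z_b: LatentCode,
                       alpha: float) -> LatentCode:
    """Part-wise ``z_a + alpha * (z_b - z_a)`` with a single shared alpha."""
    if z_a.shapes != z_b.shapes:
        raise ShapeError(
            f"latent shapes differ: {z_a.shapes} vs {z_b.shapes}")
    # the (1-a)*za + a*zb form makes the alpha = 0 and 1 endpoints exact
    return LatentCode([(1.0 - alpha) * pa + alpha * pb
                       for pa, pb in zip(z_a.parts, z_b.parts)])


def draw_alpha(spec: AugmentationSpec, rng: np.random.Generator) -> float:
    """U(0,1) draw mapped affinely into ``spec.alpha_range``."""
    lo, hi = spec.alpha_range
    return lo + (hi - lo) * float(rng.uniform())


def generate_synthetic(x_a: np.ndarray, x_b: np.ndarray, model: Glow3D,
                       spec: AugmentationSpec,
                       rng: np.random.Generator) -> SyntheticVOI:
    """Decode a latent interpolation of two model-space volumes."""
    if not model.actnorm_initialized:
        raise InitializationRequiredError(
            "model must be trained (actnorm initialized) before augmentation")
    alpha = draw_alpha(spec, rng)
    z_a = model.encode(x_a).latent
    z_b = model.encode(x_b).latent
    volume = model.decode(interpolate_latent(z_a, z_b, alpha))
    return SyntheticVOI(volume, provenance={
        "strategy": "flow", "alpha": alpha, "index_a": None, "index_b": None})


# ---------------------------------------------------------------------------
# classical operators
# ---------------------------------------------------------------------------

def _central_zoom(x: np.ndarray, factor: float) -> np.ndarray:
    """Magnify by ``factor`` about the volume center, same output grid."""
    if factor == 1.0:
        return x
    center = (np.array(x.shape) - 1) / 2.0
    coords = np.indices(x.shape, dtype=np.float64)
    coords = center[:, None, None, None] + (coords - center[:, None, None, None]) / factor
    return ndimage.map_coordinates(x, coords, order=1, mode="nearest")


def baseline_augment(x: np.ndarray, spec: AugmentationSpec,
                     rng: np.random.Generator) -> np.ndarray:
    """Random axis flips and/or central zoom; output shape unchanged."""
    out = np.asarray(x)
    for axis in range(3):
        if rng.uniform() < spec.flip_probability:
            out = np.flip(out, axis=axis)
    zlo, zhi = spec.zoom_range
    factor = float(rng.uniform(zlo, zhi)) if zhi > zlo else zlo
    out = _central_zoom(np.ascontiguousarray(out, dtype=np.float64), factor)
    return out.astype(x.dtype) if np.issubdtype(x.dtype, np.floating) else out


def _right_angle_rotate(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A random element of the 3D right-angle rotation set (exact)."""
    out = x
    for axes in ((0, 1), (0, 2), (1, 2)):
        out = np.rot90(out, k=int(rng.integers(4)), axes=axes)
    return out


def nonlinear_augment(x: np.ndarray, spec: AugmentationSpec,
                      rng: np.random.Generator) -> np.ndarray:
    """Baseline ops plus 3D shift, 3D rotation, and Gaussian noise."""
    out = np.asarray(baseline_augment(x, spec, rng), dtype=np.float64)
    if spec.shift_max_voxels > 0:
        shift = rng.integers(-spec.shift_max_voxels,
                             spec.shift_max_voxels + 1, size=3)
        out = ndimage.shift(out, shift, order=0, mode="nearest")
    if spec.rotation == "right_angle":
        out = _right_angle_rotate(out, rng)
    elif spec.rotation == "free":
        angle = float(rng.uniform(-spec.rotation_max_degrees,
                                  spec.rotation_max_degrees))
        axes = tuple(sorted(rng.choice(3, size=2, replace=False).tolist()))
        out = ndimage.rotate(out, angle, axes=axes, reshape=False,
                             order=1, mode="nearest")
    if spec.noise_sigma > 0:
        out = out + rng.normal(0.0, spec.noise_sigma, size=out.shape)
    return np.ascontiguousarray(out)


# ---------------------------------------------------------------------------
# dataset-level driver
# ---------------------------------------------------------------------------

def augment_dataset(reals: Sequence[np.ndarray], model: Optional[Glow3D],
                    spec: AugmentationSpec, n_out: int,
                    rng: Optional[np.random.Generator] = None) -> list:
    """Produce ``n_out`` synthetic volumes with full provenance records.

    The flow strategies draw uniformly random ordered pairs of *distinct*
    training volumes per output; parent latents are encoded once and cached.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    reals = list(reals)
    out: list[SyntheticVOI] = []
    uses_flow = spec.strategy in ("flow", "flow_plus_nonlinear")
    if uses_flow:
        if model is None:
            raise ValueError(f"strategy {spec.strategy!r} requires a model")
        if len(reals) < 2:
            raise ValueError("flow strategy needs at least 2 real volumes")
        if not model.actnorm_initialized:
            raise InitializationRequiredError(
                "model must be trained (actnorm initialized) before augmentation")
        latents: dict[int, LatentCode] = {}

        def latent_of(i: int) -> LatentCode:
            if i not in latents:
                latents[i] = model.encode(np.asarray(reals[i])).latent
            return latents[i]

    for _ in range(n_out):
        if uses_flow:
            ia, ib = rng.choice(len(reals), size=2, replace=False)
            ia, ib = int(ia), int(ib)
            alpha = draw_alpha(spec, rng)
            vol = model.decode(
                interpolate_latent(latent_of(ia), latent_of(ib), alpha))
            prov = {"strategy": spec.strategy, "index_a": ia, "index_b": ib,
                    "alpha": alpha}
            if spec.strategy == "flow_plus_nonlinear":
                vol = nonlinear_augment(vol[..., 0] if vol.ndim == 4 else vol,
                                        spec, rng)
            out.append(SyntheticVOI(vol, prov))
        else:
            i = int(rng.integers(len(reals)))
            x = np.asarray(reals[i])
            op = baseline_augment if spec.strategy == "baseline" else nonlinear_augment
            out.append(SyntheticVOI(
                op(x, spec, rng),
                {"strategy": spec.strategy, "index_a": i, "index_b": None,
                 "alpha": None}))
    return out
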