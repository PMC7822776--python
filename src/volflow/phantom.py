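"""Synthetic colon-wall phantom VOIs (polyp and normal) in HU-like units.

The generator emulates the geometry the flow model is meant to learn from
clinical CT colonography sub-volumes: a curved soft-tissue wall separating
air lumen from tissue, optionally carrying either a focal sessile polyp
(hemispheric bump protruding into the lumen) or an elongated haustral-fold
ridge, followed by partial-volume blur (Gaussian), additive acquisition
noise, and rounding to integer intensities.

Geometry model: the wall is a section of a randomly oriented sphere of
radius 1/curvature passing through a jittered point near the volume center,
with random convex/concave sense, so flips and rotations of generated VOIs
produce genuinely different geometry.  A polyp is a ball of random radius
centered on the wall surface; its cap protrudes into the lumen (sessile
morphology).  At 1 mm isotropic spacing, a ball radius of r voxels stands
in for a lesion of diameter ~2r mm, so the default radius range 2.5-6.0
mimics the >= 6 mm lesions that matter clinically, without claiming
anatomical realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter


@dataclass
class PhantomSpec:
    """Parameters of the phantom generator (raw units are HU-like)."""

    shape: tuple = (32, 32, 32)
    lumen_intensity: float = -1000.0
    wall_intensity_mean: float = 30.0
    wall_intensity_std: float = 15.0
    polyp_radius_range: tuple = (2.5, 6.0)
    wall_curvature_range: tuple = (1.0 / 64.0, 1.0 / 20.0)
    fold_probability: float = 0.7
    fold_radius_range: tuple = (1.0, 2.2)
    center_jitter: float = 2.0
    blur_sigma: float = 0.8
    noise_sigma: float = 15.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.polyp_radius_range
        if not 0 < lo <= hi < min(self.shape) / 2:
            raise ValueError("polyp_radius_range must lie in (0, min(shape)/2)")
        if self.blur_sigma < 0 or self.noise_sigma < 0:
            raise ValueError("sigmas must be >= 0")
        if not 0 <= self.fold_probability <= 1:
            raise ValueError("fold_probability must be in [0, 1]")


@dataclass
class LabeledVOI:
    """One generated volume with its label and ground-truth polyp mask."""

    volume: np.ndarray            # (w, h, d) raw units
    label: str                    # "polyp" | "normal"
    polyp_mask: np.ndarray        # bool (w, h, d); empty for normal
    metadata: dict = field(default_factory=dict)


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _wall_geometry(spec: PhantomSpec, rng: np.random.Generator):
    """Returns (grid coords, anchor point p0, signed wall distance phi).

    phi >= 0 on the tissue side, < 0 in the lumen; |phi| is (approximately)
    the distance to the wall surface, which passes through p0.
    """
    shape = np.array(spec.shape)
    grid = np.stack(np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape],
                                indexing="ij"), axis=-1)
    p0 = (shape - 1) / 2.0 + rng.uniform(-spec.center_jitter,
                                         spec.center_jitter, size=3)
    normal = _random_unit_vector(rng)      # points from tissue into lumen
    kappa = rng.uniform(*spec.wall_curvature_range)
    radius = 1.0 / kappa
    convex = rng.uniform() < 0.5           # tissue bulges into the lumen
    if convex:
        center = p0 - radius * normal
        phi = radius - np.linalg.norm(grid - center, axis=-1)
    else:
        center = p0 + radius * normal
        phi = np.linalg.norm(grid - center, axis=-1) - radius
    return grid, p0, phi, normal, center


def _render(tissue: np.ndarray, wall_hu: float, spec: PhantomSpec,
            rng: np.random.Generator) -> np.ndarray:
    vol = np.where(tissue, wall_hu, spec.lumen_intensity)
    if spec.blur_sigma > 0:
        vol = gaussian_filter(vol, spec.blur_sigma)
    if spec.noise_sigma > 0:
        vol = vol + rng.normal(0.0, spec.noise_sigma, size=vol.shape)
    vol = np.round(vol)
    return np.clip(vol, -1024, 1023).astype(np.float32)


def make_polyp_voi(spec: PhantomSpec,
                   rng: Optional[np.random.Generator] = None) -> LabeledVOI:
    """Generate one polyp VOI: wall plus a sessile bump into the lumen."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    grid, p0, phi, normal, _ = _wall_geometry(spec, rng)
    wall_hu = rng.normal(spec.wall_intensity_mean, spec.wall_intensity_std)
    radius = rng.uniform(*spec.polyp_radius_range)
    # bump centered on the wall surface near the anchor point
    ball = np.linalg.norm(grid - p0, axis=-1) <= radius
    mask = ball & (phi < 0)                # pre-blur protruding voxels
    tissue = (phi >= 0) | ball
    vol = _render(tissue, wall_hu, spec, rng)
    return LabeledVOI(vol, "polyp", mask,
                      metadata={"radius": float(radius),
                                "center": p0.tolist(),
                                "wall_hu": float(wall_hu)})


def make_normal_voi(spec: PhantomSpec,
                    rng: Optional[np.random.Generator] = None) -> LabeledVOI:
    """Generate one normal-anatomy VOI: wall with an optional fold ridge."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    grid, p0, phi, normal, center = _wall_geometry(spec, rng)
    wall_hu = rng.normal(spec.wall_intensity_mean, spec.wall_intensity_std)
    tissue = phi >= 0
    has_fold = rng.uniform() < spec.fold_probability
    fold_radius = 0.0
    if has_fold:
        # elongated ridge hugging the wall: half-tube of radius fold_radius
        # around the great circle through p0 (so the ridge follows the wall's
        # curvature instead of leaving the surface)
        tangent = np.cross(normal, _random_unit_vector(rng))
        tangent /= np.linalg.norm(tangent)
        plane_n = np.cross(p0 - center, tangent)
        plane_n /= np.linalg.norm(plane_n)
        d_plane = np.abs((grid - center) @ plane_n)
        fold_radius = rng.uniform(*spec.fold_radius_range)
        ridge = np.sqrt(d_plane ** 2 + phi ** 2) <= fold_radius
        tissue = tissue | (ridge & (phi < 0))
    vol = _render(tissue, wall_hu, spec, rng)
    return LabeledVOI(vol, "normal", np.zeros(spec.shape, dtype=bool),
                      metadata={"fold": bool(has_fold),
                                "fold_radius": float(fold_radius),
                                "wall_hu": float(wall_hu)})


def make_dataset(n_polyp: int, n_normal: int, spec: PhantomSpec) -> list:
    """Deterministic labeled dataset: polyps first, then normals.

    Per-item RNGs are spawned from ``spec.seed`` so each volume is
    individually reproducible and the collection is order-stable.
    """
    if n_polyp < 0 or n_normal < 0:
        raise ValueError("counts must be >= 0")
    children = np.random.SeedSequence(spec.seed).spawn(n_polyp + n_normal)
    out = []
    for i in range(n_polyp):
        out.append(make_polyp_voi(spec, np.random.default_rng(children[i])))
    for i in range(n_normal):
        out.append(make_normal_voi(spec, np.random.default_rng(children[n_polyp + i])))
    return out


def _fit_wall_excess(tissue: np.ndarray) -> np.ndarray:
    """Signed protrusion of each tissue voxel past a robustly fitted wall.

    The wall surface is estimated from the tissue boundary (volume faces
    excluded) by iteratively trimmed least squares, trying both a sphere
    and a plane and keeping the better fit; positive values are distances
    past the fitted surface toward the lumen side.
    """
    from scipy import ndimage as ndi

    bnd = tissue & ~ndi.binary_erosion(tissue, border_value=1)
    for ax in range(3):
        sl = [slice(None)] * 3
        sl[ax] = 0
        bnd[tuple(sl)] = False
        sl[ax] = -1
        bnd[tuple(sl)] = False
    b = np.argwhere(bnd).astype(np.float64)
    pts = np.argwhere(tissue).astype(np.float64)
    if len(b) < 20 or len(pts) < 20:
        return np.zeros(max(len(pts), 1))

    def sphere_fit(p):
        a = np.c_[2 * p, np.ones(len(p))]
        sol, *_ = np.linalg.lstsq(a, (p ** 2).sum(1), rcond=None)
        c, r = sol[:3], np.sqrt(max(sol[3] + (sol[:3] ** 2).sum(), 1e-6))
        return lambda q: np.linalg.norm(q - c, axis=1) - r

    def plane_fit(p):
        mu = p.mean(0)
        n = np.linalg.svd(p - mu, full_matrices=False)[2][-1]
        return lambda q: (q - mu) @ n

    best = None
    for fit in (sphere_fit, plane_fit):
        keep = np.ones(len(b), bool)
        model = None
        for _ in range(4):
            model = fit(b[keep])
            resid = model(b)
            threshold = max(1.5 * np.percentile(np.abs(resid[keep]), 75), 1.0)
            new = np.abs(resid) < threshold
            if new.sum() < 20:
                break
            keep = new
        score = np.median(np.abs(model(b[keep])))
        if best is None or score < best[0]:
            best = (score, model)
    resid = best[1](pts)
    # the tissue bulk lies on one side of the surface; protrusions stick out
    # on the other (lumen) side
    return resid if (resid < 0).mean() > 0.5 else -resid


def summary_statistics(volume: np.ndarray,
                       tissue_threshold: float = -500.0) -> np.ndarray:
    """Three per-volume statistics for the polyp/normal logistic probe.

    1. maximum tissue protrusion (voxels) past the robustly fitted wall,
    2. log(1 + count) of tissue voxels protruding more than 1 voxel,
    3. elongation (sqrt of top-two principal-variance ratio) of the
       protruding voxel cloud — a ridge-like fold is elongated, a sessile
       polyp is compact.
    """
    from scipy import ndimage as ndi

    tissue = ndi.binary_opening(volume > tissue_threshold,
                                ndi.generate_binary_structure(3, 1))
    excess = _fit_wall_excess(tissue)
    pts = np.argwhere(tissue).astype(np.float64)
    prot = pts[excess > 1.0] if len(pts) == len(excess) else pts[:0]
    if len(prot) >= 4:
        ev = np.linalg.eigvalsh(np.cov(prot.T))
        elongation = float(np.sqrt(max(ev[2], 1e-9) / max(ev[1], 1e-9)))
    else:
        elongation = 1.0
    return np.array([float(excess.max(initial=0.0)),
                     float(np.log1p(len(prot))), elongation])
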