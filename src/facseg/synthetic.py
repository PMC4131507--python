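"""Synthetic two-region test scenes with exact ground truth.

The generators emulate the structure that defeats global-prototype
segmentation: a smooth background intensity ramp makes the object and
background intensity *ranges* overlap globally, while the object keeps a
constant local contrast (a fixed intensity offset over the ramp). The
default scene is a ring plus a detached arch below it on a horizontal ramp —
two objects whose lower parts sit on background brighter than the upper
object parts, so no single threshold or global mean pair separates them.

Degradations are layered on top of the clean scene: Gaussian boundary blur
(applied to the image; the ground-truth mask stays the exact pre-blur
geometry), additive Gaussian noise, and salt-and-pepper impulses. All
randomness flows through explicit integer seeds, and every generator returns
the exact geometry indicator as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "SceneSpec",
    "make_ramp_ring",
    "make_blurred_boundary",
    "add_gaussian_noise",
    "add_salt_pepper",
    "make_scene",
    "default_suite",
]


@dataclass
class SceneSpec:
    """Parameters of a generated scene.

    The geometry defaults (ring centre/radii, arch position) are fixed free
    choices, versioned here so that every run regenerates the identical
    scene. ``ramp`` gives the background intensity at the left and right
    image edges (linear in the column index); ``offset`` is the constant
    intensity added on the object geometry, i.e. the local object/background
    contrast before any degradation.
    """

    shape: Tuple[int, int] = (143, 150)
    ramp: Tuple[float, float] = (20.0, 120.0)
    offset: float = 60.0
    ring_center: Tuple[float, float] = (58.0, 75.0)
    ring_outer: float = 36.0
    ring_inner: float = 21.0
    arch_inner: float = 45.0
    arch_outer: float = 57.0
    arch_half_angle_deg: float = 35.0
    blur_sigma: float = 0.0
    noise: str = "none"  # none | gaussian | salt_pepper
    noise_sd: float = 10.0
    noise_fraction: float = 0.02
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def _geometry_mask(spec: SceneSpec) -> np.ndarray:
    # ring plus a detached concentric arc ("arch") curving below it
    h, w = spec.shape
    rr, cc = np.mgrid[0:h, 0:w]
    dr = rr - spec.ring_center[0]
    dc = cc - spec.ring_center[1]
    d = np.hypot(dr, dc)
    ring = (d <= spec.ring_outer) & (d >= spec.ring_inner)
    ang = np.abs(np.arctan2(dc, dr))  # 0 = straight down from the ring centre
    arch = (
        (d <= spec.arch_outer)
        & (d >= spec.arch_inner)
        & (ang <= np.deg2rad(spec.arch_half_angle_deg))
    )
    return ring | arch


def make_ramp_ring(spec: Optional[SceneSpec] = None) -> tuple[np.ndarray, np.ndarray]:
    """Clean ramp-background scene with ring + arch object.

    Returns ``(image, truth)`` where ``truth`` is the exact geometry
    indicator. The background ramps linearly from ``ramp[0]`` to ``ramp[1]``
    across the columns; object pixels add ``offset`` on top of the local
    ramp value, so the minimum local contrast equals ``offset`` everywhere
    (before clipping to [0, 255]).
    """
    spec = spec or SceneSpec()
    h, w = spec.shape
    ramp = np.linspace(spec.ramp[0], spec.ramp[1], w)
    img = np.broadcast_to(ramp, (h, w)).astype(np.float64).copy()
    truth = _geometry_mask(spec)
    img[truth] += spec.offset
    return np.clip(img, 0.0, 255.0), truth


def make_blurred_boundary(spec: Optional[SceneSpec] = None) -> tuple[np.ndarray, np.ndarray]:
    """Ramp-ring scene convolved with a Gaussian; truth stays pre-blur."""
    spec = spec or SceneSpec(blur_sigma=2.0)
    img, truth = make_ramp_ring(spec)
    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma, mode="nearest")
    return np.clip(img, 0.0, 255.0), truth


def add_gaussian_noise(image: np.ndarray, sd: float, seed: int = 0) -> np.ndarray:
    """Add i.i.d. zero-mean Gaussian noise, clipped to [0, 255]."""
    if sd < 0:
        raise ValueError("noise sd must be >= 0")
    img = np.asarray(image, dtype=np.float64)
    if sd == 0:
        return img.copy()
    rng = np.random.default_rng(seed)
    return np.clip(img + rng.normal(0.0, sd, img.shape), 0.0, 255.0)


def add_salt_pepper(image: np.ndarray, fraction: float, seed: int = 0) -> np.ndarray:
    """Set round(fraction * n) pixels (without replacement) to 0 or 255.

    Each corrupted pixel is salt (255) or pepper (0) with probability 1/2.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    img = np.asarray(image, dtype=np.float64).copy()
    n = img.size
    k = int(round(fraction * n))
    if k == 0:
        return img
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=k, replace=False)
    salt = rng.random(k) < 0.5
    flat = img.reshape(-1)
    flat[idx[salt]] = 255.0
    flat[idx[~salt]] = 0.0
    return img


def make_scene(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    """Full pipeline: geometry + ramp, then blur, then noise (in that order)."""
    if spec.blur_sigma > 0:
        img, truth = make_blurred_boundary(spec)
    else:
        img, truth = make_ramp_ring(spec)
    if spec.noise == "gaussian":
        img = add_gaussian_noise(img, spec.noise_sd, spec.seed)
    elif spec.noise == "salt_pepper":
        img = add_salt_pepper(img, spec.noise_fraction, spec.seed)
    elif spec.noise != "none":
        raise ValueError(f"unknown noise model {spec.noise!r}")
    return img, truth


def default_suite(seed: int = 0) -> dict[str, tuple[np.ndarray, np.ndarray, SceneSpec]]:
    """The four standard test scenes: clean, blurred, Gaussian, salt-pepper.

    Noise magnitudes default to sd = 10 intensity units and a 2% impulse
    fraction — strong enough to perturb the overlap structure without
    swamping the 60-unit local contrast.
    """
    scenes = {}
    for name, spec in [
        ("clean", SceneSpec(seed=seed)),
        ("blurred", SceneSpec(blur_sigma=2.0, seed=seed)),
        ("gaussian", SceneSpec(noise="gaussian", noise_sd=10.0, seed=seed)),
        ("salt_pepper", SceneSpec(noise="salt_pepper", noise_fraction=0.02, seed=seed)),
    ]:
        img, truth = make_scene(spec)
        scenes[name] = (img, truth, spec)
    return scenes
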