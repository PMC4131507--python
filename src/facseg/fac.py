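"""Global-prototype fuzzy active contour (FAC) baseline.

The FAC model partitions an image into object and background by minimising

    F(u, c1, c2) = lambda1 * sum u^m (I - c1)^2
                 + lambda2 * sum (1 - u)^m (I - c2)^2

over a fuzzy membership map u and two *global* prototypes c1, c2 (the
membership-weighted mean intensities inside and outside the contour). The
curve-length regulariser of the full model is omitted: it matters only for
very noisy images and plays no role in the minimisation implemented here.
Minimisation alternates a closed-form prototype update with a closed-form
per-pixel membership update until the energy stalls. Because both half-steps
are exact coordinate minimisations, the energy trace is non-increasing.

The global prototypes are the model's weakness on intensity-inhomogeneous
images: when the object and background intensity ranges overlap (a smooth
ramp, an MR bias field), no pair of constants separates them, and parts of
the object are absorbed into the background. The local model in
:mod:`facseg.lfac` exists to fix exactly this.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .core import ModelParams, SegmentationResult, as_gray_image, as_membership, threshold_mask
from .exceptions import DegeneratePartitionError

__all__ = [
    "GlobalPrototypes",
    "global_prototypes",
    "fac_membership",
    "membership_update",
    "fac_energy",
    "run_fac",
    "morph_band",
]


@dataclass(frozen=True)
class GlobalPrototypes:
    """Mean intensities inside (c1) and outside (c2) the evolving contour."""

    c1: float
    c2: float


def global_prototypes(image: np.ndarray, membership: np.ndarray, m: float) -> GlobalPrototypes:
    """Membership-weighted mean intensities of the two regions.

    c1 = sum(u^m I) / sum(u^m),  c2 = sum((1-u)^m I) / sum((1-u)^m),
    both over the whole image domain.

    Raises
    ------
    DegeneratePartitionError
        If either weight total is zero (the membership assigns everything
        to a single region), leaving a prototype undefined.
    """
    I = as_gray_image(image)
    u = as_membership(membership, I.shape)
    w1 = u**m
    w2 = (1.0 - u) ** m
    s1 = w1.sum()
    s2 = w2.sum()
    if s1 == 0.0 or s2 == 0.0:
        raise DegeneratePartitionError(
            "membership gives zero total weight to one region; prototypes undefined"
        )
    return GlobalPrototypes(c1=float((w1 * I).sum() / s1), c2=float((w2 * I).sum() / s2))


def membership_update(
    image: np.ndarray,
    c1: np.ndarray | float,
    c2: np.ndarray | float,
    m: float,
    lambda1: float = 1.0,
    lambda2: float = 1.0,
) -> np.ndarray:
    """Closed-form membership minimiser for fixed prototypes, vectorised.

    u = 1 / (1 + (lambda1 (I-c1)^2 / (lambda2 (I-c2)^2))^(1/(m-1)))

    Zero-distance hazards follow the limits of the formula: if both squared
    distances vanish, u = 0.5; if only (I-c2)^2 vanishes, u = 0; if only
    (I-c1)^2 vanishes, u = 1. Accepts scalar prototypes (global model) or
    per-pixel prototype grids (local model).
    """
    I = np.asarray(image, dtype=np.float64)
    d1 = lambda1 * (I - c1) ** 2
    d2 = lambda2 * (I - c2) ** 2
    u = np.empty_like(I)
    both_zero = (d1 == 0.0) & (d2 == 0.0)
    only_d2 = (d2 == 0.0) & ~both_zero
    only_d1 = (d1 == 0.0) & ~both_zero
    regular = ~(both_zero | only_d1 | only_d2)
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(regular, d1, 1.0) / np.where(regular, d2, 1.0)
        u[regular] = 1.0 / (1.0 + ratio[regular] ** (1.0 / (m - 1.0)))
    u[both_zero] = 0.5
    u[only_d2] = 0.0
    u[only_d1] = 1.0
    return u


def fac_membership(intensity: float, c1: float, c2: float, params: ModelParams) -> float:
    """Scalar membership update for a single pixel (see membership_update)."""
    u = membership_update(
        np.asarray([[float(intensity)]]), c1, c2, params.m, params.lambda1, params.lambda2
    )
    return float(u[0, 0])


def fac_energy(
    image: np.ndarray,
    membership: np.ndarray,
    prototypes: GlobalPrototypes,
    params: ModelParams,
) -> float:
    """Total fuzzy energy for global prototypes (length term omitted)."""
    I = as_gray_image(image)
    u = as_membership(membership, I.shape)
    f = params.lambda1 * (u**params.m * (I - prototypes.c1) ** 2).sum()
    f += params.lambda2 * ((1.0 - u) ** params.m * (I - prototypes.c2) ** 2).sum()
    return float(f)


def _stalled(f_new: float, f_old: float, params: ModelParams) -> bool:
    df = abs(f_new - f_old)
    if params.relative_stop:
        return df / max(abs(f_old), 1.0) < params.epsilon
    return df < params.epsilon


def run_fac(
    image: np.ndarray, init: np.ndarray, params: ModelParams | None = None
) -> SegmentationResult:
    """Alternating minimisation of the global-prototype fuzzy energy.

    Each sweep recomputes the global prototypes from the current membership
    and then applies the closed-form membership update to every pixel;
    iteration stops when the energy change drops below ``params.epsilon``
    or after ``params.max_iters`` sweeps.
    """
    params = params or ModelParams()
    I = as_gray_image(image)
    u = as_membership(init, I.shape).copy()
    n = I.size
    energies: list[float] = []
    f_old = np.inf
    converged = False
    it = 0
    total_updates = 0
    while it < params.max_iters:
        proto = global_prototypes(I, u, params.m)
        u = membership_update(I, proto.c1, proto.c2, params.m, params.lambda1, params.lambda2)
        f = fac_energy(I, u, proto, params)
        energies.append(f)
        total_updates += n
        it += 1
        if np.isfinite(f_old) and _stalled(f, f_old, params):
            converged = True
            break
        f_old = f
    return SegmentationResult(
        mask=threshold_mask(u),
        membership=u,
        energy_trace=np.asarray(energies),
        band_size_trace=np.full(it, n, dtype=int),
        accepted_trace=np.full(it, n, dtype=int),
        iterations=it,
        converged=converged,
        total_updates=total_updates,
        model="fac",
        params=params,
    )


_SQUARE3 = np.ones((3, 3), dtype=bool)


def morph_band(membership: np.ndarray) -> np.ndarray:
    """Morphological boundary band around the crisp 0.5 contour.

    The membership is crisped with a hard step at 0.5, the one-pixel
    boundary is extracted as A minus its erosion by a 3x3 square, and the
    boundary is expanded by dilation with a disk of radius 5. The erosion
    pads beyond the image frame with foreground, so the frame itself never
    counts as a contour (a full-foreground map has no boundary and yields
    an empty band).
    """
    u = np.asarray(membership, dtype=np.float64)
    fg = u - 0.5 > 0.0
    eroded = ndimage.binary_erosion(fg, structure=_SQUARE3, border_value=1)
    boundary = fg & ~eroded
    return ndimage.binary_dilation(boundary, structure=disk(5).astype(bool))
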