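"""Narrow-band local fuzzy active contour (LFAC).

The local model replaces the two global prototypes of the FAC baseline with
the spatially varying ones of :mod:`facseg.local` and minimises

    F = sum u^m (I - c1(x,y))^2 + sum (1-u)^m (I - c2(x,y))^2

over the membership map. Each sweep only touches the approximation region
R_a near the current contour (the shadowed-sets band of
:mod:`facseg.shadowed`, or the morphological band of the baseline): for each
band pixel the candidate membership u_n is the closed-form minimiser for the
pixel's local prototypes, and the candidate is accepted only if the
closed-form energy difference

    dF = (u_n^m (s1 / (s1 + u_n^m - u_o^m))^2 - u_o^m) (I_o - c1)^2
       + ((1-u_n)^m (s2 / (s2 + (1-u_n)^m - (1-u_o)^m))^2 - (1-u_o)^m) (I_o - c2)^2

is strictly negative. dF is exactly the change of the pixel's own energy
contribution when its membership moves from u_o to u_n and the prototypes
are re-derived with the new value, provided the weight sums s1, s2 count the
centre pixel with weight 1; the default ``center_weight="unit"`` convention
rescales the kernel-weighted sums accordingly (see docs/methods.md).

Prototypes and weight sums are computed once per sweep from the membership
at sweep start, so the per-pixel accept/reject decisions within a sweep are
independent of each other and of the visit order; with a window covering the
whole image and uniform weights a full-domain sweep reduces exactly to one
sweep of the global baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import (
    ModelParams,
    SegmentationResult,
    as_gray_image,
    as_membership,
    threshold_mask,
)
from .exceptions import DegeneratePartitionError, DegenerateUpdateError
from .fac import global_prototypes, membership_update, morph_band
from .local import KernelWindow, build_kernel, local_prototype_field
from .shadowed import boundary_region

__all__ = ["DeltaFTerms", "delta_f", "delta_f_values", "lfac_step", "lfac_energy", "run_lfac"]


@dataclass(frozen=True)
class DeltaFTerms:
    """Inputs of the closed-form energy difference at one pixel."""

    u_o: float
    u_n: float
    I_o: float
    c1_loc: float
    c2_loc: float
    s1: float
    s2: float


def delta_f_values(u_o, u_n, I_o, c1, c2, s1, s2, m):
    """Vectorised closed-form energy difference; NaN where a denominator
    s + (new weight - old weight) is non-positive (update not evaluable)."""
    u_o = np.asarray(u_o, dtype=np.float64)
    u_n = np.asarray(u_n, dtype=np.float64)
    d1 = s1 + u_n**m - u_o**m
    d2 = s2 + (1.0 - u_n) ** m - (1.0 - u_o) ** m
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (u_n**m * (s1 / d1) ** 2 - u_o**m) * (I_o - c1) ** 2
        t2 = ((1.0 - u_n) ** m * (s2 / d2) ** 2 - (1.0 - u_o) ** m) * (I_o - c2) ** 2
        out = np.where((d1 > 0) & (d2 > 0), t1 + t2, np.nan)
    return out


def delta_f(terms: DeltaFTerms, m: float) -> float:
    """Energy difference for replacing u_o by u_n at a single pixel.

    Raises
    ------
    DegenerateUpdateError
        If a denominator s + (new - old) weight is non-positive, in which
        case the update cannot be evaluated and must be rejected.
    """
    val = delta_f_values(
        terms.u_o, terms.u_n, terms.I_o, terms.c1_loc, terms.c2_loc, terms.s1, terms.s2, m
    )
    if np.isnan(val):
        raise DegenerateUpdateError(
            "energy-difference denominator non-positive; update rejected"
        )
    return float(val)


def _effective_s(field_s: np.ndarray, kernel: KernelWindow, convention: str) -> np.ndarray:
    """Weight sums on the scale the energy-difference rule expects."""
    if convention == "unit":
        return field_s / kernel.center_weight
    return field_s


def _sweep_candidates(
    I: np.ndarray,
    u: np.ndarray,
    kernel: KernelWindow,
    params: ModelParams,
    band: np.ndarray,
):
    """Candidate memberships, energy differences and the acceptance mask for
    one sweep, all computed from the membership at sweep start."""
    field = local_prototype_field(I, u, kernel, params.m)
    u_n = membership_update(I, field.c1, field.c2, params.m)
    s1 = _effective_s(field.s1, kernel, params.center_weight)
    s2 = _effective_s(field.s2, kernel, params.center_weight)
    df = delta_f_values(u, u_n, I, field.c1, field.c2, s1, s2, params.m)
    # strictly-negative dF, with a numerical floor so float dust on exact
    # ties (no local evidence) does not count as an improvement
    accept = band & np.isfinite(df) & (df < -params.accept_tol)
    if params.contiguous_flips:
        # the contour may only move by contact: crossing the 0.5 level is
        # allowed solely for pixels 8-adjacent to the opposite region
        mask = threshold_mask(u)
        flips = threshold_mask(u_n) ^ mask
        s = np.ones((3, 3), dtype=bool)
        at_contour = ndimage.binary_dilation(mask, s) & ndimage.binary_dilation(~mask, s)
        accept &= ~flips | at_contour
    return u_n, df, accept


def lfac_step(
    image: np.ndarray,
    membership: np.ndarray,
    kernel: KernelWindow,
    params: ModelParams,
    band: np.ndarray,
):
    """One narrow-band sweep: candidate update + acceptance on each band pixel.

    The prototype field and the weight sums are computed from the membership
    at sweep start; every band pixel then independently receives the
    closed-form candidate and keeps it iff the energy difference is strictly
    negative. Pixels outside the band are untouched.

    Returns
    -------
    (u_new, accepted) : (ndarray, int)
    """
    I = as_gray_image(image)
    u = as_membership(membership, I.shape)
    band = np.asarray(band, dtype=bool)
    u_n, _, accept = _sweep_candidates(I, u, kernel, params, band)
    u_new = np.where(accept, u_n, u)
    return u_new, int(np.count_nonzero(accept))




def lfac_energy(
    image: np.ndarray, membership: np.ndarray, kernel: KernelWindow, m: float
) -> float:
    """Total local-prototype energy over the full domain (prototypes
    recomputed from the given membership)."""
    I = as_gray_image(image)
    u = as_membership(membership, I.shape)
    field = local_prototype_field(I, u, kernel, m)
    f = (u**m * (I - field.c1) ** 2).sum()
    f += ((1.0 - u) ** m * (I - field.c2) ** 2).sum()
    return float(f)


def _clear_frame_margin(band: np.ndarray, radius: int) -> np.ndarray:
    """Drop band pixels whose kernel window would be clipped by the frame."""
    out = band.copy()
    r = min(radius, (band.shape[0] - 1) // 2, (band.shape[1] - 1) // 2)
    if r > 0:
        out[:r, :] = False
        out[-r:, :] = False
        out[:, :r] = False
        out[:, -r:] = False
    return out


def _stalled(f_new: float, f_old: float, params: ModelParams) -> bool:
    df = abs(f_new - f_old)
    if params.relative_stop:
        return df / max(abs(f_old), 1.0) < params.epsilon
    return df < params.epsilon


def run_lfac(
    image: np.ndarray,
    init: np.ndarray,
    params: ModelParams | None = None,
    band_method: str = "shadowed",
) -> SegmentationResult:
    """Narrow-band minimisation of the local-prototype fuzzy energy.

    Updates are confined to a band near the current contour from the very
    first sweep: the contour grows or shrinks from the seed partition and
    locks onto intensity edges where the local prototypes separate, while
    pixels far from any contour keep their seed labels (in a locally
    homogeneous window the two prototypes coincide and carry no evidence
    either way, so touching such pixels could only corrupt them). Band
    strategies:

    ``band_method='shadowed'``
        two-phase adaptive schedule. The bootstrap phase updates the
        fixed-width morphological band around the crisp 0.5 contour: a
        crisp or piecewise-constant membership map (the seed partition in
        particular) has an empty shadow, because constant membership levels
        are atoms of the value multiset and the threshold search always
        places atoms outside the strict shadow inequalities, so the
        morphological band is what lets the contour start moving. Once a
        bootstrap sweep accepts no update (the contour has locked), the
        run switches to the pure shadowed-sets region R_a = S1 | S2 of
        the membership map and iterates it until it too accepts no update
        or empties; by then only the thin halo of genuinely uncertain
        pixels around the locked contour remains updatable.
    ``band_method='morphological'``
        fixed-width band from the crisp contour (3x3 erosion boundary
        dilated by a radius-5 disk) every sweep.
    ``band_method='none'``
        every pixel is updated every sweep.

    Whatever the band method, pixels whose kernel window extends beyond the
    image frame (a margin of ``params.radius``) are never updated: their
    local prototypes would be weighted means of a clipped, one-sided
    neighbourhood, which on any intensity gradient is a biased estimate that
    manufactures spurious evidence. Such pixels keep their current labels;
    objects are assumed not to touch the frame.

    Iteration stops when the total energy change falls below
    ``params.epsilon``, the band is empty, a sweep accepts no update, or
    ``params.max_iters`` is reached. The default path is deterministic.
    """
    params = params or ModelParams()
    if band_method not in ("shadowed", "morphological", "none"):
        raise ValueError(f"unknown band method {band_method!r}")
    I = as_gray_image(image)
    u = as_membership(init, I.shape).copy()
    if np.all(u == 0.5):
        raise DegeneratePartitionError("initial membership is uniformly 0.5")
    kernel = build_kernel(params.sigma, params.radius)

    f = lfac_energy(I, u, kernel, params.m)
    energies = [f]
    band_sizes: list[int] = []
    accepted_counts: list[int] = []
    total_updates = 0

    converged = False
    bootstrap = True  # only meaningful for the 'shadowed' schedule
    it = 0
    while it < params.max_iters:
        if band_method == "shadowed":
            band = morph_band(u) if bootstrap else boundary_region(u, params.alpha_step)
        elif band_method == "morphological":
            band = morph_band(u)
        else:
            band = np.ones_like(u, dtype=bool)
        band = _clear_frame_margin(band, kernel.radius)
        band_size = int(np.count_nonzero(band))
        if band_size == 0:
            if band_method == "shadowed" and bootstrap:
                bootstrap = False
                continue
            converged = True
            break
        u, accepted = lfac_step(I, u, kernel, params, band)
        f_new = lfac_energy(I, u, kernel, params.m)
        energies.append(f_new)
        band_sizes.append(band_size)
        accepted_counts.append(accepted)
        total_updates += band_size
        it += 1
        if accepted == 0:
            if band_method == "shadowed" and bootstrap:
                bootstrap = False  # contour locked; refine within the shadow
                continue
            converged = True
            break
        stalled = _stalled(f_new, f, params)
        f = f_new
        if stalled:
            converged = True
            break

    # align the per-sweep traces with the energy trace (entry 0 = initial state)
    return SegmentationResult(
        mask=threshold_mask(u),
        membership=u,
        energy_trace=np.asarray(energies),
        band_size_trace=np.asarray([0] + band_sizes, dtype=int),
        accepted_trace=np.asarray([0] + accepted_counts, dtype=int),
        iterations=it,
        converged=converged,
        total_updates=total_updates,
        model="lfac",
        params=params,
    )
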