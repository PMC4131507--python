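"""Shared domain types and grid conventions.

A grayscale image is a 2-D float array of intensities on the 8-bit scale
[0, 255]; a membership map is a same-shaped float array ``u`` with values in
[0, 1] giving each pixel's degree of belonging to the object region. The
contour is the 0.5 level of ``u``: the object region is the strict superlevel
set {u > 0.5}, the background is {u <= 0.5} (ties go to background).
Coordinates are 0-based (row, col), row-major; one pixel is one unit length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .exceptions import ParameterError

__all__ = [
    "ModelParams",
    "SegmentationResult",
    "threshold_mask",
    "as_gray_image",
    "as_membership",
]


@dataclass
class ModelParams:
    """Parameters of the fuzzy active contour models.

    Attributes
    ----------
    m : float
        Fuzzy coefficient (softness exponent of the memberships), > 1.
        The membership update raises an intensity-distance ratio to the
        power 1/(m-1), which is undefined at m = 1.
    lambda1, lambda2 : float
        Positive weights of the inside/outside residual terms; default 1
        balances the two regions.
    sigma : float
        Standard deviation, in pixels, of the Gaussian kernel that defines
        the local neighbourhood for spatially varying prototypes.
    kernel_radius : int or None
        Truncation radius of the kernel window in pixels; ``None`` means
        ceil(3 * sigma), which captures >99% of the kernel mass.
    epsilon : float
        Stopping tolerance on the change of the total energy between sweeps.
    relative_stop : bool
        If True the stopping test uses |dF| / max(|F|, 1) < epsilon instead
        of the absolute change (the energy scales with image size).
    max_iters : int
        Safety cap on the number of sweeps.
    alpha_step : float
        Grid step of the exhaustive shadowed-sets threshold search.
    init_inside, init_outside : float
        Membership levels used to encode a geometric seed: u = init_inside
        within the seed contour, init_outside elsewhere. They must straddle
        0.5 while leaving headroom for the threshold search.
    accept_tol : float
        Numerical floor on the energy decrease required to accept a pixel
        update. The exact acceptance rule is "accept iff dF < 0"; computed
        with floating-point prototypes an exact tie (a pixel with no local
        evidence) lands at dF ~ -1e-26 rather than 0, and accepting such
        dust-level "improvements" lets label noise diffuse through
        evidence-free regions. The default 1e-6 (squared-intensity units,
        ~1e-10 of a typical energy on the 8-bit scale) is far below any
        genuine evidence and only filters round-off.
    center_weight : {"unit", "printed"}
        Convention for the kernel weight of the centre pixel inside the
        energy-difference acceptance rule. "unit" rescales the local weight
        sums so the centre counts with weight 1, which makes the closed-form
        energy difference exact; "printed" uses the kernel normalisation as
        is. See docs/methods.md.
    contiguous_flips : bool
        If True (default) a pixel may cross the 0.5 contour level only when
        it is 8-adjacent to the opposite region, so the contour moves
        gradually instead of nucleating new components wherever noise tips
        an uncertain pixel across 0.5. Membership refinements that stay on
        one side of 0.5 are never restricted.
    seed : int
        Seed for optional randomised initialisations; the default fitting
        path is deterministic and ignores it.
    """

    m: float = 2.0
    lambda1: float = 1.0
    lambda2: float = 1.0
    sigma: float = 3.0
    kernel_radius: Optional[int] = None
    epsilon: float = 1e-2
    relative_stop: bool = False
    max_iters: int = 500
    alpha_step: float = 0.001
    accept_tol: float = 1e-6
    init_inside: float = 0.8
    init_outside: float = 0.2
    center_weight: str = "unit"
    contiguous_flips: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.m > 1:
            raise ParameterError(f"fuzzy coefficient m must be > 1, got {self.m}")
        if self.lambda1 <= 0 or self.lambda2 <= 0:
            raise ParameterError("lambda1 and lambda2 must be positive")
        if self.sigma <= 0:
            raise ParameterError(f"sigma must be > 0, got {self.sigma}")
        if self.kernel_radius is not None and self.kernel_radius < 1:
            raise ParameterError("kernel_radius must be >= 1")
        if self.epsilon <= 0:
            raise ParameterError("epsilon must be > 0")
        if self.alpha_step <= 0:
            raise ParameterError("alpha_step must be > 0")
        if self.accept_tol < 0:
            raise ParameterError("accept_tol must be >= 0")
        if self.max_iters < 1:
            raise ParameterError("max_iters must be >= 1")
        if not (0.5 < self.init_inside <= 1.0 and 0.0 <= self.init_outside < 0.5):
            raise ParameterError(
                "init_inside must lie in (0.5, 1] and init_outside in [0, 0.5)"
            )
        if self.center_weight not in ("unit", "printed"):
            raise ParameterError("center_weight must be 'unit' or 'printed'")

    @property
    def radius(self) -> int:
        """Effective kernel truncation radius in pixels."""
        if self.kernel_radius is not None:
            return int(self.kernel_radius)
        return int(np.ceil(3.0 * self.sigma))

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass
class SegmentationResult:
    """Raw output of a segmentation run.

    ``mask`` is exactly the 0.5-thresholding of ``membership``; the traces
    record, per sweep, the total energy F, the size of the update band |R_a|,
    and the number of accepted pixel updates.
    """

    mask: np.ndarray
    membership: np.ndarray
    energy_trace: np.ndarray
    band_size_trace: np.ndarray
    accepted_trace: np.ndarray
    iterations: int
    converged: bool
    total_updates: int = 0
    model: str = ""
    params: ModelParams = field(default_factory=ModelParams)

    @property
    def final_energy(self) -> float:
        return float(self.energy_trace[-1])


def threshold_mask(membership: np.ndarray) -> np.ndarray:
    """Crisp the membership map at the 0.5 contour level.

    Returns a boolean grid that is True exactly where u > 0.5; the tie
    u = 0.5 is assigned to the background, so the object region is the
    strict superlevel set.
    """
    u = np.asarray(membership)
    return u > 0.5


def as_gray_image(arr: np.ndarray) -> np.ndarray:
    """Validate and convert an array to a float64 grayscale image grid."""
    img = np.asarray(arr, dtype=np.float64)
    if img.ndim != 2 or img.shape[0] < 1 or img.shape[1] < 1:
        raise ParameterError(f"image must be a 2-D grid, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ParameterError("image intensities must all be finite")
    return img


def as_membership(arr: np.ndarray, shape=None) -> np.ndarray:
    """Validate and convert an array to a float64 membership map in [0, 1]."""
    u = np.asarray(arr, dtype=np.float64)
    if u.ndim != 2:
        raise ParameterError(f"membership must be a 2-D grid, got shape {u.shape}")
    if shape is not None and u.shape != tuple(shape):
        raise ParameterError(f"membership shape {u.shape} != image shape {shape}")
    if not np.all(np.isfinite(u)) or u.min() < 0.0 or u.max() > 1.0:
        raise ParameterError("membership degrees must lie in [0, 1]")
    return u
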