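"""Spatially varying prototypes from a truncated Gaussian window.

Instead of two global mean intensities, each pixel (x, y) gets local
prototypes computed over its neighbourhood with Gaussian weights

    g(d) = (1 / (2 pi sigma)) * exp(-d^2 / (2 sigma^2)),

where d is the Euclidean offset in pixels:

    c1(x, y) = sum_w u^m g I / sum_w u^m g
    c2(x, y) = sum_w (1-u)^m g I / sum_w (1-u)^m g.

The denominators s1 = sum_w u^m g and s2 = sum_w (1-u)^m g are returned as
well; the narrow-band update rule reuses them. The window is truncated at a
finite radius (default ceil(3 sigma), >99% of the kernel mass); at image
borders the window is clipped and the sums run over in-image pixels only, so
the prototypes remain true weighted means of real pixels.

The kernel normalisation cancels in the c1/c2 ratios; it only sets the scale
of s1 and s2 (see docs/methods.md for the centre-weight convention used by
the acceptance rule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import as_gray_image, as_membership
from .exceptions import ParameterError

__all__ = ["KernelWindow", "build_kernel", "PrototypeField", "local_prototype_field"]

# below this weight total a window is considered empty of a region
S_FLOOR = 1e-12


@dataclass(frozen=True)
class KernelWindow:
    """Truncated Gaussian weight window on a (2r+1) x (2r+1) offset grid."""

    sigma: float
    radius: int
    weights: np.ndarray

    @property
    def center_weight(self) -> float:
        return float(self.weights[self.radius, self.radius])


def build_kernel(sigma: float, radius: int | None = None) -> KernelWindow:
    """Gaussian kernel window g(d) = (1/(2 pi sigma)) exp(-d^2 / (2 sigma^2)).

    ``radius`` defaults to ceil(3 * sigma). Weights are symmetric under
    reflection, maximal at the centre (value 1/(2 pi sigma)) and strictly
    positive everywhere inside the window.
    """
    if sigma <= 0:
        raise ParameterError(f"sigma must be > 0, got {sigma}")
    if radius is None:
        radius = int(np.ceil(3.0 * sigma))
    radius = int(radius)
    if radius < 1:
        raise ParameterError(f"radius must be >= 1, got {radius}")
    off = np.arange(-radius, radius + 1, dtype=np.float64)
    d2 = off[:, None] ** 2 + off[None, :] ** 2
    weights = (1.0 / (2.0 * np.pi * sigma)) * np.exp(-d2 / (2.0 * sigma**2))
    return KernelWindow(sigma=float(sigma), radius=radius, weights=weights)


@dataclass
class PrototypeField:
    """Per-pixel local prototypes c1, c2 and their weight sums s1, s2."""

    c1: np.ndarray
    c2: np.ndarray
    s1: np.ndarray
    s2: np.ndarray


def _conv(arr: np.ndarray, kernel: np.ndarray, mode: str) -> np.ndarray:
    # 'constant' zero padding makes each sum run over in-image pixels only
    return ndimage.convolve(arr, kernel, mode=mode, cval=0.0)


def local_prototype_field(
    image: np.ndarray,
    membership: np.ndarray,
    kernel: KernelWindow,
    m: float,
    mode: str = "constant",
) -> PrototypeField:
    """Kernel-weighted local prototypes and weight sums at every pixel.

    Degenerate windows (a region's weight sum below ``S_FLOOR``, e.g. u == 0
    throughout a window) are handled without raising: the sum is clamped to
    the floor and the corresponding prototype falls back to the plain
    kernel-weighted image mean, which keeps the bounded-mean invariant.

    ``mode`` is passed to the underlying convolution; the default 'constant'
    (zero padding) clips the window at image borders, 'wrap' gives periodic
    padding (used by translation-equivariance checks).
    """
    I = as_gray_image(image)
    u = as_membership(membership, I.shape)
    g = kernel.weights
    w1 = u**m
    w2 = (1.0 - u) ** m
    s1 = _conv(w1, g, mode)
    s2 = _conv(w2, g, mode)
    n1 = _conv(w1 * I, g, mode)
    n2 = _conv(w2 * I, g, mode)
    gi = _conv(I, g, mode)
    gs = _conv(np.ones_like(I), g, mode)
    plain_mean = gi / gs
    bad1 = s1 < S_FLOOR
    bad2 = s2 < S_FLOOR
    c1 = np.where(bad1, plain_mean, n1 / np.where(bad1, 1.0, np.maximum(s1, S_FLOOR)))
    c2 = np.where(bad2, plain_mean, n2 / np.where(bad2, 1.0, np.maximum(s2, S_FLOOR)))
    return PrototypeField(
        c1=c1, c2=c2, s1=np.maximum(s1, S_FLOOR), s2=np.maximum(s2, S_FLOOR)
    )
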