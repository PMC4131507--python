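"""Shadowed-sets three-way partitioning of a fuzzy membership set.

A shadowed set splits a fuzzy set into a core (memberships elevated to 1),
an exclusion zone (memberships reduced to 0) and a shadow that retains the
uncertainty. The threshold alpha balances the membership mass destroyed by
elevation and reduction against the size of the shadow that absorbs it, by
minimising

    V(alpha) = | psi1 + psi2 - psi3 |

where, for the multiset of membership values u with maximum U_max,

    psi1 = sum of u over {u <= alpha}                 (total reduction)
    psi2 = sum of (U_max - u) over {u >= U_max-alpha} (total elevation)
    psi3 = number of values with alpha < u < U_max - alpha  (shadow size).

The shadow cardinality enters with a minus sign: the optimal threshold is
the point where the vagueness removed from the tails equals the vagueness
localised in the shadow. (A sum of the three non-negative terms would be
minimised trivially by the largest alpha, always producing an empty
shadow.)

The search is an exhaustive grid over [U_min, (U_max + U_min)/2] with a fixed
step (default 0.001), ties broken toward the smallest alpha (the larger,
more conservative shadow).

Applied to a segmentation membership map twice — once to the object fuzzy
set u and once to the background fuzzy set 1-u — the two shadows form the
approximation region R_a = S1 union S2, the narrow band of pixels near the
current contour that the local model updates each sweep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import as_membership
from .exceptions import ParameterError

__all__ = ["ShadowedThreshold", "v_objective", "optimal_alpha", "boundary_region"]


@dataclass(frozen=True)
class ShadowedThreshold:
    """Optimal shadowed-sets threshold for one fuzzy set."""

    alpha_opt: float
    v_value: float
    u_max: float
    u_min: float


def v_objective(values: np.ndarray, alpha: float) -> float:
    """Shadowed-sets balance objective V(alpha) = |psi1 + psi2 - psi3|."""
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        raise ParameterError("empty membership multiset")
    u_max = v.max()
    psi1 = v[v <= alpha].sum()
    psi2 = (u_max - v[v >= u_max - alpha]).sum()
    psi3 = np.count_nonzero((v > alpha) & (v < u_max - alpha))
    return float(abs(psi1 + psi2 - psi3))


def _alpha_grid(u_min: float, u_max: float, step: float) -> np.ndarray:
    """Grid {u_min, u_min+step, ...} up to (u_max+u_min)/2, both ends included."""
    half = 0.5 * (u_max + u_min)
    if half <= u_min:
        return np.asarray([u_min])
    grid = np.arange(u_min, half, step)
    if half - grid[-1] > 1e-15:
        grid = np.append(grid, half)
    return grid


def optimal_alpha(values: np.ndarray, alpha_step: float = 0.001) -> ShadowedThreshold:
    """Exhaustive grid minimiser of V(alpha) over [U_min, (U_max+U_min)/2].

    Ties are broken toward the smallest alpha. The evaluation is vectorised
    over the grid with prefix sums of the sorted values, but is numerically
    identical to evaluating :func:`v_objective` at every grid point.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        raise ParameterError("empty membership multiset")
    if alpha_step <= 0:
        raise ParameterError("alpha_step must be > 0")
    u_min = float(v.min())
    u_max = float(v.max())
    alphas = _alpha_grid(u_min, u_max, alpha_step)

    sv = np.sort(v)
    csum = np.concatenate(([0.0], np.cumsum(sv)))
    n = sv.size
    # psi1(a) = sum of values <= a
    k1 = np.searchsorted(sv, alphas, side="right")
    psi1 = csum[k1]
    # psi2(a) = sum of (u_max - value) over values >= u_max - a
    k2 = np.searchsorted(sv, u_max - alphas, side="left")
    cnt_hi = n - k2
    psi2 = u_max * cnt_hi - (csum[n] - csum[k2])
    # psi3(a) = count of values strictly between a and u_max - a
    psi3 = np.maximum(k2 - k1, 0)
    vvals = np.abs(psi1 + psi2 - psi3)
    i = int(np.argmin(vvals))  # argmin returns the first (smallest alpha) tie
    return ShadowedThreshold(
        alpha_opt=float(alphas[i]), v_value=float(vvals[i]), u_max=u_max, u_min=u_min
    )


def boundary_region(membership: np.ndarray, alpha_step: float = 0.001) -> np.ndarray:
    """Approximation region R_a = S1 union S2 around the current contour.

    S1 is the shadow of the object fuzzy set u, S2 the shadow of the
    background fuzzy set 1-u, each from its own optimal threshold:

        S1 = {alpha1 <  u  < max(u)  - alpha1}
        S2 = {alpha2 < 1-u < max(1-u) - alpha2}.

    The inequalities are strict, so extreme membership values are never part
    of the band; a crisp {0, 1} map yields an empty band (legal — the caller
    decides the fallback).
    """
    u = as_membership(membership)
    t1 = optimal_alpha(u, alpha_step)
    ub = 1.0 - u
    t2 = optimal_alpha(ub, alpha_step)
    s1 = (u > t1.alpha_opt) & (u < u.max() - t1.alpha_opt)
    s2 = (ub > t2.alpha_opt) & (ub < ub.max() - t2.alpha_opt)
    return s1 | s2
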