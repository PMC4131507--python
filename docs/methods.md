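# Methods

## The segmentation model

`facseg` segments a single-channel image `I(x,y)` into an object and a
background region by minimising a fuzzy region-competition energy over a
membership map `u(x,y) ∈ [0,1]`. The contour is the 0.5 level of `u`; the
object region is the strict superlevel set `{u > 0.5}` (the tie `u = 0.5`
belongs to the background, so "object" always means strictly more object
than background).

**Global baseline (FAC).** The baseline energy is

    F(u, c1, c2) = λ1 Σ u^m (I − c1)² + λ2 Σ (1−u)^m (I − c2)²

with two scalar prototypes: `c1 = Σ u^m I / Σ u^m` and
`c2 = Σ (1−u)^m I / Σ (1−u)^m`, the membership-weighted mean intensities of
the two regions. Both half-minimisations are closed-form: for fixed
prototypes the optimal membership at each pixel is

    u = 1 / (1 + (λ1 (I − c1)² / λ2 (I − c2)²)^(1/(m−1))),

and `run_fac` alternates the two until the energy stalls. The curve-length
regulariser that usually completes this family of models is omitted
throughout: it matters for very noisy data and plays no role in the
minimisation implemented here. This baseline assumes each region is
globally well summarised by one constant — precisely the assumption that
intensity-inhomogeneous images (bias fields, illumination ramps) violate:
when the two intensity ranges overlap, no pair of constants separates them
and large parts of the object are absorbed into the background. The
baseline exists to quantify that failure.

**Local model (LFAC).** The local model replaces the constants by
spatially varying prototypes computed over a truncated Gaussian window,

    c1(x,y) = Σ_w u^m g I / Σ_w u^m g,   g(d) = (1/(2πσ)) exp(−d²/2σ²),

(`c2(x,y)` analogously with `(1−u)^m`), and minimises

    F = Σ u^m (I − c1(x,y))² + Σ (1−u)^m (I − c2(x,y))².

Minimisation is per pixel: each candidate `u_n` is the closed-form update
evaluated with the pixel's local prototypes, and it replaces the old value
`u_o` only when the closed-form energy difference

    ΔF = (u_n^m (s1/(s1+u_n^m−u_o^m))² − u_o^m)(I−c1)²
       + ((1−u_n)^m (s2/(s2+(1−u_n)^m−(1−u_o)^m))² − (1−u_o)^m)(I−c2)²

is strictly negative, where `s1 = Σ_w u^m g` and `s2 = Σ_w (1−u)^m g` are
the prototype denominators. ΔF is *exact* for the change of the pixel's own
energy term when its membership moves from `u_o` to `u_n` and the
prototypes are re-derived with the new value — provided the weight sums
count the centre pixel with weight 1. The default `center_weight="unit"`
convention therefore rescales `s1, s2` by `1/g(0)` before applying the
rule; the oracle test in the suite confirms exact agreement with a
from-scratch rebuild of the pixel energy. (`center_weight="printed"` keeps
the raw kernel normalisation, under which the rule is only approximate.)

Within one sweep the prototype field is computed once, from the membership
at sweep start, and all per-pixel decisions are taken against it
(Jacobi-style). This makes sweeps order-independent and exactly reducible:
with a uniform window covering the whole image, one full-domain sweep
equals one baseline sweep — the property the test suite checks. A
sequential (Gauss–Seidel) scan that refreshes prototypes after every pixel
was evaluated during development; it converges to the same attractors on
the synthetic suite but breaks the reduction property and order
independence, so the simultaneous sweep is used.

## The update band

Curve-evolution practice restricts updates to a band near the current
contour, for speed and because pixels far from the contour should not be
re-labelled by a local model (see "evidence" below). Two band constructions
are implemented:

* **Morphological band**: crisp the map at 0.5, take the one-pixel
  boundary (the mask minus its erosion by a 3×3 square), dilate by a disk
  of radius 5. Erosion pads beyond the frame with foreground so the image
  frame itself never counts as a contour.
* **Shadowed-sets band**: treat the membership values as a fuzzy set and
  split it three ways with the threshold `α` minimising
  `V(α) = |ψ1 + ψ2 − ψ3|`, where `ψ1` is the membership mass reduced to 0
  below `α`, `ψ2` the mass elevated to 1 above `U_max − α`, and `ψ3` the
  number of values left in between (the shadow). The balance is searched
  exhaustively on an `α`-grid of step 0.001 over
  `[U_min, (U_max+U_min)/2]`, ties toward the smaller `α` (the more
  conservative, larger shadow). Applied to the object set `u` and the
  background set `1−u`, the two shadows form the approximation region
  `R_a = S1 ∪ S2`.

A structural fact drives how the two are scheduled: *atoms* (large blocks
of identical membership values, e.g. the two-level seed partition) are
always priced out of the shadow — placing an atom of `N` values at level
`v` in the reduction/elevation terms costs `v·N` or `(1−v)·N`, strictly
less than the `N` it would cost in the shadow cardinality — so the shadow
of any crisp or piecewise-constant map is (near-)empty and cannot move a
crisp contour. The default schedule therefore runs in two phases:

1. **Bootstrap**: sweeps over the morphological band, growing/shrinking
   the contour from the seed until a sweep accepts no update.
2. **Refinement**: sweeps over the pure shadowed band, which by then
   consists of the genuinely uncertain halo around the locked contour,
   until it accepts nothing or empties.

The recorded `band_size_trace` is the update region actually used each
sweep; on the clean synthetic scene it ends far smaller than it starts
because the final shadow halo is thin. `band_method="morphological"` and
`"none"` (full-domain sweeps) are available for comparison; on the clean
scene all three produce the same final mask, the banded run simply visits
far fewer pixels.

## Evidence, and three guard rails

In a window where both regions are present, the two local prototypes
separate and the update is decisively informative. In a window that sees
only one smoothly varying region, both prototypes collapse onto the local
mean, the two residuals tie, and the formula prefers `u = 0.5` — the
energy genuinely rewards fuzziness where it cannot decide. Three small,
purely mechanical safeguards keep that indifference from corrupting the
labels; all three are exposed as parameters:

* `accept_tol = 1e-6` (squared-intensity units): ΔF must be below
  `−accept_tol` to be accepted. With exact arithmetic an evidence-free
  pixel has ΔF = 0 and is rejected by the strict inequality; in floating
  point the convolution-based prototypes are off by ~1e-13, giving
  ΔF ≈ −1e-26, and accepting such dust lets label noise diffuse through
  homogeneous regions. The default is ~1e-10 of a typical energy and
  filters only round-off.
* `contiguous_flips = True`: a pixel may cross the 0.5 level only when it
  is 8-adjacent to the opposite region. This implements the premise that
  the contour evolves gradually: without it, whenever noise tips an
  uncertain pixel across 0.5 the new speckle acquires its own contour,
  the band follows it, and mislabelling cascades through regions the
  model has no evidence about. Membership refinements that stay on one
  side of 0.5 are never restricted.
* Frame margin: pixels whose kernel window would be clipped by the image
  frame (a margin equal to the kernel radius) are never updated. A clipped
  window is one-sided, and its weighted mean is a biased estimate on any
  intensity gradient; the bias manufactures evidence exactly where there
  is none. The model therefore assumes objects do not touch the frame.

A consequence worth stating plainly: regions farther than the kernel
radius from every intensity edge carry no local evidence, and their labels
can only come from the seed partition. The synthetic scenes and the
default seed respect this (below); for real images it means the seed
should overlap each object of interest and should not bury large
featureless areas under the wrong label.

## Energy monotonicity

ΔF is exact for the centre pixel's own term but omits the change the
update induces in every *neighbour's* prototypes. The recomputed total
energy therefore descends only approximately: monotone to ~1e-4 relative
per sweep on most of the synthetic suite, but on strongly blurred edges
the neighbour coupling dominates — there are states where every candidate
update has ΔF < 0 while the total energy rises, so no per-pixel rule of
this form can descend the total there. An enforced-descent variant
(re-applying only the strongest updates until the total decreases) was
evaluated and rejected: it freezes evolution on blurred scenes and makes
the outcome depend on the seed. The per-pixel rule is kept as the model's
definition; the energy trace is reported as a diagnostic, not a Lyapunov
function.

## Parameters

| name | default | meaning |
|---|---|---|
| `m` | 2.0 | fuzziness exponent; 2 keeps `1/(m−1) = 1` and is the standard fuzzy-clustering choice (`m > 1` required) |
| `lambda1, lambda2` | 1.0 | region weights of the baseline energy; 1/1 balances the regions |
| `sigma` | 3.0 px | Gaussian window scale of the local prototypes; set it to the scale over which each region is roughly constant |
| `kernel_radius` | ceil(3σ) = 9 | window truncation; 3σ keeps >99% of the kernel mass |
| `epsilon` | 1e-2 | absolute stop threshold on the energy change (a relative variant is available via `relative_stop`) |
| `alpha_step` | 0.001 | shadowed-sets threshold grid step |
| `max_iters` | 500 | sweep cap |
| `init_inside / init_outside` | 0.8 / 0.2 | membership levels encoding a geometric seed |
| `accept_tol` | 1e-6 | numerical floor on accepted energy decreases |
| `contiguous_flips` | True | contour moves only by contact |
| `center_weight` | "unit" | centre-pixel weight convention in ΔF |

## The synthetic suite

The generators produce the situation the local model exists for: a
two-region scene whose intensity ranges overlap globally while local
contrast stays constant. The background ramps linearly across the columns
(20 → 120 by default); the object — a ring (centre (58, 75), radii 21/36)
with a detached concentric arch below it (radii 45/57, half-angle 35°) —
adds a constant offset (+60) on top of the local ramp value. Background
spans 20–120, object 80–180: overlapping ranges, fixed local contrast,
exact ground truth. Geometry choices are deliberate: object cross-sections
(15 px ring, 12 px arch) keep every object pixel within kernel reach of a
true edge, and the 9 px ring–arch gap keeps the background between them
within reach of both edges — on this scene the true segmentation is
locally decidable everywhere except in far-field background, which the
seed already labels correctly. The default seed rectangle (rows 75–109,
cols 60–89) covers the ring bottom, the gap and the arch top and contains
no evidence-free background.

Degradations, applied to the image only (ground truth stays the pre-blur
geometry): Gaussian boundary blur (σ = 2 px), additive Gaussian noise
(sd = 10 intensity units) and salt-and-pepper impulses (2% of pixels, half
salt half pepper, sampled without replacement), each strong enough to
perturb the overlap structure without swamping the 60-unit contrast. Blur
is applied before noise; clipping to [0, 255] is part of the noise model.
All randomness flows through the explicit scene seed; the clean scene is
fully deterministic.

What these scenes do *not* emulate: multiplicative/structured bias fields,
textured regions, partial-volume mixtures of more than two classes,
objects touching the frame, and correlated noise. Exact recovery on the
clean scene shows the machinery is consistent where its assumptions hold
exactly; it does not predict pixel-exact behaviour on real images, where
the same mechanisms (local separability within σ-windows, seeded far
field) hold only approximately.

## Problem sizes

All experiments run on the 143 × 150 scenes: the clean-scene fit takes a
few seconds on one core (≈56 sweeps), the noisy variants tens of seconds
(up to the 500-sweep cap on salt-and-pepper), and the four-scene benchmark
with both models about a minute and a half. The oracle cross-checks run on
grids up to 16 × 16 against quadruple-loop references and on 10⁴ fuzzed
single-pixel instances.

## Known limitations

* Strictly two-phase; no multi-region extension.
* No curve-length regularisation: boundaries may be rough on noisy data.
* Labels beyond kernel reach of any edge are seed-determined (by design;
  see "Evidence").
* The total energy is not monotone on strongly blurred edges (see "Energy
  monotonicity").
* The shadowed band needs a continuum of membership values to be
  informative; with crisp maps the morphological band does the work.
* 2-D single-channel only.
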