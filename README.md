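# facseg

Fuzzy active contour segmentation for grayscale images with intensity
inhomogeneity — smooth spatial intensity drift (illumination ramps, MR-style
bias fields) that makes the object and background intensity ranges overlap
and defeats global two-phase segmentation. Built for image-analysis work on
microscopy, radiography and other single-channel modalities where a region
of interest differs from its surroundings by *local* contrast rather than by
a global intensity band.

Two models share one interface:

* **`FuzzyActiveContour`** — the global-prototype baseline. It minimises the
  fuzzy region energy

  ```
  F(u, c1, c2) = λ1 Σ uᵐ (I − c1)² + λ2 Σ (1−u)ᵐ (I − c2)²
  ```

  over a membership map `u(x,y) ∈ [0,1]` and two scalar prototypes (the
  membership-weighted mean intensities inside and outside the contour,
  which is the 0.5 level of `u`). Alternating closed-form updates:
  `c1 = Σ uᵐI / Σ uᵐ`, `c2 = Σ (1−u)ᵐI / Σ (1−u)ᵐ`, and per pixel
  `u = 1/(1 + (λ1(I−c1)²/λ2(I−c2)²)^{1/(m−1)})`.

* **`LocalFuzzyActiveContour`** — the main model. The constants are replaced
  by spatially varying prototypes under a Gaussian window
  `g(d) = (1/2πσ)·e^{−d²/2σ²}`:

  ```
  c1(x,y) = Σ_w uᵐ g I / Σ_w uᵐ g        (c2 analogously with (1−u)ᵐ)
  ```

  and updates are confined to a narrow band near the current contour: a
  morphological band (dilated contour boundary) while the map is crisp, then
  the adaptive *shadowed-sets* region — the three-way split of the
  membership multiset by the threshold minimising `V(α) = |ψ1 + ψ2 − ψ3|` —
  once a continuum of uncertain memberships exists. Each band pixel takes
  the closed-form membership candidate and keeps it only if the exact
  per-pixel energy difference ΔF is negative.

Accuracy is scored as the percentage of mislabelled pixels,
`P_mp = (|R_mb| + |R_ms|) / (|R_b| + |R_s|) × 100`, with `R_mb` the missed
and `R_ms` the spurious object pixels.

A deterministic synthetic-scene generator (`facseg.synthetic`) reproduces
the conditions that matter — ramp background, constant local contrast,
blurred boundaries, Gaussian and salt-and-pepper noise — with exact ground
truth, so everything here runs without external data.

## Worked example

```python
from facseg import LocalFuzzyActiveContour, FuzzyActiveContour
from facseg.synthetic import make_ramp_ring

image, truth = make_ramp_ring()          # 143x150, ramp 20->120, offset +60
res = LocalFuzzyActiveContour(image).fit()
print(res.summary())
print("P_mp vs truth: %.2f%%" % res.score(truth))
print("FAC baseline P_mp: %.2f%%" % FuzzyActiveContour(image).fit().score(truth))
```

prints

```
LocalFuzzyActiveContour segmentation results
==============================================
image shape        : 143 x 150
model              : lfac
m (fuzziness)      : 2
sigma / radius     : 3 / 9
epsilon            : 0.01
iterations         : 56
converged          : True
final energy       : 31368.1
object pixels      : 3431 (16.00% of image)
total pixel visits : 224051
P_mp vs truth: 0.00%
FAC baseline P_mp: 53.48%
```

The scene's background ramps from 20 to 120 across the image while the
object (a ring and a detached arch) sits a constant +60 above its local
background, so object and background intensity ranges overlap globally. The
global baseline absorbs the brighter half of the background into the object
(P_mp 53.48%); the local model recovers the ground truth exactly (P_mp 0).
`res.band_size_trace` records the per-sweep update region — 1346 pixels
around the seed at the start, 14 in the final shadow band — and
`res.plot(truth=truth)` overlays the contour on the image.

The same pipeline is scriptable from the shell:

```
facseg gen --scene clean --outdir scenes/
facseg segment --image scenes/clean_image.tif --truth scenes/clean_truth.png \
               --model lfac --outdir out/
facseg score scenes/clean_truth.png out/mask.png
facseg bench --outdir bench/          # P_mp table, FAC vs LFAC, four scenes
```

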