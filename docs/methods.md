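# Methods

## Scope and data model

All computation happens on 2-D float64 grayscale images. Integer rasters
(8/16-bit PNG/TIFF) are normalized to [0, 1] by their bit-depth maximum on
read, so intensity-scaled parameters (Perona–Malik `k`, bilateral `tau_r`)
mean the same thing regardless of source depth; `raw=True` keeps native
units. Multi-channel input is rejected unless explicitly converted to
luminance, because every operation here is scalar-valued.

Regions of interest are rectangles (half-open integer bounds) or discs.
Disc membership is tested at pixel centers: (i−ci)² + (j−cj)² ≤ r², with
0-based (row, column) coordinates. Region statistics use the population
standard deviation (divide by n) throughout; a `ddof=1` switch selects the
sample convention. The choice is a convention, not a result: the metrics
only require that the same convention be used on both sides of every ratio.

## Quality metrics

SNRe = μ/σ over a uniform region; CNRe compares equal-size feature and
background regions. Two CNRe normalizations circulate in the elastography
literature and the linear-over-root form 2(μa−μb)/√(σa²+σb²) is the
default here, with the squared form 2(μa−μb)²/(σa²+σb²) behind
`variant="squared"`; reports always record the variant, so numbers are
never silently mixed. Growth rates are recomputed from the stored
before/after values, making every report internally consistent by
construction.

Degenerate inputs are errors, not infinities: a constant region (σ = 0)
raises `DegenerateRegionError`, as do unequal-size ROI pairs and
non-positive strain means. The strain ratio operates on a user-supplied
(or phantom-generated) strain image; this package does not estimate strain
from RF or displacement data.

## Filters

**Bilateral.** Direct windowed implementation: for each offset in the
(odd, ≥ 3) window the spatial weight exp(−(dy²+dx²)/2τ_d²) and range
weight exp(−ΔI²/2τ_r²) multiply the shifted image, and the accumulated sum
is normalized per pixel. Cost is O(window² · pixels). In the τ_r → ∞ limit
this reduces exactly to a windowed spatial-Gaussian mean, which is the
oracle the tests compare against.

**Heat diffusion.** The linear heat equation's solution at time t is
Gaussian convolution at scale σ = √(2t) (one sometimes sees σ² written
conflated with 2t; the square root is what makes the impulse response
match the closed-form 2-D Gaussian, and the tests verify that at t = 2,
σ = 2). Implemented with `scipy.ndimage.gaussian_filter`; t = 0 returns
the input bit-exactly.

**Perona–Malik.** Classic explicit 4-neighbor scheme,
E_u ← E_u + λ Σ_t c(|E_t−E_u|)(E_t−E_u), with the per-neighbor "gradient"
being the plain intensity difference. Both classic conductivities are
provided; `exponential` is the default variant. λ is validated to
(0, 0.25], the stability bound of the explicit 4-neighbor scheme, with
0.2 the conventional denoising default. Iteration count defaults to 100.

*Boundaries.* All filters reflect at the border (Neumann). Note the
convention: the edge-repeating reflection (numpy pad mode `symmetric`,
scipy mode `reflect`). With this convention each border pixel's mirrored
neighbor is itself, the boundary flux vanishes, and one diffusion step
conserves the image sum to floating precision — a property the tests
assert at 1e−9 relative. The non-repeating mirror (numpy `reflect`) would
leak flux through the border. `boundary="nearest"` (edge replication) is
available and shares the conservation property.

*Threshold heuristic.* `suggest_k` returns a percentile (default 90th) of
the pooled absolute nearest-neighbor differences of the input — the same
quantity the scheme itself thresholds, rather than a central-difference
gradient, which on pure noise is smaller by about √2 and would
systematically under-diffuse. This is a labeled starting-point heuristic;
adaptive k selection is out of scope.

## Synthetic phantom

The generator emulates the geometry the metrics presuppose: a uniform
tissue background with one disc lesion. Defaults, chosen once: 256×256
pixels, background level 0.4, lesion contrast 2.0 (lesion level 0.8),
lesion radius 40 px, speckle with L = 4 looks, no additive noise, seeded
`numpy.random.default_rng`. Speckle is unit-mean multiplicative
Gamma(L, 1/L) noise — the standard fully-developed-speckle intensity
model — so a uniform region of the noisy image has mean equal to its clean
level and standard deviation level/√L, giving raw background SNRe = √L.
That moment identity is the generator's acceptance surface: the tests
recover √L within 10% for L ∈ {1, 4, 16}.

The ROI pair is a disc concentric with the lesion at 70% of its radius and
an equal-radius disc on the same image row in the background, 4 px clear of
the lesion boundary. Equal pixel counts hold exactly because the background
disc is an integer translate of the feature disc. The lesion radius (40 px)
makes each ROI ≈ 2450 px, keeping Monte-Carlo fluctuations of region means
near 1%.

The strain phantom sets the lesion level to background/contrast (a stiff
lesion strains less), so the clean-image strain ratio equals the configured
contrast exactly, and speckled measurements scatter around it.

What the phantom does *not* emulate: correlated speckle (real speckle has a
point-spread-function-sized grain, ours is i.i.d. per pixel), attenuation,
depth-dependent gain, scan conversion, or any acoustic physics. Passing
these tests therefore demonstrates correctness of the algorithms and
metrics under the stated noise model, not clinical performance.

## Convergence tracing

`trace_convergence` records SNRe (background ROI) and CNRe after every
Perona–Malik iteration, including iteration 0. The qualitative observation
it operationalizes is that both metrics plateau as diffusion proceeds.
"Stabilized at s" means: every per-iteration relative change
|x_{i+1}−x_i|/|x_i| of both metrics is below the tolerance (default 1%)
for all i ≥ s. A trace still moving at its final step is reported as not
stabilized. The per-step definition was chosen over the total spread of
the trailing window because the late-stage diffusion drifts steadily at
~0.3% per iteration: a spread criterion integrates that drift over the
window and would call a visibly flat trace unstable, while the per-step
criterion matches where the plateau visibly begins. On the default
phantom ensemble (10 seeds, heuristic k, λ = 0.2, 120 iterations) the
trace stabilizes in the 30–75 iteration range and background SNRe
strictly increases on every seed.

## Problem sizes and numerical choices

The test suite and the acceptance script run phantoms at 256×256 (the
metric/convergence surface) and filter-property checks at 32–96 px, sizes
at which every Monte-Carlo tolerance above has comfortable margin. Frozen
single-pixel oracles (a 9-term bilateral sum and a 4-term diffusion update
on a 3×3 fixture) were expanded by hand before implementation and are
asserted to 1e−12/1e−15. Ties in quantization round half away from zero
via `np.rint`'s banker-rounding — the round-trip bound (half a step) holds
either way. All report serialization is plain JSON/CSV.

## Known limitations

- Speckle is i.i.d. per pixel; no spatial correlation.
- No SRAD/OSRAD-style speckle-specific diffusion; `k` is global and fixed
  per run.
- The strain ratio consumes a strain image; no strain estimation.
- No DICOM, 3-D volumes, or RF-domain processing.
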