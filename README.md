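# elastoqc

Speckle denoising and image-quality assessment for 2-D ultrasound
(elastography) images: a tested library plus a small CLI implementing three
classic smoothers — the bilateral filter, linear heat diffusion, and
Perona–Malik anisotropic diffusion — and the region-based quality metrics
used to score them (SNRe, CNRe, their growth rates, and the strain ratio).
It is aimed at people evaluating denoising schedules for ultrasound B-mode
or elastography frames, and ships a synthetic lesion-phantom generator so
the whole pipeline can be validated against known ground truth without
clinical data.

## The metrics

For a uniform region with mean μ and standard deviation σ,

    SNRe = μ / σ

For an equal-size feature (lesion) region *a* and background region *b*,

    CNRe = 2 (μ_a − μ_b) / √(σ_a² + σ_b²)

(a squared variant 2(μ_a − μ_b)²/(σ_a² + σ_b²) is available behind a switch;
every report records which was used). Growth rates compare a filtered image
to its input:

    SNRe′ = 100 · (SNRe_after / SNRe_before − 1),   likewise CNRe′

and the strain ratio of an elastography strain image is
SR = mean strain(background) / mean strain(lesion).

## The filters

* **Bilateral** — windowed weighted mean with Gaussian weights
  exp(−d²/2τ_d²)·exp(−Δ I²/2τ_r²) in spatial distance and intensity
  difference.
* **Heat diffusion** — ∂E/∂t = ΔE, solved as Gaussian convolution at scale
  σ = √(2t).
* **Perona–Malik** — explicit 4-neighbor scheme
  E_u ← E_u + λ Σ_t c(|E_t − E_u|)(E_t − E_u) with conductivity
  c(g) = exp(−(g/k)²) or 1/(1+(g/k)²); λ ∈ (0, 0.25] (default 0.2),
  reflecting boundaries, so the scheme conserves total intensity and obeys
  the extremum principle. `suggest_k` offers a heuristic threshold (90th
  percentile of neighbor differences) — a pragmatic default, not an adaptive
  estimator.

## The phantom

`make_phantom` builds a uniform background (level 0.4) with a disc lesion
(contrast 2.0), multiplied by unit-mean Gamma speckle with L looks, and
places an equal-size, non-overlapping feature/background ROI pair. Under
this noise model the background SNRe of the raw image is √L, which is the
generator's own self-check.

## Worked example

```sh
elastoqc phantom --out-dir bundle
echo '{"filter": "pm", "k": "auto", "lam": 0.2, "iterations": 100}' > pm.json
elastoqc denoise --image bundle/noisy.tif --rois bundle/rois.json \
    --config pm.json --out-image denoised.tif --report report.json
elastoqc trace --image bundle/noisy.tif --rois bundle/rois.json \
    --config pm.json --out-csv trace.csv
```

prints

```
phantom written to bundle
SNRe 2.0109 -> 32.9520 (+1538.70%), CNRe 1.7314 -> 6.0284 (+248.17%)
stabilized at iteration 44 (tol 1.0%)
```

Reading: the raw phantom's background SNRe is 2.01 ≈ √L for L = 4 speckle
looks; 100 Perona–Malik iterations raise it to 33.0 and raise lesion
contrast-to-noise from 1.73 to 6.03; the per-iteration SNRe/CNRe trace
settles (every subsequent step changes both metrics by < 1%) from iteration
44 onward. The same operations are available as library calls
(`elastoqc.make_phantom`, `elastoqc.run_denoise`,
`elastoqc.trace_convergence`); `elastoqc compare` runs several filter
blocks and writes one CSV table of before/after metrics.

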