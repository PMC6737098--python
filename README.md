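# retspm

Statistical parametric mapping of retinal layer thickness from segmented
macular OCT volumes.

## What problem this solves

Neurodegeneration thins the retina, but the thinning is *spatially
structured*: averaging thickness over large ETDRS-style sectors washes out
localized deficits. `retspm` implements a pixel-level analysis of
per-layer thickness maps for two-group comparisons (e.g. patients with
early Alzheimer's disease vs age-matched controls): it answers *where*
each of the 10 retinal layers (NFL, GCL, IPL, INL, OPL, ONL, IS/OS, OSL,
OPR, RPE) is significantly thinner or thicker, with family-wise error
control over the thousands of correlated pixel tests.

The package is aimed at imaging scientists who already have segmented
surfaces (11 delimiting surfaces per volume, e.g. from graph-based
segmentation of a 6 × 6 mm, 512 × 128 A-scan raster) and want a tested,
reproducible implementation of the full analysis chain — plus a synthetic
cohort generator with known ground truth, so every stage is testable
without patient data.

## The analysis chain

For each subject and layer:

1. **Raw thickness** `T′(x, y)` — depth difference of the two delimiting
   surfaces along the A-scan.
2. **Tilt correction** `T = T′ cos α` — the A-scan is not orthogonal to
   the retina; `α` combines three fitted unit normals: global tilt `U`
   (plane fit to the outer RPE boundary, angle γ), spherical tilt `V`
   (eye-curvature sphere from a circle fit to the central B-scan, angle
   σ), and local tilt `W` (windowed plane fit to the layer's medial
   surface in the flattened volume, angle λ); `α` is the angle between
   the A-scan axis and `U + V + W`.
3. **Spatial normalization** — left eyes mirrored; similarity transform
   placing the fovea at the grid centre, the fovea→papilla axis at
   θ = 6.766° and the papilla at s = 4.377 mm (configurable canonical
   values).
4. **Preprocessing** — bilinear resize 128 × 512 → 512 × 512; mask-aware
   Gaussian smoothing (default FWHM 1 mm, respecting the rule
   FWHM > 4 × coarser pixel pitch = 187.5 µm).
5. **Inference** — pixelwise pooled-variance t Gaussianized to z; height
   threshold `Z_c` from the Gaussian random-field expected Euler
   characteristic (`ρ₂(z) = 4 ln 2 · (2π)^{-3/2} z e^{-z²/2}`, 17 resels
   for the 3.5 mm fovea-centred circle, α_FWE = 0.05, one-sided), with a
   max-statistic permutation test as the assumption-free fallback.
6. **Descriptive indices** — thinned/thickened area percentages
   (t₀/T₀ and the >1 SD variants t₁/T₁) and volume ratios (v₀/V₀/v₁/V₁)
   over the central 4.8 × 4.8 mm square, with cross-layer one-sample t
   and exact Wilcoxon tests over the nine neural layers.
7. **Overlap** — Jaccard index `J = C/(A + B − C)` for every layer pair's
   thinned (or thickened) masks, tested exactly under the hypergeometric
   null with Bonferroni control at 0.05/(2 × 45).

## Worked example

Simulate a small cohort with a single planted 20 µm GCL thinning blob,
run the chain and fit the group-difference SPM:

```python
import numpy as np
from retspm import (CohortSpec, EffectBlob, generate_cohort, tilt_correct_subject,
                    normalize_subject, NormalizationParams, resample_maps,
                    gaussian_smooth, SmoothingSpec, build_search_region, ThicknessSPM)

spec = CohortSpec(n_patients=8, n_controls=8, seed=42,
                  effects=[EffectBlob((-0.8, 0.1), 0.8, -20.0, "GCL")])
cohort = generate_cohort(spec)

params, smooth = NormalizationParams(), SmoothingSpec((1.0, 1.0))
maps, groups = [], []
for oct_, group in cohort:
    thickness, _ = tilt_correct_subject(oct_, layers=["GCL"])
    normed = normalize_subject(thickness, oct_.fovea_xy_mm, oct_.papilla_xy_mm,
                               oct_.eye, params)
    grid = gaussian_smooth(resample_maps(normed["GCL"], (256, 256)), smooth)
    maps.append(grid.values); groups.append(group)

maps = np.array(maps); is_pat = np.array([g == "patient" for g in groups])
region = build_search_region((256, 256), (6.0, 6.0), smooth, resel_override=17.0)
model = ThicknessSPM(maps[is_pat], maps[~is_pat], region, layer_id="GCL")
res = model.fit(method="both", n_perm=500, seed=42)
print(res.summary())
```

This prints:

```
SPM results: layer GCL, direction thinner
========================================================
groups                 n=8 patients, n=8 controls (df=14)
search region          17532 px circle, 17.0 resels (area-based 9.63)
z range in region      [-4.212, 0.852]
RFT critical Zc        3.2464 (alpha_FWE=0.05)
significant pixels     2592 (1.424 mm^2)
permutation min p      0.002 (4857 px significant)
```

Reading it: the most extreme z in the fovea-centred search circle is
−4.21 (patients thinner), well past the random-field critical height
3.2464, so 1.42 mm² of the GCL — at the planted blob's location — is
declared significantly thinned at a 5% family-wise error level; the
permutation test agrees (minimum corrected p = 1/500).

The same chain end-to-end, as one call or from a shell:

```python
from retspm import PipelineConfig, run_pipeline
report = run_pipeline(PipelineConfig())   # 19 vs 24 subjects, all layers
```

```bash
retspm run-all --seed 1 --out results/
retspm simulate --out cohort/            # write per-subject containers
```

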