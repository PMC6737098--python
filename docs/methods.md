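# Methods

This note records the models, conventions and numerical choices behind
`retspm`, in the spirit of a package methods appendix: what is computed,
under which assumptions, and where the genuinely open design decisions
were resolved.

## Coordinate conventions

Grids are `[row, col]` with row 0 superior; physical coordinates are mm
in a scan-centred frame, x temporal→nasal (after right-eye
standardization), y superior, pixel centres at `(i + 0.5) × pitch`.
Depth z (µm) grows away from the pupil; the A-scan axis A is the unit
vector toward the pupil, and all fitted normals are oriented into A's
hemisphere before use. The default acquisition geometry is a 6 × 6 mm
raster of 128 B-scans × 512 A-scans (pitch 11.71875 × 46.875 µm, depth
quantum 3.5 µm).

## Tilt model and its accuracy

Measured ("raw") thickness runs along the A-scan, which is generally not
orthogonal to the retina; a slab of orthogonal thickness T inclined at
angle θ measures `T / cos θ`. The correction `T = T′ cos α` uses three
fitted components:

* **Global tilt γ** — normal of the ordinary-least-squares plane (in z)
  through all valid outer-RPE points. At tilts ≤ 15° OLS-in-z and total
  least squares differ negligibly, so OLS is used throughout.
* **Spherical tilt σ(x, y)** — a circle is fitted to the central B-scan
  of the outer RPE boundary (algebraic Kåsa fit refined by Gauss–Newton
  geometric least squares, exact to machine precision on noise-free
  arcs) and revolved into a sphere; V points from each retinal point to
  the sphere centre. Fits whose radius exceeds a configurable maximum
  (default 500 mm, i.e. an essentially flat B-scan) raise an error; the
  subject-level driver then substitutes V = A, σ = 0. Apparent eye
  curvature of ~35 mm reproduces the few-degree corner tilts seen on
  6 mm scans. The fit uses the native (unflattened) volume.
* **Local tilt λ(x, y)** — per-pixel plane fit over a 0.5 × 0.5 mm
  window of the layer's medial surface in the flattened volume
  (outer-RPE depth subtracted per A-scan). The fit is solved in closed
  form from windowed moments via box filters, which makes the per-pixel
  cost independent of window size. Windows are truncated at borders;
  pixels whose window holds < 50% valid samples are invalidated. All
  fits run in physical µm coordinates so the ~4:1 pitch anisotropy
  cannot bias the normals.

The combined angle α is taken between A and the *unweighted sum*
U + V + W of the three unit normals. Because each normal is near A, this
average attributes roughly one third of a single component's inclination
to α: when only one source of tilt is present the correction removes
only part of the measurement excess (e.g. a pure 10° global tilt on a
300 µm retina leaves ~2.5 µm of the 4.7 µm raw excess). This is an
intrinsic property of the three-normal average, which guards against
over-correction when the components partially double-count the same
physical tilt (the sphere fit absorbs part of the global tilt; the
flattened medial surface excludes both). Accordingly:

* each *component estimator* plus the cosine correction recovers slab
  thickness within 1 µm at the observed extreme angles (10° global, 7°
  spherical at scan corners, 14.4° local at thin-layer scale) — this is
  what the acceptance suite verifies;
* the *end-to-end* corrected thickness of individual layers
  (≈ 15–65 µm) is accurate to well under 1 µm at default tilt scales,
  while the 300 µm total retina can retain a ~2 µm residual at extreme
  combined tilt. Total-retina correction uses γ and σ only (a single
  "medial surface of the whole retina" has no meaningful local scale).

## Spatial normalization

Similarity transform only (translate/rotate/scale): the fovea centre maps
to the output-grid centre, the maculopapillar axis to θ = 6.766° above
the temporal→nasal axis, and the papilla to s = 4.377 mm from the fovea.
θ and s are configuration defaults (sample means of the study that
motivated them); the synthetic generator draws per-subject axes around
them. Thickness values are transported, never rescaled — scaling acts on
x–y geometry, thickness is a z-quantity. Resampling is inverse-mapped
bilinear interpolation; an output pixel is invalid if any of its four
source neighbours is invalid or out of bounds (conservative masks).
Left eyes are mirrored (with their landmarks) before the transform.
Macula and papilla are assumed co-registered in one frame; co-registering
separately acquired scans is out of scope.

## Smoothing, search regions, resels

Maps are resized to 512 × 512 (bilinear, aligned pixel centres) and
smoothed with an isotropic Gaussian, default FWHM (1, 1) mm — above the
187.5 µm minimum implied by the >4 × voxel rule at the native pitch.
Smoothing is normalized convolution: invalid pixels carry zero weight,
the smoothed mask renormalizes the result, and outputs with in-support
weight < 0.5 are invalidated; this doubles as the boundary policy (no
reflective padding). Smoothing is applied per subject, after
normalization and resampling, before any group statistic.

Two search regions are built around the fovea: a 4.8 × 4.8 mm square for
the descriptive indices and a 3.5 mm-diameter circle for random-field
inference. The area-based resel count of the circle at 1 mm FWHM is
~9.6; the pipeline's default is a pinned override of 17 resels, kept as
configuration because the area formula and the pinned value are both
exposed (`resels_area` vs `resels`) and the origin of the larger count
(possibly boundary-corrected counting) cannot be recovered from the
area formula alone. A larger resel count raises the threshold, so the
default is conservative; measured family-wise false-positive rates on
matched-smoothness null cohorts land at ~2–4% for nominal 5%.

## Inference

Per pixel, a pooled-variance two-sample t (df = n₁ + n₂ − 2) over the
subjects valid at that pixel; pixels lacking any subject's data leave
the search region. The t map is Gaussianized by the tail-preserving
probability integral transform `z = Φ⁻¹(F_t(t))` (standard SPM
practice), sign convention negative = thinner in patients. Height
thresholding declares significant exactly the in-region pixels with
supra-threshold |z| in the tested direction; `Z_c` solves
`E[EC](z) = α` using the 2D Euler-characteristic area term
`R · 4 ln 2 (2π)^{-3/2} z e^{-z²/2}` (boundary R₀/R₁ terms are
implemented but off by default, matching area-style resel counting).
Solved by Brent's method on (1, 10); 17 resels at α = 0.05 gives
Z_c ≈ 3.2464.

The permutation fallback recomputes the z map under relabelings sampled
without replacement (exhaustive when ≤ `n_perm` distinct labelings
exist; the observed labeling always included) and corrects each pixel by
the null distribution of the in-region extremum — the max-statistic
construction with strong FWE control. Assumption checks are per-pixel
Shapiro–Wilk per group and median-centred Levene between groups;
constant-data pixels are flagged degenerate, not violating.

## Thinned/thickened indices

Classification uses the patient-minus-control mean map over the analysis
square: thinned = diff < 0, thickened = diff > 0 (strict, so zero-pixels
belong to neither side), and the ">1 SD" variants additionally require
|diff| > SD of the per-pixel difference distribution of that layer over
the square — the SD printed beside the difference histogram, not a
per-pixel sampling SD. Volume ratios divide by the patient group's mean
volume over the square (Σ mean_patient × pixel area). Cross-layer
dominance over the nine neural layers (RPE excluded) is tested with a
one-sample t (df = 8) on the t−T differences and an exact Wilcoxon
signed-rank test (T = smaller rank sum; with all nine differences
positive, T = 0 and two-sided p = 2/2⁹ ≈ 0.0039) on the v−V differences.

## Exact overlap tests

For layer pair masks with counts (N, A, B, C), J = C/(A + B − C)
(J := 0 for two empty masks). Significance is computed under the null of
independent uniform placement of an A-set and a B-set in the N-pixel
domain, i.e. C ~ hypergeometric(N, A, B) — the standard exact null for
set overlap. Two-sided p by the point-probability method (sum of all
outcome probabilities ≤ the observed one, with a 1e-12 relative tie
tolerance in floating point); a doubled-smaller-tail variant is
available. Probabilities are evaluated from the log-pmf with a max-shift
exponential sum; an mpmath arbitrary-precision path cross-checks the
log-space result (agreement to 6 significant digits at N = 512² scale).
Bonferroni control at 0.05/(2 × 45) covers the 45 thinned plus 45
thickened pairs; star grades are assigned on family-wise adjusted p.

Caveat: pixels of smoothed maps are not exchangeable — spatial
autocorrelation makes pixel-resolution p values anti-conservative. A
resel-resolution mode (masks evaluated on a 1 mm block grid) is provided
as a conservative variant; the pixel-resolution default matches the
classical presentation of such tables.

## Synthetic cohorts: what they emulate, and what they do not

The generator produces segmented-surface volumes, not OCT images: no
speckle, no segmentation algorithm, no vendor formats. Per subject:

* **Baselines** — radially symmetric analytic templates around the
  fovea: parafoveal rings and a foveal pit (inverted Gaussian, σ 0.30 mm,
  ~95% pit depth) on the inner layers, a foveal ONL peak, flat outer
  bands, a mild nasal NFL gradient. Templates are scaled so the control
  scan-mean total is exactly 286.5 µm (per-layer means ≈ 37/33/32/32/27/
  62/24/15/10/16 µm). No published per-layer variance maps constrain the
  spatial texture; only geometry and summary statistics do.
* **Noise** — per layer, a subject-level scalar offset
  (SD 13% of the layer mean; gives ~13 µm between-subject SD of
  scan-mean total thickness, matching the 11.9–16.9 µm summary range)
  plus a smooth zero-mean field (SD 8% of the layer mean) built by
  Gaussian-filtering white noise to a known FWHM (default 1 mm, circular
  boundary, analytically renormalized to unit pointwise variance) — so
  the field smoothness assumed by RFT is exactly controllable.
* **Effects** — isotropic Gaussian blobs (radius = half width at half
  maximum; support = that disc) added to patients. The default set
  plants parafoveal thinning in NFL/GCL/IPL/INL/ONL/OSL/OPR and mild RPE
  thickening, sized to a ~5 µm scan-mean total deficit. Note the
  *observed* cohort deficit fluctuates around the planted value with
  SE ≈ 4 µm at n = 19/24 — as in any real cohort of this size.
* **Tilt** — global plane (uniform 0–3°, random azimuth), spherical sag
  (apparent radius 35 ± 3 mm), and a smooth 3 µm-SD undulation of the
  outer RPE boundary. Surfaces are stacked from the outer RPE upward
  with along-A-scan thickness `T/cos θ`, θ the analytic orientation of
  each layer's medial surface, so the true orthogonal thickness is known
  exactly. Thickness gradients themselves (pit walls) generate realistic
  local tilt of >10° in inner layers near the fovea.
* **Dropout and laterality** — smooth random blobs covering
  `dropout_rate` (default 2%) of the area are marked invalid; subjects
  are left-eyed with probability 4/43 and mirrored whole. Negative
  thickness (deep pit + strong thinning) is clamped to a 0.5 µm floor
  with a per-subject warning counter, or the subject is redrawn.
* **Determinism** — subject seeds derive from `(cohort seed, index)` via
  `numpy.random.SeedSequence`; identical specs are bit-reproducible.

Because baselines are analytic and noise is Gaussian and stationary,
passing tests demonstrate the *statistical machinery* (calibration,
recovery, exactness), not robustness to real segmentation pathology,
vascular shadows or non-Gaussian thickness distributions.

## Problem sizes used by the acceptance script

Calibration quantities are measured at the sizes a laptop CPU handles in
minutes: the family-wise error rate on 500 null cohorts of 43 subjects
at a 128 × 128 analysis grid (the statistic is grid-resolution
independent once the kernel spans many pixels); blob recovery on 50
cohorts at the same grid; the full pipeline once at the native
512 × 512 analysis resolution with all 10 layers plus the total retina.

## Known limitations

* The three-normal tilt average under-corrects single-source tilt (see
  above); per-component accuracy is verified instead.
* The RFT threshold uses the area EC term with a pinned resel count;
  boundary terms are available but unvalidated against any reference.
* Exact overlap p values at pixel resolution ignore spatial
  autocorrelation (documented conservative alternative provided).
* The 17-resel override and the θ/s normalization constants are
  study-sample values kept as defaults, not population constants.
* `run_pipeline` caches only the final report keyed by config hash;
  per-stage artifact caching is limited to the CLI's stage directories.
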