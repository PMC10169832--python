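# Methods

This note records the model, the numerical choices and the limitations of
`octacov`. Defaults quoted here are the library defaults; every one of them
is a constructor or function argument.

## Measurement model

An acquisition is a sequence of T en-face OCTA frames (default problem
size: 20 frames of 304 × 304 px covering a 3 × 3 mm macular field,
~10 µm/px). The OCTA signal at a perfused pixel fluctuates between
repeats; the target quantity is the per-pixel **coefficient of variation**

CoV(x) = sd_t I(x, t) / mean_t I(x, t) × 100 %,

with the sample (ddof = 1) standard deviation, computed only where (a) the
pixel is valid in every aligned frame and (b) the temporal mean exceeds a
floor (default 1 % of the global mean over valid pixels) that guards the
ratio against near-zero denominators. Invalid pixels are NaN, never zero.
CoV is invariant to global intensity scaling and to frame order, and a
constant series gives exactly 0 — properties the test suite enforces. The
quartile coefficient of dispersion, QCD = (Q3 − Q1)/(Q3 + Q1) × 100 with
linear-interpolation quartiles, is provided as an outlier-resistant
companion (undefined when Q1 + Q3 = 0; requires ≥ 4 samples).

## Alignment

Frames are bilinearly upscaled (default factor 2; output pixel (i, j)
samples the input at (i/f, j/f), so original grid points are preserved
exactly) and registered to a reference — the first frame by default, or
the temporal mean. Rigid motion is parameterized as (dx, dy, θ) about the
image centre; the estimate is initialized by FFT phase cross-correlation
(50× subpixel upsampling) and refined by a SimpleITK Euler2D optimization
of the correlation metric (regular-step gradient descent, 2-level
pyramid). The candidate with the best normalized cross-correlation wins;
a candidate set that *degrades* the similarity raises an error instead of
silently passing through. Measured recovery error for shifts ≤ 5 px and
rotations ≤ 3° is below 0.01 px / 0.01°.

The optional non-linear stage fits a B-spline displacement field (control
point spacing ≥ 8 px, default 32 px; L-BFGS-B, 30 iterations) on a
coarse pyramid only — the field is smooth by construction, so coarse-level
optimization loses no accuracy and is roughly an order of magnitude
faster. The resulting dense field uses the backward sampling convention
out(q) = in(q + u(q)), stored as a (2, H, W) array of (row, col)
components. If the optimized field does not improve the correlation the
identity field is returned and flagged; the stage never degrades an
alignment. Smooth warps of 2 px peak magnitude are recovered with ≥ 80 %
residual reduction.

Resampling marks every pixel mapped from outside the source field of view
as invalid; downstream statistics use only pixels valid in all frames, so
border effects never masquerade as temporal variance.

## Centrelines and vessel segments

Vessel centrelines are detected on the temporal mean of the aligned
(upscaled) stack: Frangi vesselness over σ ∈ {1, 2, 3} px, hysteresis
thresholding at 1 % / 5 % of the maximum response, removal of components
smaller than 20 px, morphological closing with a 1-px disk, and
topological thinning to single-pixel width.

The skeleton is decomposed into **segments** — maximal runs of centreline
pixels between junctions and/or endpoints. Pixel adjacency is
8-connectivity with redundant diagonals pruned (a diagonal link is dropped
when the two pixels already share an orthogonal skeleton neighbour); under
this adjacency a pixel with one neighbour is an endpoint, two a path
pixel, three or more a junction. Junction pixels belong to no segment.
Segments shorter than 3 px (a thinning-spur scale) are discarded by
default. A crossing of two straight lines therefore decomposes into
exactly four arms, and every non-junction pixel of any skeleton belongs to
exactly one segment — both are tested invariants.

Each segment carries the arithmetic mean of the per-pixel CoV over its
valid pixels. Within a region, the median of segment mean CoVs is the
temporal-variation summary and their IQR the spatial-variation summary.

## ROI categories

Seven categories partition the field with respect to operator-supplied
primary masks (major arterioles a1…, major venules v1…, the FAZ):

- **Arteriole / Venule** — the vessel masks themselves;
- **Arteriole-net / Venule-net / FAZ-net** — the generalized Voronoi
  influence zone of each seed over the capillary domain, computed with one
  Euclidean distance transform per seed and an argmin; distance ties break
  toward the lowest seed index, making the partition deterministic;
- **FAZ-cp** — the terminal capillary band around the FAZ (default: a
  6-px annulus outward from the FAZ boundary when no mask is drawn);
- **Quadrant** — four axis-aligned quadrants through the foveola centre
  (default: the FAZ centroid), excluding the vessels and the FAZ; pixels
  on the split lines belong to no quadrant.

A segment joins the ROI containing the majority of its pixels, one ROI per
category; ties break toward the ROI holding the segment midpoint, then
lexicographically. Masks drawn on the acquisition grid are replicated
pixel-wise onto the upscaled analysis grid.

## Cohort statistics

Per subject and category, segment mean CoVs are pooled and summarized by
their median and IQR, producing two subjects × 7 tables. Each is analysed
with a one-way repeated-measures ANOVA: SS decomposition into effect,
subject and error terms; F = MS_effect/MS_error with (k−1), (k−1)(n−1)
degrees of freedom; generalized η² = SS_effect/(SS_effect + SS_subjects +
SS_error). Sphericity is assessed with Mauchly's W on the covariance of
orthonormal (Helmert) contrasts using the second-order χ² approximation
(the convention of mainstream R implementations); when Mauchly rejects at
α = 0.05 the headline p value uses Huynh–Feldt-corrected degrees of
freedom (ε_HF capped at 1; Greenhouse–Geisser ε is always reported
alongside). Post-hoc comparisons are all 21 pairwise paired t-tests with
Bonferroni adjustment p_adj = min(1, 21 p) and confidence intervals at the
per-comparison level 1 − α/21. The implementation is written in-package
from the definitions; the test suite cross-checks every statistic (F, p,
η², W, Mauchly p, both ε, post-hoc p values) against an independent
reference implementation to ~10⁻⁹ relative error, and verifies SS
conservation, the ordering 1/(k−1) ≤ ε_GG ≤ ε_HF ≤ 1 over 1000 random
tables, and exact ε = 1 with Mauchly p = 1 on constructed spherical data.

## Synthetic phantom

Real macular OCTA sequences cannot be redistributed, so validation uses a
phantom that emulates the salient structure of the field: an avascular FAZ
disc (default radius 30 px) with a terminal capillary ring; alternating
radial arteriole/venule trees (default 8 + 8, two to three branching
generations, drawn 3 px wide) converging toward the fovea; and an
interstitial capillary mesh built from Delaunay edges between blue-noise
points (default spacing 9 px). Ground truth includes the vessel label
map, per-vessel class, centreline mask, the full ROI set and the
generative CoV map.

Temporal model: all pixels of a vessel share one course. Large vessels
follow a sinusoid of amplitude a over two whole periods with random phase
(population CoV = a/√2; default a = 0.16·√2 → 16 %). Capillaries follow a
symmetric random telegraph, flipping i.i.d. between baseline·(1 ± a)
(population CoV = a; default a = 0.33 → 33 %). Baselines default to
220/200/120 intensity units for arterioles/venules/capillaries over a
background of 8. Each frame is blurred by an isotropic Gaussian PSF
(default σ = 1 px, matching the ~15–20 µm lateral resolution of the
instrument at ~10 µm/px) and then receives additive Gaussian sensor noise
(σ = 4, floored at zero). The PSF is essential: without band-limiting, the
binary-sharp vessels could not be resampled consistently by *any*
registration method, and motion-then-realignment would inflate the CoV of
edge pixels by an order of magnitude. A documented consequence is that
the *measured* pixel CoV of 1-px capillaries is diluted below the
generative 33 % (to ~26 % at default settings) by mixing with the static
background, while the 3-px-wide large vessels stay at their generative
16 %. Known rigid and/or smooth non-linear motion can be injected
per-frame for registration validation.

## Limitations

- The phantom emulates geometry and temporal statistics, not the physics
  of decorrelation imaging (no speckle, no projection or segmentation
  artefacts, no flow-dependent saturation).
- The capillary temporal model is i.i.d. per frame; real perfusion
  fluctuations have temporal autocorrelation. CoV is insensitive to frame
  order, so this does not affect the target quantity.
- Influence zones use pixel-centre Euclidean distance; anisotropic pixel
  spacing is not modelled.
- The non-linear registration optimizes on a coarse pyramid; displacement
  fields with energy at wavelengths below ~2× the control-point spacing
  are not recoverable by design.
- The statistical battery assumes complete tables (no missing cells) and
  a single within-subject factor.
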