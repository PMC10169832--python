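# octacov — spatio-temporal perfusion variability in macular OCTA sequences

`octacov` quantifies how strongly the perfusion signal of the human macula
fluctuates over time, and how that fluctuation is organized in space, from a
sequence of *en face* OCT angiography (OCTA) frames acquired at the same
location. The OCTA signal is a decorrelation measure driven by moving red
blood cells, so repeated acquisitions of the same field do not produce
identical images: capillaries "blink" as single-file flow stalls and
resumes, while the larger radial arterioles and venules vary far more
gently. The package turns that qualitative observation into calibrated,
statistically testable numbers.

## What it computes

1. **Alignment.** Each frame is bilinearly upscaled (default ×2) and
   registered to a reference frame — a translation + rotation stage driven
   by phase correlation and normalized cross-correlation, followed by an
   optional regularized B-spline non-linear stage. Pixels resampled from
   outside the field of view are flagged invalid, never zero-filled.
2. **Pixel-wise CoV map.** For every valid pixel, the coefficient of
   variation of its intensity over time: sample standard deviation divided
   by the temporal mean, in percent. A quartile coefficient of dispersion
   (QCD) is available as an outlier-resistant alternative.
3. **Vessel segments.** Vessel centrelines are detected on the temporal
   mean image (Frangi vesselness → hysteresis threshold → topological
   thinning) and decomposed into junction-to-junction *segments*; each
   segment carries the mean of its pixels' CoV values. Within a region,
   the **median** of segment mean CoVs summarizes temporal variation and
   their **IQR** summarizes spatial variation.
4. **Seven ROI categories.** Arteriole, Venule (the radial vessels
   themselves); Arteriole-net, Venule-net, FAZ-net (the capillary
   territory nearest each seed — generalized Voronoi influence zones
   computed by Euclidean distance transform); FAZ-cp (the terminal
   capillary band hugging the foveal avascular zone); and four Quadrants
   through the foveola.
5. **Cohort statistics.** Subjects × categories tables of medians and IQRs
   are analysed with a one-way repeated-measures ANOVA including Mauchly's
   sphericity test, Greenhouse–Geisser and Huynh–Feldt ε corrections,
   generalized η², and Bonferroni-corrected post-hoc paired t-tests with
   adjusted confidence intervals.

Because clinical OCTA sequences cannot be redistributed, the package ships
a synthetic macular phantom generator with complete ground truth (vessel
labels, centrelines, ROI masks, true CoV, injected motion), which is also
how the whole pipeline is validated.

## Worked example

```python
import numpy as np
from octacov import (generate_phantom, simulate_sequence, TemporalModel,
                     FrameSequence, upscale, compute_cov_map,
                     segment_centrelines, decompose_segments,
                     segment_mean_cov, assign_segments, build_roi_set)

# one synthetic subject: 304x304 px (3x3 mm), 20 frames
ph = generate_phantom(seed=0)
seq, true_cov = simulate_sequence(ph, TemporalModel(rng_seed=0))

# measurement pipeline (frames are simulated pre-aligned here)
up = FrameSequence.from_frames(
    np.stack([upscale(f, 2) for f in seq.frames]), aligned=True)
cov = compute_cov_map(up)
skel = segment_centrelines(up)
segments = segment_mean_cov(cov, decompose_segments(skel, 3))

# assign segments to the ground-truth ROI set (upscaled to match)
k2 = np.ones((2, 2), bool)
roi = ph.roi_truth
roi_up = build_roi_set(
    {n: np.kron(roi.masks[n], k2) for n in roi.masks
     if n.startswith("a") and not n.endswith("-net")},
    {n: np.kron(roi.masks[n], k2) for n in roi.masks
     if n.startswith("v") and not n.endswith("-net")},
    np.kron(roi.faz_mask, k2),
    foveola_centre=tuple(2 * c for c in ph.fovea_centre))
table = assign_segments(segments, roi_up)
print(table.groupby("category")["mean_cov"].median().round(2))
```

Output (2053 vessel segments):

```
category
Arteriole        15.85
Arteriole-net    26.07
FAZ-cp           27.37
FAZ-net          25.98
Quadrant         25.80
Venule           15.78
Venule-net       25.57
```

The two large-vessel categories sit at the generative 16% level and are
statistically indistinguishable from each other, while every capillary
category is far more variable (the generative 33% capillary level is
measured lower because the instrument point-spread function mixes thin
capillaries with the static background). On a 10-subject cohort the
repeated-measures battery yields, for the medians table,
F ≈ 147, generalized η² ≈ 0.93, Huynh–Feldt ε ≈ 0.26,
Mauchly p ≈ 2 × 10⁻²⁵; the Bonferroni-adjusted Arteriole-vs-Venule
comparison is non-significant (p = 1.00) while all ten vessel-vs-capillary
comparisons are significant.

## Command line

```bash
octacov simulate --out subj0 --seed 0            # phantom with ground truth
octacov align subj0/frames.tif --out aligned.tif # upscale + register
octacov covmap aligned.tif --out cov.tif
octacov segment aligned.tif --out segments.tif
octacov run-all config.yaml                      # whole subject from YAML
octacov stats s*/segments.csv --out cohort/      # RM ANOVA + post-hoc
octacov render subj0_out/                        # heat map + box plots
```

## Layout

- `src/octacov/phantom.py` — synthetic macular phantom + temporal model
- `src/octacov/registration.py` — upscaling, rigid and B-spline alignment
- `src/octacov/covmap.py` — CoV/QCD maps, centrelines, segment decomposition
- `src/octacov/roi.py` — influence zones, quadrants, segment assignment
- `src/octacov/rmstats.py` — repeated-measures ANOVA battery
- `src/octacov/pipeline.py` / `cli.py` — orchestration, rendering, CLI
- `docs/methods.md` — methods note with all modelling choices

See `docs/methods.md` for assumptions, parameter defaults and limitations.
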