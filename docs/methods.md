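# Methods

This note documents the models behind each pipeline stage, the defaults
that matter, what the synthetic generators do and do not emulate, and the
numerical choices a maintainer would want to know.

## Tip fields and their rendering

Microvillus tips of an intact brush border are modeled as a triangular
lattice with constant `spacing` (default 0.1 μm, the order of magnitude of
tightly packed duodenal microvilli).  Three disorder knobs emulate the
loss of intermicrovillar crosslinking:

* `jitter_sd` — isotropic Gaussian displacement per tip (applied first;
  points jittered outside the field are clipped to the boundary minus
  1 nm so the field stays closed);
* `dropout_frac` — independent removal probability per tip (applied after
  jitter);
* `hard_core` — minimum tip separation enforced last by dependent
  thinning (of any pair closer than the radius the later point is
  removed).  Microvillus shafts are ~0.1 μm thick, so tips of a real brush
  border cannot approach arbitrarily; free Gaussian jitter alone *lowers*
  the mean nearest-neighbor distance (colliding neighbors), whereas the
  observed disordered phenotype combines fewer microvilli with *larger*
  nearest-neighbor distances.  A hard core of 0.08 μm reproduces that
  combination; it defaults to 0 (off) so the plain jittered-lattice
  contract is unchanged.

Lattice orientation is uniform in [0°, 60°) per seed, so orientation never
leaks into any statistic.  A homogeneous Poisson generator provides the
fully disordered null; its nearest-neighbor distance has the closed-form
mean 1/(2√λ), which the NND implementation must hit within 3% — this is
the pipeline's primary numerical oracle.

Rendering sums unit-amplitude isotropic Gaussian bumps (sd `psf_sigma`)
plus additive Gaussian noise clipped at zero.  Defaults: `psf_sigma` =
10 nm and a render pixel of 5 nm.  These are deliberately
high-magnification-SEM-like: with a 30 nm PSF, tips jittered to within a
few tens of nanometres merge into single intensity maxima and *no*
detector can separate them, which would say nothing about the detector and
everything about an unrealistically blurry imaging model.  Poisson shot
noise is deliberately omitted; additive Gaussian noise suffices to test
the deterministic operators.

## Tip detection

Gaussian smoothing (default 6 nm) is followed by topographic-prominence
peak selection: the h-maxima transform retains exactly the maxima whose
prominence exceeds `prominence` × the smoothed dynamic range (default
0.1).  Maxima closer than `min_separation` (default 30 nm) are suppressed
keeping the brighter (ties: smaller row/column index), and each survivor
is refined by the 3×3 intensity centroid.  With these defaults, rendered
lattices with jitter 0.2 × spacing and 5–10% noise are recovered at
precision ≥ 0.99 and recall ≥ 0.98 against generator ground truth (20
seeds, 0.5 × spacing match radius).  All detection parameters were
calibrated on synthetic renders only; real SEM micrographs will need
per-dataset tuning, which is why all three are exposed.

## Spectral hexagonal order (h₆)

The image is cropped to its largest centered square, mean-subtracted and
Hann-windowed; the first-order ring is the integer radius (excluding DC
± 3 bins) maximizing angularly integrated power, and

    h₆ = |Σ P e^{i6θ}| / Σ P   over the ring band (radius ± 10%).

The statistic is bounded in [0, 1] and rotation-invariant (rotating the
image rotates the spectrum rigidly; the 6th-harmonic modulus drops the
phase).  Order contrasts are evaluated on 5.12 μm square fields (640² px
at 8 nm/px): measured h₆ ≈ 0.998 for perfect lattices and 0.04 ± 0.02 for
density-matched Poisson fields, with the ring radius within 0.3% of the
analytic 2/(√3·a).  Small fields bias Poisson h₆ upward — the speckle
band then contains too few independent cells (the Hann mainlobe correlates
neighboring spectrum pixels), and the modulus of a short random phasor sum
is systematically positive.  A constant image raises an undefined-ring
error.

## Cross-section morphometry

Segmentation is Gaussian blur (default 2 nm) → global Otsu threshold
(`fixed` available as an escape hatch) → 8-connected components; objects
below `min_area` (default 100 nm², standing in for the study's manual
correction) or touching the border (truncated profiles bias areas) are
discarded.  Area is the pixel count × pixel area.  Perimeter is the
marching-squares iso-contour at level 0.5 of the zero-padded mask after a
1 px Gaussian smooth: a raw binary contour carries staircase bias that
alone breaks the circularity ≈ 1 invariant for disks, while the light
smooth displaces a locally symmetric boundary negligibly.  Against
analytic oracles: disk circularity 0.992, square 0.802 (analytic π/4 ≈
0.785), 2:1 ellipse within 0.01 of the quadrature value; circularity is
scale-stable to < 0.02 across a 2× resolution change and strictly
decreasing in axis ratio at fixed area.  Circularities in (1, 1.05] are
treated as discretization slack and capped at 1.0.  Fused profiles are a
biological observation, not an artifact: no watershed splitting is
attempted, and fused blobs correctly score lower circularity than either
constituent ellipse.

## Line-scan colocalization

Profiles are sampled per pixel step with bilinear interpolation, averaging
`width_px` (default 12) perpendicular offsets, over a fixed 4 μm scan whose
increasing coordinate is the luminal (distal) direction.  Each channel is
divided by its own maximum; offsets are re-expressed relative to the
reference maximum (first occurrence on ties), with no resampling.  The
correlation uses only samples with normalized *reference* > 0.7 — the
reference (ezrin, present along the whole microvillus) defines the
brush-border region; a stricter both-channels reading is available via
`threshold_channel="both"`.  Spearman is the default method (Pearson
available): it is invariant under monotone transforms of either channel
and robust to the saturating nonlinearities of fluorescence imaging.
Coefficients are *missing*, not exceptions, when fewer than 3 samples
survive or a retained vector is constant.

Group comparison uses the exact Mann–Whitney null when the combined sample
is ≤ 20 without ties (complete separation at 3 vs 3 gives the enumerated
two-sided p = 2/20 = 0.1), and the tie-corrected normal approximation
otherwise — without continuity correction, so identical groups report
exactly p = 1.

The synthetic reference channel is a plateau spanning the microvillus,
tilted from 0.85 at the base to 1.0 at the distal tip and smoothed with a
50 nm Gaussian.  The distal tilt reflects the distal enrichment of ezrin
along microvilli and is load-bearing: a perfectly flat plateau makes the
above-threshold window rank-degenerate (its ordering would be pure noise),
and no colocalization procedure could then distinguish a tip-localized
from a delocalized marker.  Tip-mode markers are Gaussian peaks
(sd 0.25 μm) at the distal plateau edge; delocalized markers are broad
bumps (sd 0.8 × length) centered mid-plateau.  Per-profile lognormal
amplitude scatter (10%), length CV 5% and 50 nm positional jitter provide
the biological variability that makes group comparisons meaningful.  Under
these conditions the median Spearman coefficient is ≈ 0.44 for tip-mode
vs. ≈ 0.06 for delocalized profiles, and the rank-sum test at n = 30 per
group rejects in ~100% of replicate experiments.

AUC is the trapezoidal integral over the full scan; signal length is the
extent of the longest contiguous run at ≥ 0.5 × channel max with linearly
interpolated crossings (half-max is the conventional width definition);
AUC per length is their quotient (missing at zero length).  For
equal-amplitude microvilli of lengths 1.0 vs. 0.5 μm the AUC ratio is
1.98 while AUC-per-length agrees to 0.2% — length normalization removes
the shortening effect and isolates protein *density*.

## Histology quantification

The colitis rubric is pure arithmetic: raw sum = inflammation (0–3) +
crypt damage (0–5) + ulceration (0–3), total = raw sum × area multiplier.
The printed area bands overlap at the quarter boundaries, so boundaries
are assigned lower-inclusive upward (0.25 → 1, 0.50 → 2, 0.75 → 3).
Exhaustive enumeration of all 4·6·4 sub-score combinations × 4 bands
confirms the range {0..44} with 44 attained only at (3, 5, 3) × 4.

FISH classification applies the exclusion rules at the signal level (the
study's spot calls were visual, so features — Cy3 intensity, green
intensity, nuclear overlap — are the natural inputs), in decision order:
not Cy3-positive → negative; nuclear overlap above the cut →
excluded nuclear false positive; green-positive → excluded
autofluorescent (double-positive) false positive; else counted.  The
intensity cuts (defaults 50/50 and overlap 0.3) are free parameters —
the study never quantified its visual thresholds.  The invasion rate is
counted bacteria / total cells.

Mucus thickness samples `n_samples` (default 11) arc-length-uniform points
on the inner boundary and takes the nearest distance to the outer
polyline — identical to normal-ray casting for parallel boundaries and
robust to annotation jitter elsewhere.  Only *properly crossing*
annotations are rejected; identical/touching boundaries legitimately give
zero thickness.  Corner effects make concentric-polygon means read low by
up to ~15% at 11 samples; dense sampling converges to the same value.

Weight curves (% of day-0 weight, day 0 ≡ 100) are reduced to per-mouse
trapezoidal AUCs and compared by one-way ANOVA with Tukey HSD pairwise
comparisons (the study's alternative post-hoc tests agreed, so one default
suffices).

## Problem sizes and determinism

Every generator is bit-reproducible for a fixed seed.  The test-suite and
acceptance-script problem sizes — 50 Poisson fields of ~900 points, 20
rendered lattices of ~300 tips, 20 + 20 spectral fields of 640² px, 200
colocalization replicates of 2 × 30 profiles, 100 FISH fields — were
chosen so the full suite completes in well under a minute per stage on a
single CPU while leaving the statistical margins (3% NND tolerance, 0.95
precision/recall, 0.15 h₆ bound, 90% rejection) comfortably wide.

## Limitations

The generators produce the minimum structure the operators quantify, not
photorealistic micrographs: no SEM/TEM texture, charging or shading
gradients; additive Gaussian noise only; elliptical cross-sections without
membrane rendering; line scans without cytoplasmic background structure.
Passing tests therefore validate the *operators* (geometry, statistics,
contracts) and the direction of every biological readout, but say nothing
about segmentation robustness on real-image texture, where thresholds and
detection parameters will need dataset-specific calibration.  Tip
detection assumes bumps on a comparatively flat background; strongly
varying illumination would require background flattening first.  The FISH
stage classifies pre-extracted signal features and deliberately does not
detect spots in raw images.
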