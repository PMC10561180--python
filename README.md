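# brushborder

Quantitative morphometry of the intestinal brush border.

The apical surface of intestinal epithelial cells is covered by microvilli
packed into a near-hexagonal lattice by the intermicrovillar adhesion
complex (IMAC, built around the protocadherins CDHR2/CDHR5 at the tips).
When crosslinking fails, microvilli become fewer, shorter, thicker and
disordered, and tip-localized IMAC proteins delocalize — changes that show
up in electron micrographs, fluorescence line scans and downstream colitis
phenotypes.  This package implements the measurement chain for that
biology, for researchers who quantify such micrographs:

* **Tip packing** — detection of microvillus tips in top-view images as
  prominent local maxima with subpixel refinement; counts per high-power
  field; exact nearest-neighbor distances (NND) with frequency
  distributions; and a rotation-invariant spectral order parameter
  *h₆* = |Σ P(θ) e^{i6θ}| / Σ P(θ) evaluated on the first-order ring of the
  2-D power spectrum (1 for a perfect triangular lattice, ≈0 for disorder;
  the ring sits at 2/(√3·a) cycles/μm for lattice constant *a*).
* **Cross-section shape** — Gaussian blur + Otsu threshold + connected
  components on TEM-like images; per-object area, subpixel iso-contour
  perimeter, and circularity 4πA/P² (1 for a circle; fused or thickened
  profiles score lower); area histograms and polyline lengths.
* **Line-scan colocalization** — fixed-length (4 μm, 12-px-wide) two-channel
  profiles, each channel normalized to 1 and aligned on the reference
  (ezrin) maximum; Spearman (or Pearson) correlation restricted to samples
  with normalized reference > 0.7; Wilcoxon–Mann–Whitney group comparison
  (exact for combined n ≤ 20 without ties); trapezoidal AUC, half-max
  signal length, and AUC per unit length.
* **Histology quantification** — the composite colitis score
  (inflammation 0–3 + crypt damage 0–5 + ulceration 0–3, max 11, times an
  affected-area factor 1–4, max 44); FISH bacterial counting with exclusion
  of nuclear and Cy3/green double-positive false positives; mucus-layer
  thickness from paired boundary annotations (≥ 11 samples); weight-curve
  AUC with one-way ANOVA and Tukey post-hoc tests.
* **Synthetic data** — seeded generators for every input above (hexagonal /
  disordered tip fields, rendered top views, elliptical cross-sections with
  fusion events, two-channel line scans, FISH signal tables, weight
  curves), each with ground truth, so the whole chain is testable without
  any raw micrographs.

## Worked example

```python
import numpy as np
from brushborder import (SimulationConfig, gen_tip_pattern, render_topview,
                         detect_tips, nnd, density_per_field, hex_order_fft,
                         ColitisSubScores, colitis_score)

wt = SimulationConfig(seed=1, spacing=0.1)                      # intact crosslinking
ko = SimulationConfig(seed=1, spacing=0.1, jitter_sd=0.04,      # disordered brush border
                      dropout_frac=0.3, hard_core=0.08)
for name, cfg in [("wildtype-like", wt), ("knockout-like", ko)]:
    pattern = gen_tip_pattern(cfg, 1.6, 1.6)
    image = render_topview(pattern, cfg.psf_sigma, noise_sd=0.05,
                           pixel_size=0.005, seed=cfg.seed, pad=0.1)
    tips_found = detect_tips(image)
    res = nnd(tips_found)
    count, density = density_per_field(pattern)
    print(f"{name}: {count} tips ({density:.0f}/um^2), "
          f"mean NND {res.mean*1000:.0f} nm")

big = render_topview(gen_tip_pattern(wt, 5.12, 5.12), wt.psf_sigma, 0.0, 0.008, seed=1)
order = hex_order_fft(big)
print(f"hexagonal order h6 = {order.h6:.2f}, "
      f"ring at {order.ring_radius:.1f} cycles/um")

raw, total = colitis_score(ColitisSubScores(2, 3, 1, affected_fraction=0.6))
print(f"colitis: raw sum {raw}, area multiplier x3, total {total}")
```

prints

```
wildtype-like: 305 tips (119/um^2), mean NND 98 nm
knockout-like: 122 tips (48/um^2), mean NND 112 nm
hexagonal order h6 = 1.00, ring at 11.5 cycles/um
colitis: raw sum 6, area multiplier x3, total 18
```

The ordered field packs ~119 tips/μm² at the lattice spacing of 100 nm and
a first-order spectral ring at 2/(√3·0.1) ≈ 11.5 cycles/μm; the disordered
field has fewer tips *and* a larger mean nearest-neighbor distance, the
knockout readout direction.  The colitis example: sub-scores 2+3+1 = 6,
60% of the colon affected → multiplier 3, total 18 of a possible 44.

A `brushborder` command-line tool wraps the same functionality
(`brushborder simulate tips …`, `brushborder tips detect|nnd|hexorder …`,
`brushborder sections segment …`, `brushborder coloc run|compare …`,
`brushborder score colitis|fish|weights …`); every subcommand reads and
writes plain TIFF/CSV/JSON.

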