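# Methods

This document records the models implemented in `osseoquant`, the default
parameters and the reasons behind them, what the synthetic generators do and
do not emulate, and the known limitations. Values quoted for concrete inputs
are computed by the package itself (the test suite asserts them).

## 1. Histomorphometry

### 1.1 Color gating

Section images are RGB rasters of stained, plastic-embedded sections in which
the ceramic scaffold appears dark gray-blue and mineralized bone appears
red-pink. Classification is by inclusive box gates in 8-bit HSV space.

The 8-bit convention: `skimage.color.rgb2hsv` returns floats in [0, 1]; hue is
scaled by **179** and saturation/value by **255**, then rounded. Scaling hue to
0–179 keeps the full HSV triple inside a byte while using distinct ranges for
hue vs. saturation/value, and matches the convention of common imaging
tooling, so gate bounds can be exchanged with other software without
renormalization. `hsv8_to_rgb` inverts the mapping; the round trip is exact to
quantization.

| Gate | Lower (H, S, V) | Upper (H, S, V) |
|---|---|---|
| scaffold | (0, 0, 0) | (70, 67, 90) |
| bone | (155, 57, 67) | (179, 202, 187) |

Bounds are treated as opposite corners of an axis-aligned box; membership is
inclusive on both ends. Note the bone gate's upper saturation bound (202)
exceeds what an 8-bit pixel can reach above 179-scaled hue — the box is simply
clipped by the representable range; no pixel is misclassified by this. Gates
must be disjoint: overlapping boxes raise `GateOverlapError` at construction,
because a pixel cannot be both scaffold and bone. Pixels in neither gate
(soft tissue, void, stain background) are labeled *other*.

### 1.2 Scaffold hull and region partition

1. The scaffold mask (gate hits) is morphologically **closed** with a square
   kernel of side `kernel_px` (default **25 px**, must be odd so the kernel is
   centered) to bridge pore openings between struts, then **hole-filled**
   (`scipy.ndimage.binary_fill_holes`) into a solid hull. The kernel must
   exceed the pore opening width for the hull to be solid; 25 px suits strut
   pitches up to ~twice that and is exposed as a parameter for other
   magnifications.
2. From the hull: centroid (pixel mean), extreme points (left/right/top/
   bottom), and the horizontal centerline through the centroid.
3. Regions, expressed as a label raster (each pixel exactly one of):
   - **circumference**: hull pixels within `band_px` (default = `kernel_px`)
     of the hull boundary, by Euclidean distance transform;
   - **superficial** / **deep** interior: hull minus the circumference band,
     split at the centerline (above = superficial, below = deep);
   - **sides**: non-hull pixels within `band_px` of the left/right extreme
     points — host-bone interface zones lateral to the scaffold;
   - **exterior**: everything else.
   A separate, deliberately overlapping **center** disk of radius
   `0.25 · min(hull width, hull height)` about the centroid captures the zone
   slowest to vascularize.

One band width tied to the closing kernel keeps the margin scale consistent
with the pore scale; both are independently overridable.

### 1.3 Metrics

For each region, ingrowth is `100 · bone / (region pixels − scaffold pixels)`.
Scaffold material is excluded from the denominator because ceramic cannot be
replaced by bone on the timescale measured; the quantity is "fraction of
available (pore/soft-tissue) space occupied by new bone". A region whose
denominator is zero yields `NaN` plus a `UserWarning`, and is listed in
`HistoMetrics.undefined` — never silently 0. An overlay renderer tints the
regions, draws the hull boundary, centerline and centroid for visual QC;
rendering is deterministic.

## 2. Nanoindentation (Oliver–Pharr)

### 2.1 Segmentation

Traces sampled at `sample_rate` (default 100 Hz) are split into
loading / hold / unloading purely from the load channel, in two passes:

1. a coarse pass collects the contiguous run of samples within 2 % of the
   peak, anchoring a robust noise estimate `σ = MAD/0.6745` of that run;
2. the hold plateau is the contiguous run around the peak staying within
   `max(5σ, 10⁻⁶·P_max)` of the plateau median.

The noise-scaled second pass segments a clean curve at sample resolution
while keeping the full hold of a noisy one; the `10⁻⁶·P_max` floor prevents a
zero threshold on noiseless data. A plateau shorter than 3 samples, or one
that runs to the end of the trace (a monotone ramp), raises
`MalformedCurveError`. Curves shorter than 50 samples are rejected.

### 2.2 Unloading fit and derived quantities

`P = α (h − h_f)^m` is fitted (`scipy.optimize.curve_fit`, bounds
`m ∈ [1, 3]`, `h_f <` smallest depth in window) over the load window from
**95 % down to 20 %** of the unloading load range — the upper branch, where
the power law describes elastic recovery, excluding the very top (hold-exit
transients in real data) and the tail (surface adhesion, pile-up contact
loss). The final hold sample (the peak-depth point) is prepended to the
unloading branch so `h_max` is the true peak depth rather than one sample
below it. Then:

| Quantity | Formula |
|---|---|
| stiffness | `S = α m (h_max − h_f)^(m−1)` |
| contact depth | `h_c = h_max − ε P_max / S` |
| area | `A = C₀ h_c²`, or a calibrated polynomial if supplied |
| reduced modulus | `E_r = (√π/2) S/√A` |
| hardness | `H = P_max / A` |
| specimen modulus | `1/E_r = (1−ν_b²)/E_b + (1−ν_i²)/E_i` |

Defaults: `ε = 0.75` (the standard value for paraboloid-like contact, also
conventional for Berkovich tips), `C₀ = 24.5` (ideal Berkovich projected-area
constant), `E_i = 1140 GPa`, `ν_i = 0.07` (diamond), `ν_b = 0.3` (customary
for bone when the true Poisson ratio is unknown).

**Units.** Loads in μN, depths in nm, areas in nm². Stresses therefore come
out in μN/nm² = 10¹² Pa, and moduli/hardness are converted to GPa with the
factor **1 μN/nm² = 1000 GPa**. At the bone-like operating point
(`P_max = 300 μN`, `H = 0.46 GPa`) this gives `A ≈ 6.5 × 10⁵ nm²` and
`h_c ≈ 163 nm` — physically plausible contact scales.

`E_r` at or above the indenter limit `E_i/(1−ν_i²) ≈ 1145.6 GPa` would imply
negative specimen compliance and raises `NonphysicalInputError`. `H > E_r`
triggers a warning (implausible for bone-like materials). Specimen-level
aggregation reports n, mean, and sample SD of `E_r`, `E_b`, `H` over an
indent grid (minimum 2 indents).

## 3. Clock-face bridging

The defect rim is a circle; bony union is a set of disjoint arcs
`(start°, end°) ⊂ [0°, 360°]`. For `n` equal segments (12 by default,
5-minute "clock" resolution; any `n ≥ 1` works), each segment's score is
100 × the fraction of its span covered by arcs, and the overall score is the
segment mean. Because the segments tile the circle, the overall score equals
100 × the total bridged fraction and is **independent of n** — a property the
tests verify by comparing 12- against 8-segment scorings. Rotating the model
by one segment width permutes the per-segment scores cyclically.

Multiple raters' segment scores are averaged elementwise; agreement is
**ICC(2,1)** — two-way random effects, absolute agreement, single rater —

    ICC = (MS_R − MS_E) / (MS_R + (k−1) MS_E + k (MS_C − MS_E)/n)

with subjects × raters mean squares from the standard decomposition. A table
with zero total variance has no defined agreement: `NaN` plus a warning.

## 4. CT volumetrics

Mineralized tissue is segmented by an inclusive HU window, default
**[225, 3070]** — lower bound at the trabecular-bone threshold commonly used
for in-vivo micro-CT scoring, upper bound below ceramic/metal saturation so
residual scaffold with higher radiodensity can be excluded by window choice or
by an explicit exclusion mask (same shape as the volume). Volume is
`count × voxel volume` from the spacing in mm. NIfTI I/O via nibabel with a
diagonal affine from the voxel spacing.

## 5. Statistics

Small-cohort battery, mostly thin wrappers over `scipy.stats` with explicit
small-n contracts:

- **Shapiro–Wilk** (3 ≤ n ≤ 50; constant sample → `NaN` + warning);
- **one-way ANOVA** (`f_oneway`; NaNs dropped per group; degenerate cases
  special-cased: all groups identical → `F = 0, p = 1`; zero within-group
  variance with distinct means → `F = ∞, p = 0`);
- **Tukey HSD** (`scipy.stats.tukey_hsd`; all-identical → `p = 1`);
- **pooled two-sample t**, with Bonferroni adjustment helper;
- **Mann–Whitney U** (exact for small n without ties — `p = 0.1` is the floor
  for 3 vs 3, which the tests verify by enumerating all 20 assignments);
- **Kruskal–Wallis** plus a hand-implemented **Dunn post hoc** (pooled
  mid-ranks, tie correction `Σ(t³−t)/(12(N−1))`, Bonferroni by default),
  implemented here because no runtime dependency provides it.

### 5.1 Table reproduction

`reproduce_tables()` recomputes, from the shipped per-subject CSV fixtures,
every summary statistic the source study printed — group means and SDs of
micro-CT bridging, explant mineralized volume and regional histology;
longitudinal and final ANOVAs; pairwise volume t-tests — and compares each to
the printed value **at the printed rounding**, emitting a `match` flag.
Printed values that cannot be recovered from the printed per-subject data are
flagged, not forced; the computed value is always reported. Known mismatches:

- interior-histology ANOVA: printed 0.226, computed 0.2299 (rounds to 0.230);
- longitudinal bridging ANOVAs differ from the computed values by ~0.01 at
  3 decimals (e.g. 2-month: printed 0.073, computed 0.0749), consistent with
  software-side rounding or a slightly different missing-data treatment in the
  original analysis (two missing observations are dropped listwise here);
- printed "±" values do not equal the sample SDs of the printed per-subject
  volumes (e.g. 128.1 computed vs 145 printed for the top group), suggesting
  the published ± figures are not plain `ddof = 1` SDs.

## 6. Synthetic generators

Each generator emits an input plus exact ground truth, making every pipeline
testable end to end.

- **Micrographs**: a square strut lattice (default 600×600 px, 60 px margin,
  45 px pitch, 9 px struts) colored with in-gate colors (scaffold (20, 30, 40),
  bone (165, 130, 130), tissue (110, 150, 200) RGB — validated against the
  gates at construction). Pore fill per generator region is exact:
  `round(fraction · N)` pore pixels are turned to bone via a seeded
  permutation, so truth fractions are pixel-exact; optional HSV noise. Truth
  is recomputed from the emitted pixels, not the request. The generator's
  regions (outermost cell ring = circumference, midline split) are defined
  independently of the analysis partition, so recovery tests compare the
  analyzer to a per-pixel recount on the analyzer's own partition, and to the
  generator's truth only through the requested fill fractions.
  *Not emulated*: staining gradients, section tears, out-of-gate debris,
  non-rectangular scaffolds.
- **Indent curves**: closed-form inversion of the Oliver–Pharr relations at
  peak load (§2.2) gives `A, h_c, S, h_max, h_f, α` from `(E_r, H, m)`; the
  residual depth `h_f` is **derived** (tangency: the power law's slope at
  `h_max` must equal `S`), not a free parameter — specifying it independently
  would over-determine the curve. Loading follows `P ∝ h²` (self-similarity of
  a pyramidal indenter), hold sits at peak (no creep model), unloading is
  linear in load vs. time with depth from the inverted power law; Gaussian
  noise on the load channel only. Default profile: 60 μN/s × 5 s → 300 μN,
  10 s hold, 2 s unload, 100 Hz.
  *Not emulated*: thermal drift, creep during hold, tip-rounding area error,
  surface-detection offset.
- **Interfaces**: arcs with exact bridged fraction; **HU volumes**:
  constant-background (40 HU) grids with sphere/box inclusions rasterized at
  voxel centers, truth reported analytically and as voxel counts; **cohorts**:
  seeded normal group tables for calibration studies.

## 7. Verification scales

Chosen to exercise each stage meaningfully while keeping the full suite under
~10 s: histomorphometry recovery on 360×360 and 600×600 rasters (pixel-quantum
tolerance: one pixel's worth of percentage per region); nanoindentation
recovery on a 3×2 (E_r × H) grid at < 1 % relative error, compliance
round-trip at 10⁻¹⁰; null calibration of t/ANOVA at 10,000 simulated cohorts
(nominal 0.05 ± 0.01); Mann–Whitney exact floor by enumeration; ICC against an
independent reference implementation.

## 8. Limitations

- Gates are fixed boxes; stain variability across labs will require re-derived
  bounds (they are parameters, not constants, throughout).
- The region partition assumes a roughly convex, horizontally oriented
  scaffold; rotated or concave implants would need a pose-normalization step.
- The ideal `C₀ h_c²` area is used unless a calibrated polynomial is supplied;
  at sub-100 nm contact depths tip rounding makes the ideal area a poor
  approximation.
- ICC is implemented for complete two-way tables only (no missing cells).
- The exact Mann–Whitney p floor at n = 3 per group (0.1) means no two-sided
  significance at α = 0.05 is attainable for such samples — a property of the
  test, surfaced here because the shipped cohorts are that small.
- The HU window segments by intensity alone; partial-volume effects at
  inclusion boundaries bias volumes by up to a voxel shell (≈ 0.8 % for the
  test sphere at 0.5 mm spacing).
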