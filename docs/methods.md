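# Methods

This document specifies the measurement model, the synthetic data
generator, every user-facing parameter (units, defaults, rationale), the
numerical choices, and the known limitations.

## 1. Data model

A field is an `ImageStack`: one `(z, y, x)` float array of non-negative
intensities per named channel, all sharing one shape. Plane index 0 is the
**topmost** plane (farthest from the substrate); "below" always means
increasing plane index. Physical calibration defaults to 0.5 µm z-spacing
and 0.5 µm lateral pixel size, matching typical high-NA confocal
acquisition of these cultures. The three channel roles are `nuclei`
(DAPI), `fibronectin` (antibody-labeled) and `tmp` (bulk amine-reactive
labeled total matrix protein); the two matrix channels are the scored
ones.

Stacks persist as multi-page TIFF, axes ZCYX, with channel names and
calibration in the shaped-TIFF metadata (`tifffile`), so written stacks
round-trip losslessly. Foreign TIFFs are read with an explicit
`channel_map` (role → channel index); calibration always comes from
metadata or configuration, never guesswork.

### The 0–225 scale

All analysis runs on a closed 0–225 pseudo-color intensity scale — the
display scale on which the thresholds were originally defined — not the
usual 0–255. `rescale_to_225` maps each channel affinely
(`v → 225·(v−lo)/(hi−lo)`, clipped):

* `"global-minmax"` — per-channel min/max of the stack; a constant channel
  maps to all zeros (conservative: no spurious high-intensity area).
* `"fixed-range"` — one explicit `(lo, hi)` shared by all channels; use
  this when stacks of one experiment must stay mutually comparable (take
  the interval from the untreated control).

The map is order-preserving, so every threshold below is well-defined
regardless of mode.

## 2. Layer partition

Matrix organization changes with depth, so scores are reported per layer.
The partition derives from the per-plane fibronectin **stain-positive
coverage** — the fraction of pixels at or above `positive_threshold`
(default 90, deliberately identical to the high/low scoring bin edge so
one cutoff governs both uses). Scanning from the topmost plane downward:

* **top** — the first plane with coverage ≥ `top_coverage` (default 0.20)
  plus one plane below;
* **bottom** — the first plane at/below the top plane with coverage ≥
  `full_coverage` plus one plane above. "Covers the entire field" is
  operationalized as 0.995 because noisy real fields never reach exactly
  1.0;
* **middle** — the central one (odd span length) or two (even) planes of
  the top-to-bottom span.

If no plane reaches full coverage — which heavily degraded matrices can
legitimately cause — the bottom falls back to the deepest plane attaining
the maximum coverage (plus one above) and the partition carries a
`bottom_fallback` flag rather than failing or guessing silently.

`max_projection` collapses a layer's planes per-pixel; `orthogonal_reslice`
produces the XZ view (max over a `thickness_um` band of rows, default
10 µm), used to inspect the depth structure the partition captures.

## 3. Regions and the remodeling score

### Segmentation

The original procedure traces around nuclei-defined cell clumps by hand.
`segment_cell_region` automates it on the nuclei maximum projection:

1. Otsu threshold; discard blobs < `min_blob_area` px (default 30 — a
   plausible nucleus cross-section at 0.5 µm pixels is hundreds of px);
2. group blobs within `clump_link_um` (default 4 µm) into clumps;
3. enclose each clump by the convex hull of its nuclei and dilate outward
   by `dilation_radius_um` (default 3 µm) — the traced "circumvention";
4. the cell-devoid region is the complement minus a `buffer_um` exclusion
   ring (default 10 µm), so halo signal at the cluster edge contaminates
   neither region.

`region_from_polygons` accepts manual tracings instead ((x, y) vertex
lists). The two masks are disjoint by construction and validated as such.

### The area-ratio score

On a layer projection, each pixel is **high** if its value lies in the
closed bin [90, 225], else **low**. Per region,
`ratio = n_high / n_low`, and

`score% = 100 × ratio_cell / ratio_devoid`.

100 = no cell-induced change; < 100 = degradation; > 100 =
accumulation/contraction. Because the comparison is within one field, it
is robust to per-field staining and illumination differences.

*Zero-count guard.* A region can legitimately have an empty low bin (a
saturated bottom layer). With `smoothing="auto"` (default), 0.5 is added
to **both** counts only when a zero count occurs; when the guard trips for
either region the score's two ratios are both smoothed so they stay
comparable. Boundary pixels at exactly 90 are high (closed bin).

### Phenotype call

The **top layer** is the deciding layer — the two phenotypes separate
most where the cells sit. The mean top-layer score below
`100 − neutral_margin` calls a degrader, above `100 + neutral_margin` an
accumulator, otherwise neutral. `DEFAULT_NEUTRAL_MARGIN = 35` was frozen
once as 3× the across-seed SD (11.8) of the top-layer score under the
null simulation defaults; `calibrate_neutral_margin()` recomputes it for
other generator settings.

`normalize_to_control` optionally re-expresses scores so the untreated
control's bottom-layer mean is exactly 100 per channel (cross-condition
display convention). `timelapse_change` tracks region mean intensities of
one re-imaged field over culture days (default days 0/7/10) and their
day-over-day percent change; `widefield_image` (z-mean) is the
stack-derived stand-in for widefield time-lapse frames.

## 4. Statistics

Replicates are per-field scores (matrix channels averaged within a
field). Score variances scale with means across conditions, so values are
natural-log transformed before testing; non-positive values are a hard
error, never silently dropped. Each inhibitor condition is compared
against the untreated control per layer with classical one-way ANOVA
(`scipy.stats.f_oneway`; zero within-group variance raises a
`DegenerateVarianceError` rather than returning p = 0; exactly identical
group means return F = 0, p = 1). The family of all (condition × layer)
raw p-values in one call is adjusted with the Benjamini–Hochberg step-up
procedure (`statsmodels`, verified in the tests against a definitional
oracle) at FDR `alpha_fdr = 0.05`; comparisons with raw p ≤
`alpha_significant = 0.01` are flagged significant. Reported means/SEs
stay on the percent scale.

## 5. Synthetic data generator

The generator emulates the phenomenology the score can see, not the
biophysics.

**Fiber mesh.** Random straight segments (length ~ N(20, 7²) px, ≥ 6;
log-normal amplitudes; uniform orientation) are accumulated and
Gaussian-blurred (σ = 1 px). Segments are drawn on a canvas padded by
`length_mean + 3·length_sd` and cropped, with the segment count scaled to
the padded area, so texture statistics are stationary up to the field
border — without this, border effects biased null scores by 10–25%. A
persistent pixel-scale speckle (0.8× the texture SD) is added so
high/low pixel counts behave binomially per region instead of
patch-wise. One mesh persists across planes and matrix channels (plus a
small 0.12-weighted per-plane perturbation), so low-coverage "holes" line
up in z as in a real matrix.

**Coverage profile.** Per plane, the texture is thresholded at the k-th
largest value with k = ⌈coverage·N⌉ (count-based, guaranteeing fraction ≥
target — an `np.quantile` cut could undershoot and spuriously trigger the
bottom fallback at 0.995). Positive pixels get intensities
~ N(`fiber_intensity_mean` = 140, 25²) floored at 100; negatives are
compressed into [0, 80]. The 80–100 gap keeps the additive noise
(`noise_sd` = 3, truncated at 0) from flipping pixels across the 90
cutoff. The default 12-plane profile tapers 0.05 → 0.995, crossing 20% at
plane 2 and reaching full coverage at plane 10.

**Cells.** `n_clusters` (default 3) non-overlapping circular footprints
(radius 30–42 px, ≥ 30 px apart) are placed at seed-determined positions;
15 nuclei per cluster (ellipses, axes ≈ 3–4.5 × 5–7 px, centers within
0.92·r) are rendered on two reference planes near 55% depth.

**Remodeling transforms** (`apply_remodeling`, matrix channels only):

* *Degrader* — multiplies intensities inside the footprint by
  `1 − (1−f)·w_z`, where `w_z = exp(−max(z−origin, 0)/tau)` and `origin`
  is the 20%-coverage onset plane; `depth_tau_planes=None` means uniform
  ×f at every plane (the exactly-multiplicative reference case), while
  the generator passes `tau = n_planes/4` so degradation is strongest at
  the matrix top, as observed.
* *Accumulator* — multiplies inside intensities by `1 + (f−1)·w_z` (the
  same depth attenuation: contraction acts where the cells sit; a
  depth-uniform gain over the dense bottom volume would dominate the
  bottom layer, contradicting the observed top-layer dominance); removes
  `conserve_fraction` of the gain from a surrounding annulus (8–40 px
  dilation ring) by multiplicative down-scaling allocated across planes by
  a water-filling scheme (preferentially near the top, never below a
  plane's available signal); deposits `apical_fraction` of the removed
  signal on the top `n_apical_planes` planes over the footprint,
  proportionally to existing signal (matrix piles up along existing
  fibers; dark pixels stay dark). With `conserve_fraction = 1`,
  `apical_fraction = 0` and uniform depth, the field total is conserved
  exactly.

`simulate_timecourse` re-renders the identical seed-fixed field with the
effect scaled per day by `effect_timescale` (default (0, 0.6, 1.0) over
days 0/7/10, non-decreasing required), mirroring repeated imaging of
preselected fields. Presets: `null`, `ovcar5_like` (degrader, f = 0.3),
`ovcar10_like` (accumulator, f = 3.0).

**What it does not model:** fibrillogenesis or real fiber mechanics,
optical PSF/attenuation with depth, cell bodies beyond nuclei, membrane
channels, photobleaching, or stage drift.

## 6. Pipeline, determinism and reporting

`RunConfig` captures everything a run needs — simulation preset (with
`n_fields` and base seed; field *i* uses `seed + i`) or input TIFFs plus
channel map, the rescale mode, all thresholds, segmentation parameters,
neutral margin and alphas. Its SHA-256 hash (16 hex chars) is embedded as
a `# config_hash=…` first line of every CSV and in the JSON outputs;
identical config + seed yields byte-identical outputs.
`stats_from_scores` turns a multi-condition scores table into the
ANOVA/BH results table. The report renderer pseudo-colors projections
with a discrete 226-level black/blue→red→white map (one color per
integer intensity level, color ticks at 0/90/225) and writes an HTML
report with the exact score table.

## 7. Numerical and design choices

* Intensities are float64 end-to-end; integer TIFF input is promoted.
* The score uses pixel **counts**, so it is invariant to any
  order-preserving intensity map above/below the bin edge.
* The water-filling allocation solves for λ in
  `Σ min(λ·w_z·cap_z, cap_z) = demand` by bisection (80 iterations,
  machine-precision) — closed forms fail once planes saturate.
* `one_way_anova` re-derives SSW first so degenerate inputs raise typed
  errors instead of producing misleading p-values.
* Errors form a typed hierarchy (`EcmError` → config/format/data
  subtypes); the CLI maps them to exit codes 2 (config) and 3 (data).
* Generator defaults were calibrated once against the null model (border
  stationarity, speckle, intensity mean, count-based thresholding) and
  then frozen; the neutral margin follows the stated 3×SD rule.

## 8. Limitations

* The segmentation assumes nuclei mark all cell-occupied area; cytoplasmic
  protrusions beyond the dilated hull end up in neither region.
* The area-ratio score saturates: once a region's low (or high) bin
  empties, further remodeling changes the score only through the smoothing
  guard, so extreme accumulator scores are order-of-magnitude indicators,
  not linear measures.
* The layer rules presume coverage increases with depth; inverted or
  non-monotone matrices yield a valid but possibly unintuitive partition
  (the flags and the recorded coverage curve make this auditable).
* Statistical power calibrations assume approximately log-normal scores
  with comparable group variances; heavy-tailed deviations would need a
  rank-based alternative.
* The synthetic generator is a phenomenological validation instrument; its
  effect sizes are not calibrated to any specific cell line's biology.
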