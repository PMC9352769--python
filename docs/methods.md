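# Methods

This note documents the models, conventions and numerical choices behind
the package, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the closed-loop validation does and does not
establish.

## Coordinate and photometric conventions

Window coordinates are µm, origin at the corner of the 8 × 8 mm window
nearest the holder aperture; y increases along the laminar-flow path.
Pixel centres sit at half-integer offsets; all intervals (class bounds,
histogram bins, matching radii) are half-open, lower-inclusive.

Images follow the transmitted-light convention: bright background, dark
particles, segmentation on the blue channel.  Under this convention a
threshold *above* the background median would select the background
itself, so the high-zoom stack statistic — the background median offset by
k = 2 times the mean per-frame SD — is applied on the **dark side** of the
median: threshold = median − k·mean(SD).  The helper
`compute_stack_threshold(stack, k)` implements the signed formula
median + k·mean(SD) exactly (per-frame SDs are population SDs, ddof = 0,
computed from exact integer sums); the pipeline calls it with k = −2.
The low-zoom pass uses a constant grey level (default 75), which the
synthetic low-zoom photometry (background 140, particle core 10) places at
mid-contrast, so thresholded pixel areas are unbiased estimates of the
optical footprint.

## Segmentation chain

1. **Shadow-frame rejection (high zoom only).**  A provisional background
   threshold (stack median − k × *median* per-frame SD; the median keeps
   contaminated frames from inflating the statistic) flags implausibly
   dark pixels; a frame whose dark fraction exceeds 0.10 is rejected, and
   so are its tile-grid neighbours (±1 tile), because a shadow's penumbra
   extends past the frames it dominates — without the dilation, small
   penumbra slivers in retained border frames register as spurious
   fine-class detections.  Rejection happens before the stack threshold is
   computed and never alters retained pixel values.  Densities are always
   normalised by the retained imaged area, so rejection cannot bias them.
   An all-rejected stack raises an explicit error.
2. **First pass.**  Connected components (8-connectivity, the FIJI
   Analyze-Particles convention) of sub-threshold pixels, with an area
   floor of 4 px (low zoom) / 10 px (high zoom).  The high-zoom floor is a
   noise floor: with the threshold 2 SD below the background median,
   2.27 % of background pixels are dark; measured 8-connected cluster
   rates on pure noise are ≈ 340 clusters/Gpx at ≥ 6 px, ≈ 5/Gpx at ≥ 8 px
   and < 1/Gpx at ≥ 10 px.  The floor implies a detection limit of
   ≈ 0.7 µm² nominal area at the reference pixel size, below the fine
   class for all but ≈ 0.1 % of the reference fine size model.
3. **Crop refinement.**  Each detection is re-segmented in a crop of
   half-width 2 × equivalent radius + 4 px (clamped to [6, 320] px) centred
   on it, sampled from the blue channel (low zoom) or the 8-bit grayscale
   RGB average (high zoom).  The local threshold is crop mean − c·crop SD
   with c = 1.5, floored at the global threshold minus a guard band
   (default 100 grey levels, rarely binding).  With the packaged contrast,
   the implied coverage cut sits near 0.5 for typical crop filling
   fractions, which is what makes refined areas ≈ unbiased (median
   absolute error ≈ 4 % in the fidelity runs) while first-pass areas at
   the high-zoom threshold are inflated.  The retained component must
   contain the crop centre (or best-overlap fallback) and overlap the
   first-pass mask by ≥ 50 %; otherwise the detection is flagged and falls
   back to its first-pass measurement rather than being dropped.
   Elongation is the fitted-ellipse major/minor axis ratio with a 0.7 px
   minor-axis floor (sub-pixel-wide fibers would otherwise divide by
   zero).

## Synthetic campaigns

The generator emulates exactly the structure the analysis assumes:

* **Counts** are Poisson with mean density × area, independently per class
  (fine, coarse, and a per-window rate of macroscopic objects).
* **Sizes** are log-normals parameterised by their mode, clipped by
  rejection to the half-open class supports.  Defaults: coarse mode
  155 µm², σ_log 0.35 on [50, 1500); fine mode 3 µm² (bacteriomorph
  scale), σ_log 0.6 on [0.5, 50); macroscopic mode 32 000 µm², σ_log 0.3
  on [1500, 2 × 10⁵).  The published histograms are monomodal and
  right-skewed but name no family; σ_log 0.35 makes the coarse 50 µm²-bin
  histogram mode decisively the bin containing 155 µm².
* **Shapes**: discs (cocci), two-overlapping-disc division figures with a
  faint evaporation-halo annulus (the halo is rendered ≈ 8 grey levels
  below background and is *not* part of the ground-truth area; the
  refinement threshold excludes it), regular hexagons (scale discs),
  high-aspect capsules (fibers, aspect 5–15), irregular star polygons
  (angular crystals) and unions of rotated rectangles (parallelepipedic
  aggregates).  Shapes are rasterised at 4× supersampling with a random
  sub-pixel phase; coverage sums are calibrated to the nominal area
  (≤ 3–4 % error; ≤ 2 % for compact shapes).
* **Placement** is uniform in x; along the flow axis y an optional
  exponential (density ∝ exp(−s·y/H)) or linear gradient applies, sampled
  by inverse CDF.  Positive strength concentrates particles at the
  aperture.  The packaged stratified presets use s = +2 (coarse) and
  s = −2 (fine), reproducing the reported asymmetry signs; only the signs
  are constrained by the published histograms, the strengths are free
  parameters.  An MLE (`fit_gradient`) recovers s from ground-truth
  positions and anchors the recovery tests.
* **Frames** partition the scanned region with no overlap, as a stage tile
  scan delivers them.  A particle crossing a tile boundary is rendered
  clipped in each tile; split detections conserve total area exactly
  (coverage statistics are unbiased) at the cost of a ≤ 1 % double-count
  bias on counts (crossing probabilities ≈ 0.35 % coarse at low zoom,
  ≈ 1 % fine at high zoom), well under the replicate-window sampling
  error.  Macroscopic objects additionally cast a penumbra disc
  (2.5 × equivalent radius, 60 grey levels deep at high zoom — below the
  stack threshold, so it must trigger rejection; 40 at low zoom — above
  the constant threshold, so low-zoom coverage is unaffected by shadows).
* **Noise** is additive Gaussian (SD 5 grey levels) on every channel;
  identical config + seed gives bit-identical frames and tables.

### Reference campaigns

`reference_config(campaign, timepoint)` packages the published campaign
parameters: exposure durations (193/41/95/354/365 days), occupancy rates
(η = 1.0 for the high-occupancy exposures, 0.35 for the low), and the
per-campaign density centerlines (coarse 2.45/2.01/0.36 /mm², fine
4.45/4.68/1.02 and 3.82 /mm² at the intermediate timepoint).  Values never
printed are fixed once, by interpolation: the MATISS-2 coarse densities at
41/95 days sit on the line through the origin and the 354-day value
(near-linear accumulation), the fine density at 41 days on the line
through the 95- and 354-day values.  Macroscopic-object rates are not
published; the MATISS-2 values (8 per window at 354 days, scaling with
exposure) are set so the expected total low-zoom coverage matches the
reported ≈ 0.5 %/yr — coverage is necessarily dominated by rare large
debris, since 2 coarse particles/mm² of ≤ 1500 µm² each cannot exceed
≈ 0.3 %/yr.  Campaign reference configs use gradient "none" (the density
targets are placement-free); stratification is exercised by the dedicated
stratified presets.

θ in the occupancy association is the per-campaign contamination rate:
density/exposure for single-timepoint campaigns and the fitted WLS slope
for the MATISS-2 kinetics series, each paired with its campaign's η.  The
kinetics line is fitted with a free intercept (weights 1/SE², SE = SD/√n;
zero SDs fall back to an unweighted fit with a note); a forced-zero
intercept is available.  The asymmetry index
(N_far − N_near)/(N_far + N_near) is a standard normalised difference,
sign-anchored to the aperture-at-0 convention, and reported as missing
(not 0) for empty profiles.

## Problem sizes

The desk-scale runs trade acquisition scale for replicates.  Low zoom uses
4 tiles of 1818² px at 2.2 µm/px (full window coverage); high zoom tiles a
sub-region strip with 1024² px frames at 0.35 µm/px — a calibration that
still resolves the 0.5 µm² fine floor at ≥ 4 px (the package default of
0.22 µm/px remains available, as does a "full" preset with the flight
frame counts of 30/1452 per window).  Replicate-window counts (20–24) and
per-campaign scan areas were sized for ≈ 4–5 % standard error on the mean
densities; the low-density MATISS-2.5 campaign scans ≈ 20 mm² per window
for the same reason.  High-zoom scans of gradient-free campaigns may
legitimately sample a sub-region; with gradients on, densities are only
interpretable if the scan spans the full flow axis.

## Known limitations

* Window-to-window dispersion is purely Poisson; the published ±SDs
  exceed Poisson dispersion (real windows saw heterogeneous air loads), so
  only mean densities — not dispersions — are recovered quantities.
* Shape families exist only in the generator; the measurement chain does
  not classify detected particles by shape, and colour information (RGB
  gains) is acquisition metadata, not simulated.
* No tile registration errors, illumination drift or flat-field structure
  beyond the local refinement's reach; passing tests show the chain is
  correct on its assumed imaging model, not that it is robust to optics
  the generator does not emulate.
* Sub-pixel (< 0.5 µm²) objects are rendered as unresolved discs and
  reported as a separate "subresolution" class, excluded from fine
  statistics.
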