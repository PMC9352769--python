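# matiss — surface-contamination measurement on tile-scanned coupon windows

Passive exposure coupons (8 × 8 mm hydrophobic-coated glass windows in the
MATISS sample holders flown in the ISS Columbus module) collect airborne
particles over months.  Tile-scanning optical microscopy at two
magnifications turns each window into a stack of RGB frames; the analysis
problem is to segment every deposited particle, measure its position, area
and elongation, and summarise contamination as per-window densities, size
distributions, flow-axis deposition profiles, accumulation kinetics and an
area-coverage rate.

The flight imagery is not publicly deposited, so this package implements
the measurement chain **closed-loop**: a synthetic tile-scan generator with
exact ground truth reproduces the statistical structure of the data
(Poisson-placed particles, right-skewed class-bound size models, shape
families, deposition gradients, macroscopic shadow-casting debris), and
every stage of the analysis is validated by recovering what was seeded.
It is intended for the contamination-monitoring niche: people building or
re-analysing passive particle-collection experiments.

## The measurement chain

Segmentation runs on the blue channel of the RGB tiles, dark particles on a
bright background:

* **Low zoom (×3)** — constant, empirically set grey threshold
  (default 75); used for the *coarse* fraction, 50 ≤ A < 1500 µm².
* **High zoom (×30)** — frames whose shadow from a macroscopic object
  (A ≥ 1500 µm²) would mask small particles are rejected first (dark-pixel
  fraction rule, dilated one tile); the remaining stack is thresholded at
  the stack statistic *median − k·mean(per-frame SD)*, k = 2; used for the
  *fine* fraction, 0.5 ≤ A < 50 µm².
* **Refinement** — every first-pass detection is re-segmented in a crop
  centred on it with a local threshold (*crop mean − c·crop SD*, c = 1.5),
  which corrects areas for local background structure and strips
  evaporation halos.  Areas are calibrated to µm² and classified with
  half-open, lower-inclusive bounds.

Summary statistics follow the published conventions: per-window densities
(count / imaged area), mean ± sample SD over replicate windows, 50 µm²- and
2.5 µm²-bin size histograms with cumulative curves, flow-axis profiles with
an asymmetry index (N_far − N_near)/(N_far + N_near) (aperture at y = 0),
weighted least-squares density-vs-time kinetics, coverage in % of window
area per year, and the contamination rate θ tabulated against the module
occupancy rate η.

## Worked example

Simulate one window of the packaged MATISS-2 354-day reference campaign
and measure it end-to-end:

```python
import numpy as np
from matiss import reference_config, simulate_window, measure_window, coverage_rate

cfg = reference_config("MATISS-2", 354)          # published 354-day campaign
rng = np.random.default_rng([cfg.seed, 0, 0])    # window 0, low zoom
sim = simulate_window(cfg, "low", rng)           # 8 x 8 mm tile scan + truth
window, log = measure_window(sim.stack, "w0")    # segment -> refine -> classify

print(f"threshold used: {log['threshold']:.0f} (grey level)")
print(f"coarse density: {window.density_coarse:.2f} /mm^2 "
      f"(campaign centerline 2.01 +/- 0.84)")
print(f"macroscopic objects: {window.count('macroscopic')}")
print(f"coverage rate: "
      f"{coverage_rate(window.particles, window.window_area_mm2, 354):.2f} %/yr")
```

prints

```
threshold used: 75 (grey level)
coarse density: 2.09 /mm^2 (campaign centerline 2.01 +/- 0.84)
macroscopic objects: 13
coverage rate: 0.75 %/yr
```

The measured coarse density sits on the seeded campaign centerline
(2.01 /mm²) within single-window Poisson noise; the coverage rate of one
window is dominated by the handful of macroscopic debris objects it
happens to carry (13 here), and averages to ≈ 0.5 %/yr over replicate
windows.  The `analysis/` scripts run the full desk-scale study: example
window rendering, detection fidelity (precision/recall ≥ 0.99/0.95 with
≈ 4 % median area error), recovery of all published campaign centerlines,
kinetics + θ–η association, and flow-axis stratification; each writes its
tables under `results/`.

A thin CLI mirrors the library for shell use:

```bash
matiss simulate --campaign MATISS-2.5 --timepoint 365 --zoom low --out sim/
matiss segment  --zoom low --in sim/stack_low_w0.tif --out detections.csv
matiss validate --truth sim/truth_low_w0.csv --detections detections.csv --radius 10
```

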