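# Versioned analysis defaults. Values quoted by the measurement protocol
# (constant low-zoom grey threshold, stack-statistic multiplier, class
# bounds, 8 x 8 mm window) live here, not in code.
version: 1

window:
  size_um: 8000.0            # 8 x 8 mm coupon window

class_bounds:                # projected-area classes, half-open lower-inclusive
  fine_min_um2: 0.5
  coarse_min_um2: 50.0
  macro_min_um2: 1500.0

segmentation:
  low_zoom_threshold: 75     # constant grey level, empirically set for the low-zoom pass
  high_zoom_k: 2.0           # stack-statistic multiplier (median -/+ k * mean frame SD)
  reject_dark_fraction: 0.10 # high-zoom frame rejected above this dark-pixel fraction
  reject_dilate_frames: 1    # also drop tile-grid neighbours of rejected frames
  min_area_px_low: 4         # detection floor, low zoom (no noise floor at 13 sigma)
  min_area_px_high: 10       # detection floor, high zoom (noise clusters < 1 per Gpx)
  connectivity: 8
  crop_margin_px: 4          # crop half-width = 2 * equivalent radius + margin
  crop_halfwidth_min_px: 6
  crop_halfwidth_max_px: 320
  local_threshold_c: 1.5     # local threshold = crop mean - c * crop SD
  local_floor_guard: 100     # local threshold floored at global threshold - guard
  min_refine_overlap: 0.5    # refined component must overlap first-pass mask this much

imaging:
  # Desk-scale tile-scan geometry. The "full" preset reproduces the flight
  # acquisition scale (30 low-zoom / 1452 high-zoom frames per window).
  low:
    pixel_size_um: 2.2
    frame_shape: [1818, 1818]
    grid: [2, 2]             # nx columns (x) by ny rows (y, flow axis)
  high:
    pixel_size_um: 0.22
    frame_shape: [1024, 1024]
    grid: [4, 4]
  full:
    low:
      pixel_size_um: 2.2
      frame_shape: [1392, 1040]
      grid: [5, 6]
    high:
      pixel_size_um: 0.22
      frame_shape: [1392, 1040]
      grid: [33, 44]

rendering:
  # Transmitted-light convention: bright background, dark particles.
  # Low-zoom levels put the constant grey threshold 75 at mid-contrast;
  # high-zoom levels leave the stack statistic 2 SD below the background.
  background_low: 140.0
  background_high: 200.0
  particle_level_low: 10.0
  particle_level_high: 50.0
  halo_depth: 8.0            # faint evaporation halo, grey levels below background
  halo_radius_factor: 1.7    # halo outer radius / particle equivalent radius
  penumbra_depth_low: 40.0   # macroscopic-object shadow, low zoom (stays above threshold)
  penumbra_depth_high: 60.0  # high zoom (falls below stack threshold -> frame rejection)
  penumbra_radius_factor: 2.5
  noise_sd: 5.0
  supersample: 4             # sub-pixel rasterisation factor for shape coverage
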