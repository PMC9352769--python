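#!/usr/bin/env python
"""Render one example window of the MATISS-2 354-day reference campaign.

Writes a low-zoom tile scan (full 8 × 8 mm window) and a small high-zoom
strip, with their ground-truth tables, under results/example_window/.
These are the artefacts the measurement scripts consume.
"""

from pathlib import Path

import numpy as np

from matiss.config import ImagingGeometry
from matiss.io import write_stack, write_table
from matiss.synthetic import reference_config, simulate_window

OUT = Path(__file__).resolve().parents[1] / "results" / "example_window"


def main() -> None:
    cfg = reference_config("MATISS-2", 354)
    rng = np.random.default_rng([cfg.seed, 0, 0])
    low = simulate_window(cfg, "low", rng)
    write_stack(low.stack, OUT / "stack_low.tif")
    write_table(low.truth, OUT / "truth_low.csv")
    print(f"low zoom: {low.stack.n_frames} frames, "
          f"{len(low.truth)} ground-truth particles")

    small = cfg.with_(imaging_high=ImagingGeometry(0.35, (1024, 1024), (2, 6)))
    rng = np.random.default_rng([cfg.seed, 0, 1])
    high = simulate_window(small, "high", rng)
    write_stack(high.stack, OUT / "stack_high.tif")
    write_table(high.truth, OUT / "truth_high.csv")
    print(f"high zoom: {high.stack.n_frames} frames, "
          f"{len(high.shadow_frames)} shadowed frames -> {OUT}")


if __name__ == "__main__":
    main()
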