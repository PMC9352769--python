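#!/usr/bin/env python
"""Flow-axis deposition stratification on stratified-placement windows.

Places coarse and fine particles under the packaged gradient presets
(coarse toward the holder aperture at y = 0, fine away from it), builds
the particle-count profiles along the flow axis and reports the asymmetry
indices.  Writes results/stratification.csv and a profile figure.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from matiss.stats import spatial_profile
from matiss.synthetic import fit_gradient, place_particles, stratified_config

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cfg = stratified_config()
    rng = np.random.default_rng(91)
    rows = []
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.2), sharey=True)
    for ax, cls in zip(axes, ("coarse", "fine")):
        placed = place_particles(cfg, 4000, rng, cls)
        prof = spatial_profile(placed, 8, cfg.window_um)
        s_hat, se = fit_gradient(placed.y_um.to_numpy(), cfg.window_um)
        rows.append({
            "size_class": cls,
            "gradient_seeded": cfg.gradient(cls).strength,
            "gradient_fitted": round(s_hat, 3),
            "gradient_se": round(se, 3),
            "asymmetry_index": round(prof.asymmetry_index, 3),
        })
        centers = (prof.y_bin_edges[:-1] + prof.y_bin_edges[1:]) / 2
        ax.barh(centers, prof.counts, height=np.diff(prof.y_bin_edges) * 0.9)
        ax.set_title(f"{cls} (A = {prof.asymmetry_index:+.2f})")
        ax.set_xlabel("particles per bin")
    axes[0].set_ylabel("y along flow axis (µm), aperture at 0")
    fig.tight_layout()
    fig.savefig(OUT / "stratification.png", dpi=150)

    df = pd.DataFrame(rows)
    df.to_csv(OUT / "stratification.csv", index=False)
    print(df.to_string(index=False))
    print("\nCoarse particles pile up near the aperture (negative index), "
          "fine particles far from it (positive); the placement MLE "
          "recovers the seeded gradient strengths.")


if __name__ == "__main__":
    main()
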