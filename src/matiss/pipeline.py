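"""End-to-end orchestration: simulate → segment → calibrate → summarise.

The replicate-window campaign runs used for closed-loop validation live
here: each window is simulated and measured independently with a seed
derived from (campaign seed, window index, zoom), so any window of any
campaign is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CampaignConfig, ClassBounds, SegmentationConfig
from .frames import FrameStack
from .morphometry import PARTICLE_COLUMNS, calibrate
from .segmentation import run_segmentation
from .stats import WindowResult, density_summary
from .synthetic import draw_ground_truth, simulate_window

__all__ = [
    "measure_window",
    "measure_campaign",
    "ground_truth_windows",
    "CampaignMeasurement",
]

_ZOOM_CODE = {"low": 0, "high": 1}


def measure_window(
    stack: FrameStack,
    window_id: str = "w0",
    seg_cfg: SegmentationConfig | None = None,
    bounds: ClassBounds | None = None,
) -> tuple[WindowResult, dict]:
    """Run the measurement chain on one stack and calibrate the result.

    The window area used for densities is the retained (non-rejected)
    imaged area, so shadow-frame rejection cannot bias density estimates.
    """
    detections, log = run_segmentation(stack, seg_cfg)
    particles = calibrate(detections, stack.pixel_size_um, bounds)
    result = WindowResult(
        window_id=window_id,
        window_area_mm2=log["retained_area_mm2"],
        particles=particles,
    )
    return result, log


@dataclass
class CampaignMeasurement:
    """Replicate-window measurement of one campaign at one zoom."""

    config: CampaignConfig
    zoom: str
    windows: list[WindowResult]
    logs: list[dict] = field(default_factory=list)
    truths: list[pd.DataFrame] = field(default_factory=list)

    def summary(self, size_class: str) -> tuple[float, float, int]:
        """(mean, SD, n) of per-window densities for a class."""
        return density_summary(self.windows, size_class)

    @property
    def particles(self) -> pd.DataFrame:
        frames = [w.particles.assign(window_id=w.window_id) for w in self.windows]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=PARTICLE_COLUMNS + ["window_id"]
        )

    @property
    def total_area_mm2(self) -> float:
        return float(sum(w.window_area_mm2 for w in self.windows))


def _window_rng(seed: int, window_index: int, zoom: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(window_index), _ZOOM_CODE[zoom]])


def measure_campaign(
    config: CampaignConfig,
    zoom: str,
    n_windows: int | None = None,
    seed: int | None = None,
    seg_cfg: SegmentationConfig | None = None,
    keep_truth: bool = False,
) -> CampaignMeasurement:
    """Simulate and measure ``n_windows`` replicate windows of a campaign."""
    n = n_windows if n_windows is not None else config.n_windows
    base_seed = config.seed if seed is None else seed
    seg_cfg = seg_cfg or SegmentationConfig.from_defaults()
    windows, logs, truths = [], [], []
    for w in range(n):
        rng = _window_rng(base_seed, w, zoom)
        sim = simulate_window(config, zoom, rng)
        result, log = measure_window(sim.stack, window_id=f"{config.name}-w{w}",
                                     seg_cfg=seg_cfg)
        windows.append(result)
        logs.append(log)
        if keep_truth:
            truths.append(sim.truth)
    return CampaignMeasurement(config=config, zoom=zoom, windows=windows,
                               logs=logs, truths=truths)


def ground_truth_windows(
    config: CampaignConfig, n_windows: int, seed: int | None = None
) -> list[WindowResult]:
    """Replicate windows built from ground truth alone (no imaging).

    The generator-level oracle for statistics that do not depend on the
    optical chain: full-window areas, exact placed counts.
    """
    base_seed = config.seed if seed is None else seed
    area_mm2 = (config.window_um / 1000.0) ** 2
    out = []
    for w in range(n_windows):
        rng = np.random.default_rng([int(base_seed), int(w), 7])
        truth = draw_ground_truth(config, rng)
        particles = truth.rename(columns={})[
            ["x_um", "y_um", "area_um2", "size_class"]
        ].assign(elongation=np.nan, mean_intensity=np.nan)
        out.append(
            WindowResult(
                window_id=f"{config.name}-gt{w}",
                window_area_mm2=area_mm2,
                particles=particles[
                    [c for c in PARTICLE_COLUMNS if c in particles.columns
                     or c in ("elongation", "mean_intensity")]
                ],
            )
        )
    return out
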