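"""Calibration of detections into physical particles and size classes."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ClassBounds
from .errors import ConfigurationError

__all__ = ["Particle", "classify", "classify_areas", "calibrate", "PARTICLE_COLUMNS"]

PARTICLE_COLUMNS = [
    "x_um",
    "y_um",
    "area_um2",
    "elongation",
    "mean_intensity",
    "size_class",
]


@dataclass(frozen=True)
class Particle:
    """One calibrated particle in window coordinates (µm, µm²)."""

    x_um: float
    y_um: float
    area_um2: float
    elongation: float
    mean_intensity: float
    size_class: str

    def __post_init__(self) -> None:
        if self.area_um2 <= 0:
            raise ConfigurationError("particle area must be positive")
        if not np.isnan(self.elongation) and self.elongation < 1.0:
            raise ConfigurationError("elongation is major/minor and must be >= 1")


def classify(area_um2: float, bounds: ClassBounds | None = None) -> str:
    """Size class of a projected area under half-open, lower-inclusive bounds.

    fine [0.5, 50), coarse [50, 1500), macroscopic [1500, ∞) µm² by
    default; positive areas below the fine floor are ``subresolution``.
    """
    if area_um2 <= 0:
        raise ConfigurationError("area must be positive")
    b = bounds or ClassBounds()
    if area_um2 >= b.macro_min_um2:
        return "macroscopic"
    if area_um2 >= b.coarse_min_um2:
        return "coarse"
    if area_um2 >= b.fine_min_um2:
        return "fine"
    return "subresolution"


def classify_areas(areas, bounds: ClassBounds | None = None) -> np.ndarray:
    """Vectorised :func:`classify`."""
    b = bounds or ClassBounds()
    a = np.asarray(areas, dtype=float)
    if (a <= 0).any():
        raise ConfigurationError("areas must be positive")
    out = np.full(a.shape, "subresolution", dtype=object)
    out[a >= b.fine_min_um2] = "fine"
    out[a >= b.coarse_min_um2] = "coarse"
    out[a >= b.macro_min_um2] = "macroscopic"
    return out.astype(str)


def calibrate(
    detections: pd.DataFrame,
    pixel_size_um: float,
    bounds: ClassBounds | None = None,
) -> pd.DataFrame:
    """Detection table → calibrated particle table.

    Areas are pixel counts × pixel_size², except where the segmentation
    already reported a refined physical area (``area_um2`` column), which
    is kept.  Centroids already in µm pass through; pixel centroids are
    converted.
    """
    if pixel_size_um <= 0:
        raise ConfigurationError("pixel_size_um must be positive")
    df = detections.copy()
    if "area_um2" not in df or df["area_um2"].isna().all():
        df["area_um2"] = df["area_px"] * pixel_size_um**2
    if "x_um" not in df:
        df["x_um"] = (df["col_px"] + 0.5) * pixel_size_um
        df["y_um"] = (df["row_px"] + 0.5) * pixel_size_um
    for col in ("elongation", "mean_intensity"):
        if col not in df:
            df[col] = np.nan
    df["size_class"] = classify_areas(df["area_um2"].to_numpy(), bounds)
    return df[[c for c in PARTICLE_COLUMNS if c in df.columns]].reset_index(drop=True)
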