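"""Configuration objects for the contamination-measurement pipeline.

All protocol constants (class bounds, thresholds, window geometry) are read
from the versioned ``data/defaults.yaml`` shipped with the package; nothing
is hard-coded.  A :class:`CampaignConfig` bundles everything needed to
simulate and analyse one exposure campaign; a :class:`SegmentationConfig`
bundles the measurement-chain parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from importlib import resources
from typing import Literal

import numpy as np
import yaml

from .errors import ConfigurationError

__all__ = [
    "load_defaults",
    "SizeModel",
    "Gradient",
    "ImagingGeometry",
    "RenderingParams",
    "ClassBounds",
    "SegmentationConfig",
    "CampaignConfig",
]

SHAPE_FAMILIES = (
    "coccus",
    "dividing_coccus_with_halo",
    "hexagonal_disc",
    "fiber",
    "angular_crystal",
    "parallelepiped_aggregate",
)


def _read_packaged_yaml(name: str) -> dict:
    with resources.files("matiss.data").joinpath(name).open("r") as fh:
        return yaml.safe_load(fh)


def load_defaults() -> dict:
    """Return the packaged analysis defaults as a nested dict."""
    return _read_packaged_yaml("defaults.yaml")


# ---------------------------------------------------------------------------
# size models


@dataclass(frozen=True)
class SizeModel:
    """Right-skewed projected-area model for one size class.

    A log-normal parameterised by its mode (the most probable area, µm²)
    and log-scale sigma, clipped by rejection to the half-open class
    support ``[min_um2, max_um2)``.
    """

    family: Literal["lognormal"]
    mode_um2: float
    sigma_log: float
    min_um2: float
    max_um2: float

    def __post_init__(self) -> None:
        if self.family != "lognormal":
            raise ConfigurationError(f"unknown size-model family {self.family!r}")
        if not (0 < self.min_um2 < self.max_um2):
            raise ConfigurationError("size-model support must satisfy 0 < min < max")
        if self.mode_um2 <= 0 or self.sigma_log <= 0:
            raise ConfigurationError("size-model mode and sigma must be positive")

    @property
    def mu_log(self) -> float:
        # mode = exp(mu - sigma^2)  =>  mu = ln(mode) + sigma^2
        return float(np.log(self.mode_um2) + self.sigma_log**2)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` areas (µm²) by rejection onto the class support."""
        if n == 0:
            return np.empty(0)
        out = np.empty(0)
        while out.size < n:
            draw = rng.lognormal(self.mu_log, self.sigma_log, size=max(2 * n, 16))
            keep = draw[(draw >= self.min_um2) & (draw < self.max_um2)]
            out = np.concatenate([out, keep])
        return out[:n]

    def mean(self, n_grid: int = 200_000) -> float:
        """Truncated mean of the model (numerical, for expectations)."""
        from scipy import stats as sps

        dist = sps.lognorm(s=self.sigma_log, scale=np.exp(self.mu_log))
        lo, hi = dist.cdf(self.min_um2), dist.cdf(self.max_um2)
        q = np.linspace(lo, hi, n_grid, endpoint=False) + (hi - lo) / (2 * n_grid)
        return float(dist.ppf(q).mean())


# ---------------------------------------------------------------------------
# placement gradients


@dataclass(frozen=True)
class Gradient:
    """Deposition gradient along the flow axis y (aperture at y = 0).

    ``exponential``: density ∝ exp(−strength · y / H); positive strength
    concentrates particles near the aperture.  ``linear``: density ∝
    1 + strength · (y/H − 1/2) with |strength| ≤ 2.  ``none``: uniform.
    """

    kind: Literal["none", "linear", "exponential"] = "none"
    strength: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "linear", "exponential"):
            raise ConfigurationError(f"unknown gradient kind {self.kind!r}")
        if self.kind == "linear" and abs(self.strength) > 2:
            raise ConfigurationError("linear gradient strength must be in [-2, 2]")

    def sample_y(self, n: int, height_um: float, rng: np.random.Generator) -> np.ndarray:
        """Inverse-CDF sample of n flow-axis positions in [0, height_um)."""
        u = rng.random(n)
        s = self.strength
        if self.kind == "none" or abs(s) < 1e-9:
            return u * height_um
        if self.kind == "exponential":
            t = -np.log1p(-u * -np.expm1(-s)) / s
            return t * height_um
        # linear: solve (s/2) t^2 + (1 - s/2) t - u = 0 for t in [0, 1)
        a, b = s / 2.0, 1.0 - s / 2.0
        t = (-b + np.sqrt(b * b + 4 * a * u)) / (2 * a)
        return t * height_um

    def pdf_y(self, y: np.ndarray, height_um: float) -> np.ndarray:
        t = np.asarray(y) / height_um
        s = self.strength
        if self.kind == "none" or abs(s) < 1e-9:
            f = np.ones_like(t)
        elif self.kind == "exponential":
            f = s * np.exp(-s * t) / -np.expm1(-s)
        else:
            f = 1.0 + s * (t - 0.5)
        return f / height_um


# ---------------------------------------------------------------------------
# imaging geometry


@dataclass(frozen=True)
class ImagingGeometry:
    """Tile-scan geometry for one zoom level.

    Frames are laid out on a regular, non-overlapping ``grid = (nx, ny)``
    (columns along x, rows along the flow axis y) starting at the window
    corner nearest the holder aperture.  Tiles partition the scanned region;
    a particle crossing a tile boundary is drawn clipped in every tile it
    touches, as in a real tile scan.
    """

    pixel_size_um: float
    frame_shape: tuple[int, int]  # (rows, cols) px
    grid: tuple[int, int]  # (nx, ny) frames

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ConfigurationError("pixel_size_um must be positive")
        if min(self.frame_shape) < 8 or min(self.grid) < 1:
            raise ConfigurationError("degenerate frame shape or grid")

    @property
    def n_frames(self) -> int:
        return self.grid[0] * self.grid[1]

    @property
    def frame_extent_um(self) -> tuple[float, float]:
        """(width, height) of one frame footprint in µm."""
        rows, cols = self.frame_shape
        return cols * self.pixel_size_um, rows * self.pixel_size_um

    @property
    def scan_extent_um(self) -> tuple[float, float]:
        w, h = self.frame_extent_um
        return self.grid[0] * w, self.grid[1] * h

    @property
    def frame_area_mm2(self) -> float:
        w, h = self.frame_extent_um
        return w * h / 1e6

    def frame_origins(self) -> np.ndarray:
        """(n_frames, 2) array of (x0, y0) µm, row-major over the grid."""
        w, h = self.frame_extent_um
        nx, ny = self.grid
        cols, rows = np.meshgrid(np.arange(nx), np.arange(ny))
        return np.column_stack([(cols.ravel() * w), (rows.ravel() * h)]).astype(float)


@dataclass(frozen=True)
class RenderingParams:
    """Photometric parameters of the synthetic transmitted-light images."""

    background_low: float = 140.0
    background_high: float = 200.0
    particle_level_low: float = 10.0
    particle_level_high: float = 50.0
    halo_depth: float = 8.0
    halo_radius_factor: float = 1.7
    penumbra_depth_low: float = 40.0
    penumbra_depth_high: float = 60.0
    penumbra_radius_factor: float = 2.5
    noise_sd: float = 5.0
    supersample: int = 4

    def background(self, zoom: str) -> float:
        return self.background_low if zoom == "low" else self.background_high

    def particle_level(self, zoom: str) -> float:
        return self.particle_level_low if zoom == "low" else self.particle_level_high

    def penumbra_depth(self, zoom: str) -> float:
        return self.penumbra_depth_low if zoom == "low" else self.penumbra_depth_high


# ---------------------------------------------------------------------------
# classification bounds


@dataclass(frozen=True)
class ClassBounds:
    """Half-open, lower-inclusive projected-area class bounds (µm²).

    fine [fine_min, coarse_min), coarse [coarse_min, macro_min),
    macroscopic [macro_min, ∞), subresolution (0, fine_min).  Boundary
    points go to the larger class (ties at 50 µm² are coarse).
    """

    fine_min_um2: float = 0.5
    coarse_min_um2: float = 50.0
    macro_min_um2: float = 1500.0

    def __post_init__(self) -> None:
        if not (0 < self.fine_min_um2 < self.coarse_min_um2 < self.macro_min_um2):
            raise ConfigurationError("class bounds must be strictly increasing and positive")


# ---------------------------------------------------------------------------
# segmentation


@dataclass(frozen=True)
class SegmentationConfig:
    """Parameters of the two-pass measurement chain.

    ``low_zoom_threshold`` is the constant grey level of the low-zoom pass.
    ``high_zoom_k`` is the magnitude of the stack-statistic multiplier: the
    high-zoom pass thresholds at median − k · mean(per-frame SD), i.e. the
    stack statistic applied on the dark side of the background median
    (dark-particle convention).  The refinement threshold within a crop is
    ``crop mean − local_threshold_c · crop SD``, floored at the global
    threshold minus ``local_floor_guard``.
    """

    low_zoom_threshold: float = 75.0
    high_zoom_k: float = 2.0
    reject_dark_fraction: float = 0.10
    reject_dilate_frames: int = 1
    min_area_px_low: int = 4
    min_area_px_high: int = 10
    connectivity: Literal[4, 8] = 8
    crop_margin_px: int = 4
    crop_halfwidth_min_px: int = 6
    crop_halfwidth_max_px: int = 320
    local_threshold_c: float = 1.5
    local_floor_guard: float = 100.0
    min_refine_overlap: float = 0.5

    def __post_init__(self) -> None:
        if self.high_zoom_k <= 0:
            raise ConfigurationError("high_zoom_k must be positive")
        if self.connectivity not in (4, 8):
            raise ConfigurationError("connectivity must be 4 or 8")
        if not (0 < self.reject_dark_fraction <= 1):
            raise ConfigurationError("reject_dark_fraction must be in (0, 1]")
        if self.crop_halfwidth_min_px < 1:
            raise ConfigurationError("crop half-width must be >= 1")

    def min_area_px(self, zoom: str) -> int:
        return self.min_area_px_low if zoom == "low" else self.min_area_px_high

    @classmethod
    def from_defaults(cls, overrides: dict | None = None) -> "SegmentationConfig":
        d = dict(load_defaults()["segmentation"])
        d.update(overrides or {})
        return cls(**d)


# ---------------------------------------------------------------------------
# campaign


def _default_imaging(zoom: str) -> ImagingGeometry:
    d = load_defaults()["imaging"][zoom]
    return ImagingGeometry(
        pixel_size_um=d["pixel_size_um"],
        frame_shape=tuple(d["frame_shape"]),
        grid=tuple(d["grid"]),
    )


def full_preset_imaging(zoom: str) -> ImagingGeometry:
    """Flight-scale acquisition geometry (30 low / 1452 high frames/window)."""
    d = load_defaults()["imaging"]["full"][zoom]
    return ImagingGeometry(
        pixel_size_um=d["pixel_size_um"],
        frame_shape=tuple(d["frame_shape"]),
        grid=tuple(d["grid"]),
    )


@dataclass(frozen=True)
class CampaignConfig:
    """Generator + analysis parameters for one exposure campaign.

    Densities are expected particle counts per mm² of window surface;
    ``macro_rate`` is the expected number of macroscopic objects per
    8 × 8 mm window.  ``occupancy_rate`` (η) is the crewed fraction of the
    exposure period, carried as a covariate.  The per-class gradients act on
    placement only and leave the expected densities unchanged.
    """

    name: str
    exposure_days: int
    occupancy_rate: float
    coarse_density: float
    fine_density: float
    macro_rate: float = 0.0
    size_model_coarse: SizeModel = field(
        default_factory=lambda: SizeModel("lognormal", 155.0, 0.35, 50.0, 1500.0)
    )
    size_model_fine: SizeModel = field(
        default_factory=lambda: SizeModel("lognormal", 3.0, 0.6, 0.5, 50.0)
    )
    size_model_macro: SizeModel = field(
        default_factory=lambda: SizeModel("lognormal", 32000.0, 0.3, 1500.0, 200000.0)
    )
    shape_mix_coarse: dict = field(
        default_factory=lambda: {"coccus": 0.2, "hexagonal_disc": 0.2, "fiber": 0.2,
                                 "angular_crystal": 0.2, "parallelepiped_aggregate": 0.2}
    )
    shape_mix_fine: dict = field(
        default_factory=lambda: {"coccus": 0.45, "dividing_coccus_with_halo": 0.35,
                                 "fiber": 0.10, "angular_crystal": 0.10}
    )
    shape_mix_macro: dict = field(
        default_factory=lambda: {"parallelepiped_aggregate": 0.6, "angular_crystal": 0.4}
    )
    gradient_coarse: Gradient = field(default_factory=Gradient)
    gradient_fine: Gradient = field(default_factory=Gradient)
    noise_sd: float = 5.0
    seed: int = 0
    window_um: float = 8000.0
    imaging_low: ImagingGeometry = field(default_factory=lambda: _default_imaging("low"))
    imaging_high: ImagingGeometry = field(default_factory=lambda: _default_imaging("high"))
    rendering: RenderingParams = field(default_factory=RenderingParams)
    n_windows: int = 20
    eta_timepoint: float | None = None  # occupancy during this timepoint's exposure

    def __post_init__(self) -> None:
        for attr in ("coarse_density", "fine_density", "macro_rate"):
            if getattr(self, attr) < 0:
                raise ConfigurationError(f"{attr} must be >= 0")
        if not (0.0 <= self.occupancy_rate <= 1.0):
            raise ConfigurationError("occupancy_rate must be in [0, 1]")
        if self.exposure_days <= 0:
            raise ConfigurationError("exposure_days must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        for mix_name in ("shape_mix_coarse", "shape_mix_fine", "shape_mix_macro"):
            mix = getattr(self, mix_name)
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ConfigurationError(f"{mix_name} proportions must sum to 1")
            unknown = set(mix) - set(SHAPE_FAMILIES)
            if unknown:
                raise ConfigurationError(f"{mix_name}: unknown shape families {unknown}")

    def imaging(self, zoom: str) -> ImagingGeometry:
        if zoom not in ("low", "high"):
            raise ConfigurationError(f"zoom must be 'low' or 'high', got {zoom!r}")
        return self.imaging_low if zoom == "low" else self.imaging_high

    def size_model(self, size_class: str) -> SizeModel:
        return {
            "coarse": self.size_model_coarse,
            "fine": self.size_model_fine,
            "macroscopic": self.size_model_macro,
        }[size_class]

    def density(self, size_class: str) -> float:
        """Expected particles per mm² of window for a class."""
        window_mm2 = (self.window_um / 1000.0) ** 2
        return {
            "coarse": self.coarse_density,
            "fine": self.fine_density,
            "macroscopic": self.macro_rate / window_mm2,
        }[size_class]

    def gradient(self, size_class: str) -> Gradient:
        if size_class == "fine":
            return self.gradient_fine
        return self.gradient_coarse  # coarse and macroscopic share the flow response

    def shape_mix(self, size_class: str) -> dict:
        return {
            "coarse": self.shape_mix_coarse,
            "fine": self.shape_mix_fine,
            "macroscopic": self.shape_mix_macro,
        }[size_class]

    def with_(self, **kw) -> "CampaignConfig":
        """Return a copy with fields replaced (dataclasses.replace wrapper)."""
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)
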