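"""Summary statistics of surface contamination.

Per-window particle densities and their campaign summaries, class size
distributions (histogram + cumulative curve), flow-axis deposition profiles
with an asymmetry index, accumulation kinetics (weighted least-squares
density-vs-time line), area-coverage rates, and the contamination-rate vs
occupancy-rate association.

Conventions
-----------
density        particles per mm² of (retained) imaged window surface
coverage rate  percent of window area covered per year of exposure
asymmetry      (N_far − N_near)/(N_far + N_near) across the window midline,
               near = lower half along the flow axis (aperture at y = 0)
θ (theta)      per-campaign contamination rate: density/exposure for a
               single-timepoint campaign, fitted WLS slope for a kinetics
               series — both in particles·mm⁻²·day⁻¹
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

__all__ = [
    "WindowResult",
    "SizeDistribution",
    "SpatialProfile",
    "KineticsFit",
    "window_density",
    "density_summary",
    "size_distribution",
    "spatial_profile",
    "fit_kinetics",
    "coverage_rate",
    "rate_vs_occupancy",
]

DAYS_PER_YEAR = 365.0


# ---------------------------------------------------------------------------
# windows and densities


@dataclass
class WindowResult:
    """All particles measured on one window plus its imaged area."""

    window_id: str
    window_area_mm2: float
    particles: pd.DataFrame  # morphometry.PARTICLE_COLUMNS

    def __post_init__(self) -> None:
        if self.window_area_mm2 <= 0:
            raise ConfigurationError("window_area_mm2 must be positive")

    def count(self, size_class: str | None = None) -> int:
        if size_class is None:
            return len(self.particles)
        return int((self.particles["size_class"] == size_class).sum())

    @property
    def density_fine(self) -> float:
        return window_density(self, "fine")

    @property
    def density_coarse(self) -> float:
        return window_density(self, "coarse")


def window_density(window: WindowResult, size_class: str) -> float:
    """Exact count-per-area density (particles/mm²) of one class."""
    return window.count(size_class) / window.window_area_mm2


def density_summary(
    windows: list[WindowResult], size_class: str
) -> tuple[float, float, int]:
    """Mean, sample SD (n−1) and n of per-window densities of one class."""
    if not windows:
        raise InputError("density_summary needs at least one window")
    d = np.array([window_density(w, size_class) for w in windows])
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return float(d.mean()), sd, int(d.size)


# ---------------------------------------------------------------------------
# size distributions


@dataclass
class SizeDistribution:
    size_class: str
    bin_edges: np.ndarray  # µm²
    counts: np.ndarray
    cumulative_fraction: np.ndarray

    @property
    def mode_bin_midpoint(self) -> float:
        """Midpoint (µm²) of the maximal-count bin — the most probable size."""
        i = int(np.argmax(self.counts))
        return float((self.bin_edges[i] + self.bin_edges[i + 1]) / 2.0)

    @property
    def n(self) -> int:
        return int(self.counts.sum())


_DEFAULT_BIN_WIDTHS = {"coarse": 50.0, "fine": 2.5}


def size_distribution(
    particles: pd.DataFrame,
    size_class: str,
    bin_width_um2: float | None = None,
    support: tuple[float, float] | None = None,
) -> SizeDistribution:
    """Histogram and cumulative size curve of one class.

    Bins are ``bin_width`` wide over the class support (defaults: 50 µm²
    bins on [50, 1500) for coarse, 2.5 µm² on [0.5, 50) for fine).  The
    cumulative curve is normalised to the class total, so it ends at 1
    whenever any particle exists.
    """
    bin_width = bin_width_um2 or _DEFAULT_BIN_WIDTHS.get(size_class)
    if bin_width is None or bin_width <= 0:
        raise ConfigurationError("bin_width_um2 must be positive")
    if support is None:
        support = {"coarse": (50.0, 1500.0), "fine": (0.5, 50.0)}.get(size_class)
    if support is None:
        raise ConfigurationError(f"no default support for class {size_class!r}")
    areas = particles.loc[
        particles["size_class"] == size_class, "area_um2"
    ].to_numpy(float) if "size_class" in particles else particles["area_um2"].to_numpy(float)
    lo, hi = support
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, _ = np.histogram(areas, bins=edges)
    total = counts.sum()
    cum = np.cumsum(counts) / total if total else np.zeros_like(counts, dtype=float)
    return SizeDistribution(
        size_class=size_class,
        bin_edges=edges,
        counts=counts,
        cumulative_fraction=cum,
    )


# ---------------------------------------------------------------------------
# flow-axis stratification


@dataclass
class SpatialProfile:
    y_bin_edges: np.ndarray
    counts: np.ndarray
    asymmetry_index: float | None  # None when no particle is in scope

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def spatial_profile(
    particles: pd.DataFrame, n_bins: int, window_height_um: float
) -> SpatialProfile:
    """Particle-count histogram along the flow axis with asymmetry index.

    The index is (N_far − N_near)/(N_far + N_near), near/far being the
    window halves closest to/farthest from the aperture (y = 0): negative
    when deposition concentrates near the aperture.  It is undefined (None)
    for an empty profile, never silently 0.
    """
    if n_bins < 2:
        raise ConfigurationError("n_bins must be >= 2")
    y = particles["y_um"].to_numpy(float)
    edges = np.linspace(0.0, window_height_um, n_bins + 1)
    counts, _ = np.histogram(y, bins=edges)
    total = counts.sum()
    if total == 0:
        return SpatialProfile(y_bin_edges=edges, counts=counts, asymmetry_index=None)
    near = int((y < window_height_um / 2.0).sum())
    far = int(total - near)
    return SpatialProfile(
        y_bin_edges=edges,
        counts=counts,
        asymmetry_index=(far - near) / (far + near),
    )


# ---------------------------------------------------------------------------
# kinetics


@dataclass
class KineticsFit:
    slope: float  # particles mm^-2 day^-1
    intercept: float
    slope_se: float
    intercept_se: float
    residuals: np.ndarray
    weighted: bool
    note: str = ""
    series: pd.DataFrame = field(default_factory=pd.DataFrame)


def fit_kinetics(series, force_zero_intercept: bool = False) -> KineticsFit:
    """Weighted least-squares accumulation line through (t, density).

    ``series`` is an iterable of (exposure_days, mean_density, sd, n);
    weights are 1/SE² with SE = sd/√n.  The intercept is fitted by default
    (a forced-zero fit is available).  Zero or missing SEs fall back to an
    unweighted fit, noted on the result.
    """
    import statsmodels.api as sm

    df = pd.DataFrame(list(series), columns=["exposure_days", "mean", "sd", "n"])
    if len(df) < 2:
        raise InputError("kinetics fit needs at least 2 timepoints")
    se = df["sd"].to_numpy(float) / np.sqrt(df["n"].to_numpy(float))
    weighted = bool(np.all(se > 0))
    weights = 1.0 / se**2 if weighted else np.ones(len(df))
    note = "" if weighted else "zero/missing SE: unweighted fallback"
    t = df["exposure_days"].to_numpy(float)
    X = t[:, None] if force_zero_intercept else sm.add_constant(t)
    fit = sm.WLS(df["mean"].to_numpy(float), X, weights=weights).fit()
    if force_zero_intercept:
        slope, slope_se = fit.params[0], fit.bse[0]
        intercept, intercept_se = 0.0, 0.0
    else:
        intercept, slope = fit.params
        intercept_se, slope_se = fit.bse
    return KineticsFit(
        slope=float(slope),
        intercept=float(intercept),
        slope_se=float(slope_se),
        intercept_se=float(intercept_se),
        residuals=np.asarray(fit.resid, dtype=float),
        weighted=weighted,
        note=note,
        series=df,
    )


# ---------------------------------------------------------------------------
# coverage


def coverage_rate(
    particles: pd.DataFrame,
    window_area_mm2: float,
    exposure_days: float,
    size_classes: list[str] | None = None,
) -> float:
    """Area-coverage rate in percent of window surface per year.

    (Σ particle areas / window area) × 100 × 365 / exposure_days, over the
    requested classes (all classes when None — the convention used for the
    low-zoom pass, whose coverage is dominated by rare macroscopic debris).
    """
    if exposure_days <= 0:
        raise InputError("exposure_days must be positive")
    if window_area_mm2 <= 0:
        raise ConfigurationError("window_area_mm2 must be positive")
    if len(particles) == 0:
        return 0.0
    if size_classes is not None and "size_class" in particles:
        particles = particles[particles["size_class"].isin(size_classes)]
    total_um2 = float(particles["area_um2"].sum())
    frac = total_um2 / (window_area_mm2 * 1e6)
    return frac * 100.0 * DAYS_PER_YEAR / exposure_days


# ---------------------------------------------------------------------------
# occupancy association


def rate_vs_occupancy(entries) -> pd.DataFrame:
    """Ordered (η, θ) association table with a per-class monotonicity flag.

    ``entries`` is an iterable of dicts/tuples (campaign, size_class,
    occupancy_rate, theta).  No functional form is fitted; the table
    records, per class, whether θ is weakly non-decreasing in η.
    """
    df = pd.DataFrame(
        list(entries), columns=["campaign", "size_class", "occupancy_rate", "theta"]
    )
    if df["campaign"].nunique() < 2:
        raise InputError("need at least 2 campaigns to order θ against η")
    df = df.sort_values(["size_class", "occupancy_rate", "campaign"]).reset_index(drop=True)
    flags = {}
    for cls, grp in df.groupby("size_class"):
        eta = grp["occupancy_rate"].to_numpy()
        theta = grp["theta"].to_numpy()
        ok = True
        for i in range(len(grp)):
            for j in range(len(grp)):
                if eta[i] < eta[j] and theta[i] > theta[j]:
                    ok = False
        flags[cls] = ok
    df["monotone_in_class"] = df["size_class"].map(flags)
    return df
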