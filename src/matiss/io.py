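"""Stack/table IO, run manifests and whole-run orchestration."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .config import CampaignConfig, ClassBounds, SegmentationConfig
from .errors import FormatError, InputError
from .frames import FrameStack
from .pipeline import measure_campaign
from .stats import coverage_rate, density_summary, size_distribution, spatial_profile

__all__ = [
    "write_stack",
    "read_stack",
    "write_table",
    "read_table",
    "run_pipeline",
]


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(".json")


def write_stack(stack: FrameStack, tiff_path: str | Path) -> Path:
    """Write a FrameStack as a multi-page RGB TIFF plus a JSON sidecar."""
    tiff_path = Path(tiff_path)
    tiff_path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(tiff_path, stack.frames, photometric="rgb")
    meta = {k: v for k, v in stack.meta.items() if not isinstance(v, np.ndarray)}
    sidecar = {
        "zoom": stack.zoom,
        "pixel_size_um": stack.pixel_size_um,
        "bit_depth": stack.bit_depth,
        "frame_origins_um": stack.frame_origins.tolist(),
        "meta": meta,
    }
    _sidecar_path(tiff_path).write_text(json.dumps(sidecar, indent=1))
    return tiff_path


def read_stack(tiff_path: str | Path) -> FrameStack:
    """Read a multi-page TIFF + sidecar back into a validated FrameStack."""
    tiff_path = Path(tiff_path)
    if not tiff_path.exists():
        raise FormatError(f"stack not found: {tiff_path}")
    sc_path = _sidecar_path(tiff_path)
    if not sc_path.exists():
        raise FormatError(f"missing frame-origin sidecar: {sc_path}")
    sidecar = json.loads(sc_path.read_text())
    frames = tifffile.imread(tiff_path)
    if frames.ndim == 3:  # single frame
        frames = frames[None]
    if frames.ndim != 4 or frames.shape[-1] != 3:
        raise FormatError(f"{tiff_path}: expected RGB frames, got shape {frames.shape}")
    origins = np.asarray(sidecar["frame_origins_um"], dtype=float)
    if origins.shape[0] != frames.shape[0]:
        raise FormatError(
            f"{tiff_path}: {frames.shape[0]} frames but "
            f"{origins.shape[0]} origins in sidecar"
        )
    return FrameStack(
        frames=frames,
        zoom=sidecar["zoom"],
        pixel_size_um=float(sidecar["pixel_size_um"]),
        frame_origins=origins,
        bit_depth=int(sidecar["bit_depth"]),
        meta=sidecar.get("meta", {}),
    )


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"table not found: {path}")
    return pd.read_csv(path)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    return str(obj)


def run_pipeline(
    config: CampaignConfig,
    out_dir: str | Path,
    zooms: tuple[str, ...] = ("low", "high"),
    n_windows: int | None = None,
    seed: int | None = None,
    seg_cfg: SegmentationConfig | None = None,
    write_stacks: bool = False,
) -> dict:
    """Simulate → segment → calibrate → summarise one campaign, with manifest.

    Writes per-zoom particle tables, per-window density tables, histogram
    and profile tables, and a JSON manifest holding the config snapshot,
    per-stage counts, the seed, and a content hash of every output file.
    Re-running with the same manifest inputs reproduces identical outputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seg_cfg = seg_cfg or SegmentationConfig.from_defaults()
    bounds = ClassBounds()
    outputs: list[Path] = []
    stages: dict = {}
    for zoom in zooms:
        meas = measure_campaign(config, zoom, n_windows=n_windows, seed=seed,
                                seg_cfg=seg_cfg)
        particles = meas.particles
        outputs.append(write_table(particles, out_dir / f"particles_{zoom}.csv"))
        per_window = pd.DataFrame(
            {
                "window_id": [w.window_id for w in meas.windows],
                "window_area_mm2": [w.window_area_mm2 for w in meas.windows],
                "density_fine": [w.density_fine for w in meas.windows],
                "density_coarse": [w.density_coarse for w in meas.windows],
            }
        )
        outputs.append(write_table(per_window, out_dir / f"windows_{zoom}.csv"))
        cls = "coarse" if zoom == "low" else "fine"
        dist = size_distribution(particles, cls)
        hist = pd.DataFrame(
            {
                "bin_lo_um2": dist.bin_edges[:-1],
                "bin_hi_um2": dist.bin_edges[1:],
                "count": dist.counts,
                "cumulative_fraction": dist.cumulative_fraction,
            }
        )
        outputs.append(write_table(hist, out_dir / f"size_distribution_{cls}.csv"))
        prof = spatial_profile(particles, n_bins=8, window_height_um=config.window_um)
        outputs.append(
            write_table(
                pd.DataFrame(
                    {
                        "y_lo_um": prof.y_bin_edges[:-1],
                        "y_hi_um": prof.y_bin_edges[1:],
                        "count": prof.counts,
                    }
                ),
                out_dir / f"spatial_profile_{zoom}.csv",
            )
        )
        mean, sd, n = meas.summary(cls)
        stages[zoom] = {
            "n_windows": n,
            "frames_read": int(sum(l["n_frames"] for l in meas.logs)),
            "frames_rejected": int(sum(l["n_rejected_frames"] for l in meas.logs)),
            "detections": int(sum(l["n_detections"] for l in meas.logs)),
            "particles_per_class": particles["size_class"].value_counts().to_dict(),
            "density_mean": mean,
            "density_sd": sd,
            "coverage_pct_per_year": coverage_rate(
                particles, meas.total_area_mm2, config.exposure_days
            ),
            "asymmetry_index": prof.asymmetry_index,
        }
        if write_stacks:
            for w in range(n):
                from .pipeline import _window_rng
                from .synthetic import simulate_window

                sim = simulate_window(config, zoom, _window_rng(
                    config.seed if seed is None else seed, w, zoom))
                outputs.append(
                    write_stack(sim.stack, out_dir / f"stack_{zoom}_w{w}.tif")
                )
                outputs.append(
                    write_table(sim.truth, out_dir / f"truth_{zoom}_w{w}.csv")
                )

    manifest = {
        "config": json.loads(json.dumps(config.to_dict(), default=_jsonable)),
        "seed": config.seed if seed is None else seed,
        "stages": stages,
        "outputs": {
            str(p.relative_to(out_dir)): _sha256(p) for p in outputs
        },
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, default=_jsonable)
    )
    return manifest
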