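"""Two-zoom, two-pass particle segmentation.

The measurement chain mirrors the flight protocol: segmentation runs on the
blue component of the RGB tiles; the low-zoom pass uses a constant,
empirically set grey threshold (default 75), while the high-zoom pass first
discards frames whose shadows from macroscopic objects would mask small
particles, then thresholds at the stack statistic ``median − k · mean(per-
frame SD)`` (the background median offset by k = 2 standard deviations on
the dark side, matching the dark-particle photometric convention — see the
methods note).  Every first-pass detection is then re-segmented inside a
crop centred on it with a local, crop-statistics threshold, which corrects
areas for local background structure and strips evaporation halos.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import regionprops

from .config import SegmentationConfig
from .errors import AllFramesRejectedError, FormatError, InputError
from .frames import ChannelStack, FrameStack

__all__ = [
    "extract_channel",
    "compute_stack_threshold",
    "reject_shadow_frames",
    "first_pass_segment",
    "refine_particle",
    "run_segmentation",
    "match_detections",
    "RefinedParticle",
    "MatchResult",
]

DETECTION_COLUMNS = [
    "frame",
    "x_um",
    "y_um",
    "first_pass_area_px",
    "area_px",
    "area_um2",
    "elongation",
    "mean_intensity",
    "refined",
]


def _to_working_depth(frames: np.ndarray, bit_depth: int) -> np.ndarray:
    """Rescale to the 8-bit working depth used by the thresholds."""
    if bit_depth == 8:
        return frames
    if bit_depth == 12:
        return (frames >> 4).astype(np.uint8)
    raise FormatError(f"unsupported bit depth {bit_depth}")


def extract_channel(stack: FrameStack, which: str = "blue") -> ChannelStack:
    """Single-channel working stack: ``blue`` or the 8-bit ``gray`` average.

    The blue component feeds both first passes; the grayscale RGB average
    feeds the high-zoom crop refinement.
    """
    if not isinstance(stack, FrameStack):
        raise FormatError("extract_channel expects an RGB FrameStack")
    if which == "blue":
        chan = _to_working_depth(stack.frames[..., 2], stack.bit_depth)
    elif which == "gray":
        gray = stack.frames.astype(np.float32).mean(axis=-1)
        if stack.bit_depth == 12:
            gray /= 16.0
        chan = np.clip(np.round(gray), 0, 255).astype(np.uint8)
    else:
        raise FormatError(f"unknown channel {which!r}")
    return ChannelStack(
        frames=np.ascontiguousarray(chan),
        zoom=stack.zoom,
        pixel_size_um=stack.pixel_size_um,
        frame_origins=stack.frame_origins,
        frame_indices=np.arange(stack.n_frames),
    )


def _frames_array(stack) -> np.ndarray:
    if isinstance(stack, ChannelStack):
        return stack.frames
    arr = np.asarray(stack)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise InputError("expected a (n, rows, cols) single-channel stack")
    return arr


def _frame_sds(frames: np.ndarray) -> np.ndarray:
    """Population SD of each frame, via exact integer sums (fast on uint8)."""
    n_frames = frames.shape[0]
    npx = frames[0].size
    out = np.empty(n_frames)
    for i in range(n_frames):
        x = frames[i].ravel().astype(np.float64)
        s1 = x.sum()
        s2 = float(np.dot(x, x))
        mean = s1 / npx
        out[i] = np.sqrt(max(s2 / npx - mean * mean, 0.0))
    return out


def compute_stack_threshold(stack, k: float) -> float:
    """Stack-statistic grey level: median(all pixels) + k · mean(frame SDs).

    ``k`` is signed; the high-zoom dark-particle pass uses ``k = −high_zoom_k``
    so the threshold sits below the background median.  Per-frame SDs use the
    population convention (ddof = 0).
    """
    frames = _frames_array(stack)
    if frames.shape[0] == 0 or frames.size == 0:
        raise InputError("cannot compute a stack threshold on an empty stack")
    med = float(np.median(frames))
    return med + k * float(_frame_sds(frames).mean())


def reject_shadow_frames(
    stack: ChannelStack, cfg: SegmentationConfig
) -> tuple[ChannelStack, list[int]]:
    """Drop frames whose dark-pixel fraction betrays a macroscopic shadow.

    A provisional background threshold (median of all pixels minus
    ``high_zoom_k`` times the *median* per-frame SD — the median keeps
    contaminated frames from inflating the statistic) flags pixels darker
    than plausible background; frames with more than ``reject_dark_fraction``
    such pixels are removed *before* the stack threshold is computed.
    Because a shadow's penumbra extends past the frames it dominates,
    tile-grid neighbours (within ``reject_dilate_frames`` tiles) of any
    rejected frame are rejected too.  Raises
    :class:`AllFramesRejectedError` rather than returning silently when
    nothing survives.
    """
    frames = stack.frames
    if frames.shape[0] == 0:
        raise InputError("cannot reject frames from an empty stack")
    med = float(np.median(frames))
    sds = _frame_sds(frames)
    provisional = med - cfg.high_zoom_k * float(np.median(sds))
    dark_fraction = (frames < provisional).reshape(frames.shape[0], -1).mean(axis=1)
    reject = dark_fraction > cfg.reject_dark_fraction
    if cfg.reject_dilate_frames > 0 and reject.any() and not reject.all():
        fw = frames.shape[2] * stack.pixel_size_um
        fh = frames.shape[1] * stack.pixel_size_um
        ox, oy = stack.frame_origins[:, 0], stack.frame_origins[:, 1]
        for i in np.flatnonzero(reject.copy()):
            near = (
                (np.abs(ox - ox[i]) <= (cfg.reject_dilate_frames + 0.5) * fw)
                & (np.abs(oy - oy[i]) <= (cfg.reject_dilate_frames + 0.5) * fh)
            )
            reject |= near
    rejected = [int(stack.frame_indices[i]) for i in np.flatnonzero(reject)]
    if reject.all():
        raise AllFramesRejectedError(
            f"all {frames.shape[0]} frames exceeded the dark fraction "
            f"{cfg.reject_dark_fraction}"
        )
    return stack.select(~reject), rejected


_STRUCT8 = np.ones((3, 3), dtype=int)
_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)


def _structure(connectivity: int) -> np.ndarray:
    return _STRUCT8 if connectivity == 8 else _STRUCT4


def first_pass_segment(
    stack: ChannelStack, threshold: float, cfg: SegmentationConfig
) -> pd.DataFrame:
    """Connected components of sub-threshold (dark) pixels, per frame.

    Components smaller than the zoom's ``min_area_px`` floor are dropped
    (the floor sits above the clustering scale of threshold-tail noise
    pixels).  Centroids are mapped to window coordinates through the frame
    origin map.
    """
    px = stack.pixel_size_um
    struct = _structure(cfg.connectivity)
    min_area = cfg.min_area_px(stack.zoom)
    rows = []
    for i in range(stack.n_frames):
        img = stack.frames[i]
        mask = img < threshold
        lab, nlab = ndimage.label(mask, structure=struct)
        if nlab == 0:
            continue
        # component statistics on the (sparse) dark pixels only
        flat_idx = np.flatnonzero(mask.ravel())
        labs = lab.ravel()[flat_idx]
        counts = np.bincount(labs, minlength=nlab + 1)
        counts[0] = 0
        keep = np.flatnonzero(counts >= min_area)
        if keep.size == 0:
            continue
        ncols = img.shape[1]
        rr = flat_idx // ncols
        cc = flat_idx % ncols
        sum_r = np.bincount(labs, weights=rr, minlength=nlab + 1)
        sum_c = np.bincount(labs, weights=cc, minlength=nlab + 1)
        sum_i = np.bincount(labs, weights=img.ravel()[flat_idx].astype(float),
                            minlength=nlab + 1)
        ox, oy = stack.frame_origins[i]
        for label_id in keep:
            cnt = counts[label_id]
            r, c = sum_r[label_id] / cnt, sum_c[label_id] / cnt
            rows.append(
                {
                    "frame": int(stack.frame_indices[i]),
                    "stack_pos": i,
                    "row_px": r,
                    "col_px": c,
                    "x_um": ox + (c + 0.5) * px,
                    "y_um": oy + (r + 0.5) * px,
                    "first_pass_area_px": int(cnt),
                    "mean_intensity": float(sum_i[label_id] / cnt),
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=[
                "frame", "stack_pos", "row_px", "col_px", "x_um", "y_um",
                "first_pass_area_px", "mean_intensity",
            ]
        )
    return pd.DataFrame(rows)


@dataclass
class RefinedParticle:
    area_px: int
    elongation: float
    mean_intensity: float
    centroid_rc: tuple[float, float]  # within the crop
    local_threshold: float
    ok: bool
    mask: np.ndarray


def refine_particle(
    crop: np.ndarray,
    cfg: SegmentationConfig,
    global_threshold: float,
    center_rc: tuple[int, int] | None = None,
    first_mask: np.ndarray | None = None,
) -> RefinedParticle:
    """Re-segment one detection inside its crop with a local threshold.

    The local threshold is ``crop mean − c · crop SD`` (floored at the
    global threshold minus a guard band).  The component containing the
    crop centre is retained; if the centre pixel is background at the local
    threshold, the component best overlapping the first-pass mask is used.
    A detection whose refined component overlaps the first-pass mask by
    less than ``min_refine_overlap`` is flagged (``ok = False``), never
    silently dropped.
    """
    crop = np.asarray(crop, dtype=np.float64)
    if crop.size == 0:
        raise InputError("empty crop")
    if center_rc is None:
        center_rc = (crop.shape[0] // 2, crop.shape[1] // 2)
    local_thr = crop.mean() - cfg.local_threshold_c * crop.std()
    local_thr = max(local_thr, global_threshold - cfg.local_floor_guard)
    mask = crop < local_thr
    lab, nlab = ndimage.label(mask, structure=_structure(cfg.connectivity))
    r0 = int(np.clip(round(center_rc[0]), 0, crop.shape[0] - 1))
    c0 = int(np.clip(round(center_rc[1]), 0, crop.shape[1] - 1))
    target = lab[r0, c0]
    if target == 0 and first_mask is not None and nlab > 0:
        overlaps = ndimage.sum_labels(first_mask, lab, np.arange(1, nlab + 1))
        if overlaps.max() > 0:
            target = int(np.argmax(overlaps)) + 1
    if target == 0:
        return RefinedParticle(
            area_px=0, elongation=np.nan, mean_intensity=np.nan,
            centroid_rc=(np.nan, np.nan), local_threshold=float(local_thr),
            ok=False, mask=np.zeros_like(mask),
        )
    comp = lab == target
    area = int(comp.sum())
    ok = True
    if first_mask is not None:
        inter = np.logical_and(comp, first_mask).sum()
        ok = inter >= cfg.min_refine_overlap * area
    props = regionprops(comp.astype(np.uint8))[0]
    minor = max(props.axis_minor_length, 0.7)  # sub-pixel width floor
    elong = float(props.axis_major_length / minor) if props.axis_major_length > 0 else 1.0
    elong = max(elong, 1.0)
    return RefinedParticle(
        area_px=area,
        elongation=elong,
        mean_intensity=float(crop[comp].mean()),
        centroid_rc=props.centroid,
        local_threshold=float(local_thr),
        ok=ok,
        mask=comp,
    )


def _crop_bounds(center: float, halfwidth: int, size: int) -> tuple[int, int]:
    lo = int(round(center)) - halfwidth
    hi = int(round(center)) + halfwidth + 1
    return max(lo, 0), min(hi, size)


def run_segmentation(
    stack: FrameStack, cfg: SegmentationConfig | None = None
) -> tuple[pd.DataFrame, dict]:
    """Full measurement chain for one window's tile scan.

    Channel extraction → (high zoom) shadow-frame rejection → threshold
    (constant at low zoom, stack statistic at high zoom) → first pass →
    per-detection crop refinement.  Returns the detection table and a log
    of per-stage counts; deterministic for fixed input.
    """
    cfg = cfg or SegmentationConfig.from_defaults()
    blue = extract_channel(stack, "blue")
    rejected: list[int] = []
    if stack.zoom == "high":
        blue, rejected = reject_shadow_frames(blue, cfg)
        threshold = compute_stack_threshold(blue, -cfg.high_zoom_k)
    else:
        threshold = float(cfg.low_zoom_threshold)

    first = first_pass_segment(blue, threshold, cfg)
    px = stack.pixel_size_um
    use_gray = stack.zoom == "high"

    records = []
    n_flagged = 0
    for det in first.itertuples(index=False):
        pos = det.stack_pos
        frame_blue = blue.frames[pos]
        r_eq = np.sqrt(det.first_pass_area_px / np.pi)
        half = int(np.clip(2 * r_eq + cfg.crop_margin_px,
                           cfg.crop_halfwidth_min_px, cfg.crop_halfwidth_max_px))
        r0, r1 = _crop_bounds(det.row_px, half, frame_blue.shape[0])
        c0, c1 = _crop_bounds(det.col_px, half, frame_blue.shape[1])
        if use_gray:
            rgb = stack.frames[det.frame, r0:r1, c0:c1]
            crop = rgb.astype(np.float32).mean(axis=-1)
            if stack.bit_depth == 12:
                crop /= 16.0
        else:
            crop = frame_blue[r0:r1, c0:c1].astype(np.float32)
        first_mask = frame_blue[r0:r1, c0:c1] < threshold
        center = (det.row_px - r0, det.col_px - c0)
        ref = refine_particle(crop, cfg, threshold, center_rc=center,
                              first_mask=first_mask)
        if ref.ok and ref.area_px > 0:
            area_px = ref.area_px
            rr = r0 + ref.centroid_rc[0]
            cc = c0 + ref.centroid_rc[1]
            elong, inten = ref.elongation, ref.mean_intensity
            refined = True
        else:  # flagged: fall back to the first-pass measurement
            n_flagged += 1
            area_px = det.first_pass_area_px
            rr, cc = det.row_px, det.col_px
            elong, inten = np.nan, det.mean_intensity
            refined = False
        ox, oy = blue.frame_origins[pos]
        records.append(
            {
                "frame": det.frame,
                "x_um": ox + (cc + 0.5) * px,
                "y_um": oy + (rr + 0.5) * px,
                "first_pass_area_px": det.first_pass_area_px,
                "area_px": int(area_px),
                "area_um2": area_px * px**2,
                "elongation": elong,
                "mean_intensity": inten,
                "refined": refined,
            }
        )

    detections = pd.DataFrame(records, columns=DETECTION_COLUMNS)
    log = {
        "zoom": stack.zoom,
        "threshold": float(threshold),
        "n_frames": stack.n_frames,
        "n_rejected_frames": len(rejected),
        "rejected_frames": rejected,
        "n_first_pass": int(len(first)),
        "n_detections": int(len(detections)),
        "n_flagged": n_flagged,
        "retained_area_mm2": blue.n_frames * blue.frame_area_mm2,
    }
    return detections, log


@dataclass
class MatchResult:
    precision: float
    recall: float
    n_matched: int
    matches: pd.DataFrame  # truth_id, det_index, distance_um, area_true, area_det


def match_detections(
    truth: pd.DataFrame, detections: pd.DataFrame, radius_um: float
) -> MatchResult:
    """One-to-one greedy nearest-neighbour matching within ``radius_um``.

    Unmatched ground truth counts as a miss, unmatched detections as false
    positives.  Used only for validation against the generator's tables.
    """
    if radius_um <= 0:
        raise InputError("radius_um must be positive")
    nt, nd = len(truth), len(detections)
    cols = ["truth_id", "det_index", "distance_um", "area_true", "area_det"]
    if nt == 0 or nd == 0:
        return MatchResult(
            precision=np.nan if nd == 0 else 0.0,
            recall=np.nan if nt == 0 else 0.0,
            n_matched=0,
            matches=pd.DataFrame(columns=cols),
        )
    from scipy.spatial import cKDTree

    t_xy = truth[["x_um", "y_um"]].to_numpy(float)
    d_xy = detections[["x_um", "y_um"]].to_numpy(float)
    tree = cKDTree(d_xy)
    pairs = []
    for ti, nbrs in enumerate(tree.query_ball_point(t_xy, r=radius_um)):
        for di in nbrs:
            dist = np.hypot(*(t_xy[ti] - d_xy[di]))
            if dist < radius_um:  # matching band is half-open: miss at the radius
                pairs.append((dist, ti, di))
    pairs.sort()
    used_t: set[int] = set()
    used_d: set[int] = set()
    rows = []
    t_ids = truth["id"].to_numpy() if "id" in truth else np.arange(nt)
    for dist, ti, di in pairs:
        if ti in used_t or di in used_d:
            continue
        used_t.add(ti)
        used_d.add(di)
        rows.append(
            {
                "truth_id": t_ids[ti],
                "det_index": detections.index[di],
                "distance_um": dist,
                "area_true": float(truth["area_um2"].iloc[ti]),
                "area_det": float(detections["area_um2"].iloc[di]),
            }
        )
    n_matched = len(rows)
    return MatchResult(
        precision=n_matched / nd,
        recall=n_matched / nt,
        n_matched=n_matched,
        matches=pd.DataFrame(rows, columns=cols),
    )
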