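"""In-memory containers for tile-scan image stacks."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError

__all__ = ["FrameStack", "ChannelStack"]


@dataclass
class FrameStack:
    """An ordered set of RGB frames from one tile-scanned window.

    ``frames`` has shape (n, rows, cols, 3); ``frame_origins`` maps frame
    index -> (x0, y0) µm of the frame's corner pixel in window coordinates
    (y is the flow axis, aperture at y = 0).  ``bit_depth`` is 8 (uint8) or
    12 (uint16 holding 0..4095).
    """

    frames: np.ndarray
    zoom: str
    pixel_size_um: float
    frame_origins: np.ndarray
    bit_depth: int = 8
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        f = np.asarray(self.frames)
        if f.ndim != 4 or f.shape[-1] != 3:
            raise FormatError("frames must have shape (n, rows, cols, 3) RGB")
        if self.bit_depth == 8 and f.dtype != np.uint8:
            raise FormatError("8-bit stacks must be uint8")
        if self.bit_depth == 12 and f.dtype != np.uint16:
            raise FormatError("12-bit stacks must be uint16")
        if self.bit_depth not in (8, 12):
            raise FormatError(f"unsupported bit depth {self.bit_depth}")
        origins = np.asarray(self.frame_origins, dtype=float)
        if origins.shape != (f.shape[0], 2):
            raise FormatError("frame_origins must have shape (n_frames, 2)")
        if self.zoom not in ("low", "high"):
            raise FormatError(f"zoom must be 'low' or 'high', got {self.zoom!r}")
        self.frames = f
        self.frame_origins = origins

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:3]

    @property
    def frame_area_mm2(self) -> float:
        r, c = self.frame_shape
        return r * c * self.pixel_size_um**2 / 1e6


@dataclass
class ChannelStack:
    """A single-channel (8-bit working depth) view of a FrameStack.

    Produced by :func:`matiss.segmentation.extract_channel`; carries the
    geometry needed to map detections back to window coordinates.
    ``frame_indices`` tracks original frame numbers across rejection.
    """

    frames: np.ndarray  # (n, rows, cols) uint8
    zoom: str
    pixel_size_um: float
    frame_origins: np.ndarray
    frame_indices: np.ndarray  # original indices in the parent FrameStack

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise FormatError("channel stack must have shape (n, rows, cols)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_area_mm2(self) -> float:
        r, c = self.frames.shape[1:3]
        return r * c * self.pixel_size_um**2 / 1e6

    def select(self, keep: np.ndarray) -> "ChannelStack":
        keep = np.asarray(keep)
        return ChannelStack(
            frames=self.frames[keep],
            zoom=self.zoom,
            pixel_size_um=self.pixel_size_um,
            frame_origins=self.frame_origins[keep],
            frame_indices=self.frame_indices[keep],
        )
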