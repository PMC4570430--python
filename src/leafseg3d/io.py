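"""RGB-D frame, label-map and overlay I/O.

Conventions (matching the Kinect delivery format):

* color: 8-bit, 3-channel RGB PNG;
* depth: 16-bit single-channel PNG holding millimetres, with the value 0
  reserved for "no measurement" (the sensor dropout convention);
* label maps: 16-bit single-channel PNG, 0 = background, >=1 = segment id.

Pixel coordinates are (i, j) = (column, row), 0-based, origin top-left.
"""
from __future__ import annotations

from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np

from .contour import Contour, rasterize_outline
from .errors import InputError

BOUNDARY_RGB = (255, 255, 0)  # yellow final leaf boundaries
INIT_RGB = (0, 255, 0)        # green initialization circles


@dataclass
class RGBDFrame:
    """An aligned color + depth raster pair.

    Attributes
    ----------
    color : (H, W, 3) uint8
    depth : (H, W) uint16, millimetres; 0 means "not measured"
    valid_mask : (H, W) bool, True exactly where depth > 0
    frame_id : str
    """

    color: np.ndarray
    depth: np.ndarray
    frame_id: str = ""

    def __post_init__(self):
        self.color = np.asarray(self.color)
        self.depth = np.asarray(self.depth)
        if self.color.ndim != 3 or self.color.shape[2] != 3:
            raise InputError("color must be an (H, W, 3) raster")
        if self.depth.shape != self.color.shape[:2]:
            raise InputError(
                f"color {self.color.shape[:2]} and depth {self.depth.shape} "
                "dimensions differ")
        h, w = self.depth.shape
        if h < 8 or w < 8:
            raise InputError("frames must be at least 8x8 pixels")
        if np.any(self.depth < 0):
            raise InputError("depth must be non-negative millimetres")

    @property
    def valid_mask(self) -> np.ndarray:
        return self.depth > 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.depth.shape


@dataclass
class SegmentLabelMap:
    """Per-pixel integer segment labels; 0 = background/unassigned."""

    labels: np.ndarray
    n_segments: int

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.min(initial=0) < 0 or self.labels.max(initial=0) > self.n_segments:
            raise InputError("label values must lie in [0, n_segments]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def segment_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


def read_frame(color_path, depth_path, frame_id: str | None = None) -> RGBDFrame:
    """Read an aligned color/depth PNG pair into an RGBDFrame.

    The valid mask is derived from depth > 0; any dimension mismatch
    between the two rasters is an error.
    """
    try:
        color = iio.imread(color_path)
        depth = iio.imread(depth_path)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read frame: {exc}") from exc
    if color.ndim == 3 and color.shape[2] == 4:
        color = color[:, :, :3]
    if color.ndim != 3 or color.dtype != np.uint8:
        raise InputError(f"{color_path}: expected an 8-bit RGB image")
    if depth.ndim != 2:
        raise InputError(f"{depth_path}: expected a single-channel depth image")
    if depth.shape != color.shape[:2]:
        raise InputError(
            f"dimension mismatch: color {color.shape[:2]} vs depth {depth.shape}")
    if frame_id is None:
        frame_id = str(color_path)
    return RGBDFrame(color=color, depth=depth.astype(np.uint16), frame_id=frame_id)


def write_frame(frame: RGBDFrame, color_path, depth_path) -> None:
    """Write the color raster as 8-bit RGB PNG and depth as 16-bit PNG."""
    iio.imwrite(color_path, frame.color.astype(np.uint8))
    iio.imwrite(depth_path, frame.depth.astype(np.uint16))


def read_label_map(path) -> SegmentLabelMap:
    labels = iio.imread(path)
    if labels.ndim != 2:
        raise InputError(f"{path}: label maps are single-channel")
    labels = labels.astype(np.int32)
    return SegmentLabelMap(labels=labels, n_segments=int(labels.max(initial=0)))


def write_label_map(label_map: SegmentLabelMap, path) -> None:
    if label_map.n_segments > 65535:
        raise InputError("more than 65535 segments cannot be stored as 16-bit PNG")
    iio.imwrite(path, label_map.labels.astype(np.uint16))


def render_overlay(frame: RGBDFrame, contours: list[Contour],
                   init_circles: list[Contour]) -> np.ndarray:
    """Color raster with yellow segment boundaries and green init circles."""
    out = frame.color.copy()
    shape = frame.shape
    for c in contours:
        m = rasterize_outline(c, shape)
        out[m] = BOUNDARY_RGB
    for c in init_circles:
        m = rasterize_outline(c, shape)
        out[m] = INIT_RGB
    return out


def write_overlay(frame: RGBDFrame, contours: list[Contour],
                  init_circles: list[Contour], out_path) -> None:
    """Write the overlay rendering (final boundaries + initializations)."""
    try:
        iio.imwrite(out_path, render_overlay(frame, contours, init_circles))
    except OSError as exc:
        raise IOError(f"cannot write overlay: {exc}") from exc
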