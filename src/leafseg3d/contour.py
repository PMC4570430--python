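"""Closed sub-pixel contours and their rasterization.

Vertices are stored as (x, y) = (column, row) sub-pixel coordinates,
0-based, origin at the top-left pixel centre.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import polygon2mask


@dataclass
class Contour:
    """A closed polyline delimiting one leaf candidate.

    Parameters
    ----------
    vertices : (N, 2) float array
        Ordered (x, y) sub-pixel vertex positions. The polygon is
        implicitly closed (last vertex connects back to the first).
    closed : bool
        Always True for leaf contours; kept explicit for clarity.
    """

    vertices: np.ndarray
    closed: bool = True

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (N, 2) array of (x, y)")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def area(self) -> float:
        """Signed shoelace area (positive for counter-clockwise order)."""
        x = self.vertices[:, 0]
        y = self.vertices[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.vertices, self.vertices[:1]]), axis=0)
        return float(np.sum(np.hypot(d[:, 0], d[:, 1])))

    def resample(self, spacing: float) -> "Contour":
        """Redistribute vertices equally along arc length at ~`spacing` px."""
        pts = np.vstack([self.vertices, self.vertices[:1]])
        seg = np.hypot(*np.diff(pts, axis=0).T)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        total = arc[-1]
        n_new = max(int(round(total / spacing)), 3)
        t = np.linspace(0.0, total, n_new, endpoint=False)
        x = np.interp(t, arc, pts[:, 0])
        y = np.interp(t, arc, pts[:, 1])
        return Contour(np.column_stack([x, y]))

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Rasterize the contour interior to a boolean mask of `shape` (H, W)."""
        # polygon2mask expects (row, col) vertex order
        poly = self.vertices[:, ::-1]
        return polygon2mask(shape, poly)

    def clipped(self, shape: tuple[int, int]) -> "Contour":
        """Clamp vertices into the image bounds (H, W)."""
        h, w = shape
        v = self.vertices.copy()
        v[:, 0] = np.clip(v[:, 0], 0.0, w - 1.0)
        v[:, 1] = np.clip(v[:, 1], 0.0, h - 1.0)
        return Contour(v)


def circle_contour(center_xy: tuple[float, float], radius: float,
                   n_vertices: int = 40) -> Contour:
    """A circle as a closed contour with equally spaced vertices."""
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    cx, cy = center_xy
    verts = np.column_stack([cx + radius * np.cos(theta),
                             cy + radius * np.sin(theta)])
    return Contour(verts)


def rasterize_outline(contour: Contour, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of the contour's boundary pixels (Bresenham polyline)."""
    from skimage.draw import line

    h, w = shape
    out = np.zeros(shape, dtype=bool)
    pts = np.vstack([contour.vertices, contour.vertices[:1]])
    pts_rc = np.rint(pts[:, ::-1]).astype(int)
    pts_rc[:, 0] = np.clip(pts_rc[:, 0], 0, h - 1)
    pts_rc[:, 1] = np.clip(pts_rc[:, 1], 0, w - 1)
    for a, b in zip(pts_rc[:-1], pts_rc[1:]):
        rr, cc = line(a[0], a[1], b[0], b[1])
        out[rr, cc] = True
    return out
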