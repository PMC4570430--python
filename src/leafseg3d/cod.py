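"""Centers of divergence (CoD) of a GVF field and circular initialization.

A CoD is a pixel from which the vector field points outward along both
axes — a field source. In a leaf's GVF the interior field points outward
toward the rim, so each (visible part of a) leaf contains a small cluster
of CoDs near its centre; one active contour is seeded per retained CoD.

Scatter-point detection compares each pixel with its forward neighbours:
p(i, j) with (i, j) = (column, row) is a candidate along x when
x(i, j) <= x(i+1, j) and |sign(x(i, j)) + sign(x(i+1, j))| <= 1, i.e. the
x-component crosses (or touches) zero from non-positive to non-negative;
the y test is analogous with p(i, j+1). Candidates satisfying both tests
form the scatter set, which is then thinned so that no two retained
centers lie within a distance threshold of each other.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .config import CoDParams
from .contour import Contour, circle_contour
from .errors import InputError
from .gvf import VectorField

logger = logging.getLogger(__name__)


def sign3(x: float) -> int:
    """Three-valued sign: 1 for positive, 0 for zero, -1 for negative."""
    if x > 0:
        return 1
    if x < 0:
        return -1
    return 0


@dataclass
class CoDSet:
    """Detected divergence centers, with provenance sets for inspection.

    points : list of (i, j) = (column, row) integer pixel coordinates.
    psx/psy : the per-axis candidate sets before intersection (unpruned
        sets only; pruned sets keep the raw set they came from).
    """

    points: list[tuple[int, int]]
    psx: list[tuple[int, int]] = field(default_factory=list)
    psy: list[tuple[int, int]] = field(default_factory=list)

    def __len__(self):
        return len(self.points)


def scatter_points(fld: VectorField, mask: np.ndarray,
                   min_field_mag: float = 1e-6) -> CoDSet:
    """All divergence-center candidates of the field inside `mask`.

    The last column and row carry no forward neighbour and are excluded;
    pixels where the field magnitude at the pixel and both forward
    neighbours is below min_field_mag are ignored (exactly-zero background
    would otherwise satisfy the <= tests everywhere).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != fld.shape:
        raise InputError("field and mask dimensions differ")
    u, v = fld.u, fld.v
    h, w = fld.shape
    if h < 2 or w < 2:
        return CoDSet(points=[])

    su = np.sign(u)
    sv = np.sign(v)
    # forward-difference tests on the interior (i < W-1, j < H-1)
    ux0 = u[:, :-1]
    ux1 = u[:, 1:]
    condx = (ux0 <= ux1) & (np.abs(su[:, :-1] + su[:, 1:]) <= 1)
    vy0 = v[:-1, :]
    vy1 = v[1:, :]
    condy = (vy0 <= vy1) & (np.abs(sv[:-1, :] + sv[1:, :]) <= 1)

    mag = fld.magnitude()
    sig = ((mag >= min_field_mag)
           | np.pad(mag[:, 1:] >= min_field_mag, ((0, 0), (0, 1)))
           | np.pad(mag[1:, :] >= min_field_mag, ((0, 1), (0, 0))))

    full_x = np.zeros((h, w), dtype=bool)
    full_x[:, :-1] = condx
    full_y = np.zeros((h, w), dtype=bool)
    full_y[:-1, :] = condy
    interior = np.zeros((h, w), dtype=bool)
    interior[:-1, :-1] = True

    psx_m = full_x & mask & sig & interior
    psy_m = full_y & mask & sig & interior
    ps_m = psx_m & psy_m

    def to_points(m):
        rr, cc = np.nonzero(m)
        return [(int(c), int(r)) for r, c in zip(rr, cc)]

    return CoDSet(points=to_points(ps_m), psx=to_points(psx_m),
                  psy=to_points(psy_m))


def prune_cods(raw: CoDSet, dist_threshold: float,
               mode: str = "merge") -> CoDSet:
    """Thin the scatter set so retained centers are mutually separated.

    mode 'merge' (default): points are greedily clustered in raster-scan
    order — a point joins the first cluster whose seed lies within
    dist_threshold, otherwise it seeds a new cluster — and each cluster is
    replaced by its centroid rounded half-even per coordinate.

    mode 'literal': the inverse rule (one of any pair *farther* apart than
    the threshold is removed); kept only for comparison, it discards
    well-separated centers.
    """
    pts = sorted(raw.points, key=lambda p: (p[1], p[0]))  # raster order
    if not pts:
        return CoDSet(points=[], psx=raw.psx, psy=raw.psy)
    if mode == "literal":
        retained: list[tuple[int, int]] = []
        for p in pts:
            if all(math.dist(p, q) <= dist_threshold for q in retained):
                retained.append(p)
        return CoDSet(points=retained, psx=raw.psx, psy=raw.psy)
    if mode != "merge":
        raise InputError(f"unknown prune mode {mode!r}")
    seeds: list[tuple[int, int]] = []
    members: list[list[tuple[int, int]]] = []
    for p in pts:
        for s, mem in zip(seeds, members):
            if math.dist(p, s) <= dist_threshold:
                mem.append(p)
                break
        else:
            seeds.append(p)
            members.append([p])
    points = []
    for mem in members:
        arr = np.asarray(mem, dtype=float)
        ci, cj = np.round(arr.mean(axis=0))  # numpy rounds half-even
        points.append((int(ci), int(cj)))
    return CoDSet(points=points, psx=raw.psx, psy=raw.psy)


def init_contours(cods: CoDSet, init_radius: float, n_vertices: int = 40,
                  shape: tuple[int, int] | None = None) -> list[Contour]:
    """One circular contour of radius init_radius per CoD, in CoD order.

    When `shape` is given, circles reaching outside the image are clamped
    to the bounds (with a warning) so every vertex is a valid position.
    """
    out = []
    for (ci, cj) in cods.points:
        c = circle_contour((ci, cj), init_radius, n_vertices)
        if shape is not None:
            h, w = shape
            if (ci - init_radius < 0 or cj - init_radius < 0
                    or ci + init_radius > w - 1 or cj + init_radius > h - 1):
                logger.warning("init circle at (%d, %d) clipped to image "
                               "bounds", ci, cj)
            c = c.clipped(shape)
        out.append(c)
    return out


def detect_cods(fld: VectorField, mask: np.ndarray,
                params: CoDParams) -> CoDSet:
    """scatter_points followed by pruning, using one parameter block."""
    raw = scatter_points(fld, mask, params.min_field_mag)
    return prune_cods(raw, params.dist_threshold, mode=params.prune_mode)
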