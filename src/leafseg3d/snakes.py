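"""GVF snakes: contour evolution, instance rasterization, full pipeline.

Each initial circle evolves under the classic snake update
    x_{t+1} = (A + gamma I)^{-1} (gamma x_t + F_ext(x_t))
where A is the circulant pentadiagonal operator built from the elasticity
(alpha) and rigidity (beta) weights — implicit in the internal forces,
explicit in the external ones — and F_ext is kappa times the GVF sampled
bilinearly at the vertices (optionally normalized to unit direction, plus
an optional outward balloon term). Vertices are redistributed to a fixed
arc-length spacing every few iterations so the discretization stays
uniform while the contour inflates from a 5 px seed circle to a leaf rim.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .background import remove_background
from .cod import CoDSet, detect_cods, init_contours
from .config import PipelineConfig, SnakeParams
from .contour import Contour
from .errors import InputError
from .gvf import VectorField, compute_gvf, depth_edge_map
from .io import RGBDFrame

logger = logging.getLogger(__name__)

_RESAMPLE_EVERY = 10
_MIN_VERTICES = 8


@dataclass
class LeafSegment:
    """One segmented leaf instance."""

    contour: Contour
    mask: np.ndarray
    seed_cod: tuple[int, int]
    area_px: int


def _internal_inverse(n: int, params: SnakeParams) -> np.ndarray:
    """(A + gamma I)^{-1} for a closed snake with n vertices."""
    a, b, g = params.alpha, params.beta, params.gamma
    row = np.zeros(n)
    row[0] = 2 * a + 6 * b + g
    row[1] = -a - 4 * b
    row[2 % n] += b
    row[-1] += -a - 4 * b
    row[-2 % n] += b
    A = np.empty((n, n))
    for i in range(n):
        A[i] = np.roll(row, i)
    return np.linalg.inv(A)


def _sample_field(field: VectorField, verts: np.ndarray) -> np.ndarray:
    coords = [verts[:, 1], verts[:, 0]]  # (row, col)
    fu = ndimage.map_coordinates(field.u, coords, order=1, mode="nearest")
    fv = ndimage.map_coordinates(field.v, coords, order=1, mode="nearest")
    return np.column_stack([fu, fv])


def _outward_normals(verts: np.ndarray) -> np.ndarray:
    """Unit normals pointing away from the contour centroid."""
    t = np.roll(verts, -1, axis=0) - np.roll(verts, 1, axis=0)
    n = np.column_stack([t[:, 1], -t[:, 0]])
    norms = np.hypot(n[:, 0], n[:, 1])
    norms[norms == 0] = 1.0
    n /= norms[:, None]
    out = verts - verts.mean(axis=0)
    flip = np.sum(n * out, axis=1) < 0
    n[flip] *= -1.0
    return n


def evolve_snake(init: Contour, field: VectorField,
                 params: SnakeParams) -> Contour:
    """Evolve a closed contour under the GVF external force.

    Stops after n_iter iterations or when the mean vertex displacement in
    one step falls below converge_eps. The returned contour may have
    collapsed below 8 vertices; callers discard such degenerate results.
    """
    bad = params.validate()
    if bad:
        raise InputError(f"invalid snake parameters: {bad}")
    h, w = field.shape
    contour = init.resample(params.resample_spacing)
    verts = contour.vertices
    norm_reg = 0.15 * float(np.max(field.magnitude())) + 1e-12
    inv_cache: dict[int, np.ndarray] = {}
    for it in range(params.n_iter):
        n = len(verts)
        if n < _MIN_VERTICES:
            break
        if n not in inv_cache:
            inv_cache[n] = _internal_inverse(n, params)
        fext = _sample_field(field, verts)
        if params.normalize_field:
            # smooth normalization: near-unit direction away from edges,
            # tapering to zero at the (field-reversal) boundary so the
            # contour settles on the ridge instead of oscillating across it
            mag = np.hypot(fext[:, 0], fext[:, 1])
            fext = fext / (mag + norm_reg)[:, None]
        force = params.kappa * fext
        if params.balloon:
            force = force + params.balloon * _outward_normals(verts)
        new = inv_cache[n] @ (params.gamma * verts + force)
        new[:, 0] = np.clip(new[:, 0], 0.0, w - 1.0)
        new[:, 1] = np.clip(new[:, 1], 0.0, h - 1.0)
        disp = float(np.mean(np.hypot(*(new - verts).T)))
        verts = new
        if disp < params.converge_eps:
            break
        if (it + 1) % _RESAMPLE_EVERY == 0:
            verts = Contour(verts).resample(params.resample_spacing).vertices
    final = Contour(verts).resample(params.resample_spacing)
    if final.n_vertices < _MIN_VERTICES:
        logger.warning("snake collapsed to %d vertices", final.n_vertices)
    return final


def contours_to_segments(contours: list[Contour], fg_mask: np.ndarray,
                         cods: CoDSet) -> list[LeafSegment]:
    """Rasterize evolved contours into disjoint instance masks.

    Each contour interior is intersected with the foreground mask; pixels
    claimed by several contours go to the contour whose seed CoD is
    nearest (ties to the lower contour index). Empty segments are dropped.
    """
    if len(contours) != len(cods.points):
        raise InputError("need exactly one seed CoD per contour")
    fg_mask = np.asarray(fg_mask, dtype=bool)
    h, w = fg_mask.shape
    yy, xx = np.mgrid[0:h, 0:w]
    best = np.full((h, w), np.inf)
    owner = np.full((h, w), -1, dtype=np.int32)
    for k, (contour, (si, sj)) in enumerate(zip(contours, cods.points)):
        if contour.n_vertices < _MIN_VERTICES:
            continue
        m = contour.to_mask((h, w)) & fg_mask
        if not np.any(m):
            continue
        d = (xx - si) ** 2 + (yy - sj) ** 2
        take = m & (d < best)
        owner[take] = k
        best[take] = d[take]
    out = []
    for k, (contour, seed) in enumerate(zip(contours, cods.points)):
        mask = owner == k
        area = int(np.count_nonzero(mask))
        if area == 0:
            continue
        out.append(LeafSegment(contour=contour, mask=mask,
                               seed_cod=tuple(seed), area_px=area))
    return out


def segment_leaves(frame: RGBDFrame, config: PipelineConfig,
                   return_debug: bool = False):
    """Full pipeline: background removal -> GVF -> CoD -> snakes -> masks.

    Returns the list of LeafSegments (empty when no vegetation survives
    background removal). Deterministic for fixed input and config.
    """
    fg_frame, fg_labels = remove_background(frame, config.mean_shift,
                                            config.vegetation)
    debug = {"fg_frame": fg_frame, "fg_labels": fg_labels,
             "edge": None, "field": None, "cods": None, "init": []}
    if fg_labels.n_segments == 0:
        logger.info("segment_leaves: empty foreground, nothing to segment")
        return ([], debug) if return_debug else []
    fg_valid = fg_labels.labels > 0
    region = ndimage.binary_fill_holes(fg_valid)
    edge = depth_edge_map(fg_frame.depth.astype(np.float64),
                          config.gvf.presmooth_sd,
                          grad_clip=config.gvf.grad_clip,
                          fg_mask=fg_valid)
    field = compute_gvf(edge, config.gvf)
    cods = detect_cods(field, region, config.cod)
    circles = init_contours(cods, config.cod.init_radius,
                            config.cod.n_vertices, shape=frame.shape)
    logger.info("segment_leaves: %d foreground segments, %d CoDs",
                fg_labels.n_segments, len(cods))
    evolved, kept_points = [], []
    for circle, point in zip(circles, cods.points):
        snake = evolve_snake(circle, field, config.snake)
        if snake.n_vertices < _MIN_VERTICES:
            logger.warning("discarding degenerate contour seeded at %s", point)
            continue
        evolved.append(snake)
        kept_points.append(point)
    segments = contours_to_segments(
        evolved, fg_valid, CoDSet(points=kept_points))
    debug.update(edge=edge, field=field, cods=cods, init=circles)
    return (segments, debug) if return_debug else segments
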