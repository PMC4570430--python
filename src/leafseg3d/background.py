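"""Depth-domain mean shift segmentation and vegetation color filtering.

The depth raster is clustered with a spatial/range windowed mean shift:
every pixel iterates a depth mode estimate y, repeatedly replaced by the
mean depth of the pixels inside its (2*sp+1)^2 spatial window whose depth
lies within the range radius sr of the current y (a flat kernel in the
joint domain). Pixels whose converged modes agree to within sr and that
are spatially 4-connected form one segment. Segments are then kept or
discarded by a green-vegetation color rule, which removes soil, pots and
other non-green background left at leaf-like depths.

The implementation vectorizes the per-pixel iteration with cumulative
windowed depth histograms (the window contents are fixed, only y moves),
processing the image in row strips to bound memory; a literal per-pixel
loop over the same recurrence is used as the independent oracle in tests.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .config import MeanShiftParams, VegetationParams
from .errors import EmptyInputError, InputError
from .io import RGBDFrame, SegmentLabelMap

logger = logging.getLogger(__name__)

# row-strip height cap keeps the per-strip histogram tables ~< 1 GiB
_STRIP_BUDGET = 120_000_000


@dataclass
class ModeTrace:
    """Converged per-pixel modes and iteration diagnostics (internal)."""

    modes: np.ndarray        # (H, W) float, normalized depth units; NaN invalid
    iterations: np.ndarray   # (H, W) int
    max_iter_fraction: float


def normalize_depth(depth: np.ndarray, valid: np.ndarray,
                    depth_norm: str) -> np.ndarray:
    """Map valid depths to the integer clustering domain.

    scale_8bit min-max rescales valid depths onto 0..255 (so sr keeps its
    gray-level meaning); raw_mm shifts to a 0-based integer mm scale.
    Invalid pixels get -1 and take no part in clustering.
    """
    out = np.full(depth.shape, -1, dtype=np.int64)
    if not np.any(valid):
        return out
    d = depth[valid].astype(np.float64)
    if depth_norm == "scale_8bit":
        lo, hi = d.min(), d.max()
        if hi > lo:
            out[valid] = np.rint((d - lo) * (255.0 / (hi - lo))).astype(np.int64)
        else:
            out[valid] = 0
    elif depth_norm == "raw_mm":
        out[valid] = depth[valid].astype(np.int64) - int(d.min())
    else:
        raise InputError(f"unknown depth_norm {depth_norm!r}")
    return out


def _box_sum(arr: np.ndarray, sp: int) -> np.ndarray:
    """Exact clipped box sum over a (2sp+1)^2 window via integral images."""
    h, w = arr.shape
    ii = np.zeros((h + 1, w + 1), dtype=arr.dtype)
    np.cumsum(arr, axis=0, out=ii[1:, 1:])
    np.cumsum(ii[1:, 1:], axis=1, out=ii[1:, 1:])
    r0 = np.clip(np.arange(h) - sp, 0, h)
    r1 = np.clip(np.arange(h) + sp + 1, 0, h)
    c0 = np.clip(np.arange(w) - sp, 0, w)
    c1 = np.clip(np.arange(w) + sp + 1, 0, w)
    return (ii[np.ix_(r1, c1)] - ii[np.ix_(r0, c1)]
            - ii[np.ix_(r1, c0)] + ii[np.ix_(r0, c0)])


def _iterate_strip(norm, valid, params, r0, r1):
    """Run the mode iteration for rows [r0, r1) using a haloed strip."""
    h, w = norm.shape
    sp, sr = params.sp, params.sr
    h0 = max(r0 - sp, 0)
    h1 = min(r1 + sp, h)
    snorm = norm[h0:h1]
    svalid = valid[h0:h1]
    n_bins = int(snorm.max()) + 1 if np.any(svalid) else 1

    # cumulative-over-bins windowed count and depth-sum tables
    cc = np.empty((n_bins, h1 - h0, w), dtype=np.int64)
    cs = np.empty((n_bins, h1 - h0, w), dtype=np.int64)
    for b in range(n_bins):
        ind = (snorm == b) & svalid
        cc[b] = _box_sum(ind.astype(np.int64), sp)
        cs[b] = cc[b] * b
    np.cumsum(cc, axis=0, out=cc)
    np.cumsum(cs, axis=0, out=cs)

    rows = slice(r0 - h0, r1 - h0)
    act_r, act_c = np.nonzero(svalid[rows])
    act_r = act_r + (r0 - h0)
    y = snorm[act_r, act_c].astype(np.float64)
    iters = np.zeros(y.shape, dtype=np.int32)
    alive = np.ones(y.shape, dtype=bool)
    for _ in range(params.max_iter):
        idx = np.nonzero(alive)[0]
        if idx.size == 0:
            break
        yi = y[idx]
        lo = np.clip(np.ceil(yi - sr).astype(np.int64), 0, n_bins - 1)
        hi = np.clip(np.floor(yi + sr).astype(np.int64), 0, n_bins - 1)
        r = act_r[idx]
        c = act_c[idx]
        cnt = cc[hi, r, c]
        ssum = cs[hi, r, c]
        has_lo = lo > 0
        cnt = cnt - np.where(has_lo, cc[np.maximum(lo - 1, 0), r, c], 0)
        ssum = ssum - np.where(has_lo, cs[np.maximum(lo - 1, 0), r, c], 0)
        ynew = np.where(cnt > 0, ssum / np.maximum(cnt, 1), yi)
        shift = np.abs(ynew - yi)
        y[idx] = ynew
        iters[idx] += 1
        alive[idx] = shift > params.eps
    modes = np.full((r1 - r0, w), np.nan)
    its = np.zeros((r1 - r0, w), dtype=np.int32)
    modes[act_r - (r0 - h0), act_c] = y
    its[act_r - (r0 - h0), act_c] = iters
    return modes, its, np.count_nonzero(alive)


def _seek_modes(norm, valid, params: MeanShiftParams) -> ModeTrace:
    h, w = norm.shape
    n_bins = int(norm.max()) + 1
    strip = max(int(_STRIP_BUDGET // (2 * 8 * max(n_bins, 1) * w)), 2 * params.sp + 1)
    modes = np.full((h, w), np.nan)
    iters = np.zeros((h, w), dtype=np.int32)
    n_unconverged = 0
    for r0 in range(0, h, strip):
        r1 = min(r0 + strip, h)
        m, it, nu = _iterate_strip(norm, valid, params, r0, r1)
        modes[r0:r1] = m
        iters[r0:r1] = it
        n_unconverged += nu
    n_valid = int(np.count_nonzero(valid))
    frac = n_unconverged / n_valid if n_valid else 0.0
    if frac > 0:
        logger.info("mean shift: %.2f%% of pixels hit max_iter", 100 * frac)
    return ModeTrace(modes=modes, iterations=iters, max_iter_fraction=frac)


def _group_modes(modes, valid, sr, min_region_px):
    """4-connected grouping of pixels whose converged modes differ <= sr,
    then merging of small segments into their depth-nearest neighbour."""
    h, w = modes.shape
    idx = np.arange(h * w).reshape(h, w)
    rows, cols, = [], []
    # right neighbours
    ok = valid[:, :-1] & valid[:, 1:] & (
        np.abs(modes[:, :-1] - modes[:, 1:]) <= sr)
    rows.append(idx[:, :-1][ok]); cols.append(idx[:, 1:][ok])
    # down neighbours
    ok = valid[:-1, :] & valid[1:, :] & (
        np.abs(modes[:-1, :] - modes[1:, :]) <= sr)
    rows.append(idx[:-1, :][ok]); cols.append(idx[1:, :][ok])
    r = np.concatenate(rows); c = np.concatenate(cols)
    graph = coo_matrix((np.ones(len(r), dtype=np.int8), (r, c)),
                       shape=(h * w, h * w))
    _, comp = connected_components(graph, directed=False)
    comp = comp.reshape(h, w)
    comp[~valid] = -1

    labels = _relabel_raster_order(comp)
    labels = _merge_small(labels, modes, min_region_px)
    return labels


def _relabel_raster_order(comp):
    """Re-index segments 1..k by first raster-scan occurrence; -1 -> 0."""
    flat = comp.ravel()
    labels = np.zeros(flat.shape, dtype=np.int32)
    seen = flat >= 0
    pos = np.nonzero(seen)[0]
    if pos.size == 0:
        return labels.reshape(comp.shape)
    vals = flat[pos]
    uvals, uidx = np.unique(vals, return_index=True)
    order = uvals[np.argsort(pos[uidx])]  # ids by first raster occurrence
    lut = np.zeros(int(flat.max()) + 1, dtype=np.int32)
    lut[order] = np.arange(1, len(order) + 1)
    labels[seen] = lut[vals]
    return labels.reshape(comp.shape)


def _merge_small(labels, modes, min_region_px):
    """Merge segments below min_region_px into the adjacent segment whose
    mean mode depth is nearest; isolated small segments are kept."""
    if min_region_px <= 0:
        return labels
    labels = labels.copy()
    while True:
        ids, counts = np.unique(labels[labels > 0], return_counts=True)
        if ids.size == 0:
            break
        mean_depth = ndimage.mean(np.nan_to_num(modes), labels=labels, index=ids)
        small = ids[counts < min_region_px]
        if small.size == 0:
            break
        merged_any = False
        id_to_depth = dict(zip(ids.tolist(), np.atleast_1d(mean_depth).tolist()))
        # ascending size so speckles vanish before they attract anything
        small = small[np.argsort(counts[np.isin(ids, small)])]
        for s in small:
            m = labels == s
            ring = ndimage.binary_dilation(m) & ~m
            neigh = np.unique(labels[ring])
            neigh = neigh[neigh > 0]
            if neigh.size == 0:
                continue
            target = neigh[np.argmin([abs(id_to_depth[int(n)] - id_to_depth[int(s)])
                                      for n in neigh])]
            labels[m] = target
            merged_any = True
        if not merged_any:
            break
    return _relabel_raster_order(np.where(labels > 0, labels, -1))


def mean_shift_depth(frame: RGBDFrame, params: MeanShiftParams,
                     return_trace: bool = False):
    """Segment the depth image by windowed spatial/range mean shift.

    Every valid pixel is assigned a segment id >= 1; invalid (zero-depth)
    pixels get 0. Segments smaller than min_region_px are merged into the
    depth-nearest adjacent segment.
    """
    bad = params.validate()
    if bad:
        raise InputError(f"invalid mean shift parameters: {bad}")
    valid = frame.valid_mask
    if not np.any(valid):
        raise EmptyInputError("no valid depth pixels to cluster")
    norm = normalize_depth(frame.depth, valid, params.depth_norm)
    trace = _seek_modes(norm, valid, params)
    labels = _group_modes(trace.modes, valid, params.sr, params.min_region_px)
    lm = SegmentLabelMap(labels=labels, n_segments=int(labels.max(initial=0)))
    if return_trace:
        return lm, trace
    return lm


def vegetation_filter(labels: SegmentLabelMap, frame: RGBDFrame,
                      params: VegetationParams) -> SegmentLabelMap:
    """Keep only segments whose mean color passes the vegetation test."""
    if labels.shape != frame.shape:
        raise InputError("label map and frame dimensions differ")
    bad = params.validate()
    if bad:
        raise InputError(f"invalid vegetation parameters: {bad}")
    lab = labels.labels
    ids = labels.segment_ids()
    if ids.size == 0:
        return SegmentLabelMap(labels=np.zeros_like(lab), n_segments=0)
    color = frame.color.astype(np.float64)
    means = np.stack([
        ndimage.mean(color[:, :, ch], labels=lab, index=ids)
        for ch in range(3)], axis=1)  # (k, 3) mean R, G, B
    r, g, b = means[:, 0], means[:, 1], means[:, 2]
    if params.mode == "rgb_threshold":
        keep = (g >= params.g_min) & (g >= np.maximum(r, b) + params.g_margin)
    else:  # excess_green
        keep = (2.0 * g - r - b) >= params.exg_min
    kept_ids = ids[keep]
    lut = np.zeros(int(lab.max()) + 1, dtype=np.int32)
    for new, old in enumerate(kept_ids, start=1):
        lut[old] = new
    out = lut[lab]
    return SegmentLabelMap(labels=out, n_segments=int(len(kept_ids)))


def remove_background(frame: RGBDFrame, ms: MeanShiftParams,
                      veg: VegetationParams):
    """Mean shift + vegetation filtering; zero the frame outside foreground.

    Returns (foreground frame, foreground label map). The returned frame
    has depth and color set to 0 outside the surviving segments, so its
    valid mask *is* the foreground mask.
    """
    seg = mean_shift_depth(frame, ms)
    fg = vegetation_filter(seg, frame, veg)
    keep = fg.labels > 0
    color = np.where(keep[:, :, None], frame.color, 0).astype(np.uint8)
    depth = np.where(keep, frame.depth, 0).astype(np.uint16)
    out = RGBDFrame(color=color, depth=depth, frame_id=frame.frame_id)
    if fg.n_segments == 0:
        logger.info("remove_background: no vegetation segments survive")
    return out, fg
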