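"""Seeded synthetic RGB-D greenhouse scenes with per-leaf ground truth.

The generator stands in for the RGB-D camera: leaf-shaped foreground
regions (superellipses with random eccentricity, rotation and a small
radial boundary perturbation) sit on gently tilted depth planes well in
front of a background plane, a configurable fraction of leaves is placed
in occluding groups (the occluding leaf nearer the camera, silhouette
overlap 20-60%), and the depth raster gets i.i.d. Gaussian noise plus
dropout (depth = 0) near depth discontinuities, mimicking structured-light
edge artefacts. Colors are green hues on leaves and a brown/gray floor.

Everything is deterministic for a fixed seed.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import GenerationError, ConfigError
from .io import RGBDFrame

# placement retry budget per leaf before giving up
_MAX_TRIES = 400
# depth step (mm) treated as a discontinuity when carving dropout bands
_EDGE_STEP_MM = 15.0


@dataclass
class SceneParams:
    """Knobs of the synthetic greenhouse scene.

    Depths are millimetres from the camera; the camera-to-plant working
    distance of the emulated rig is ~1 m, hence the default leaf depth
    band of 700-1000 mm with the floor/background at 1600 mm.
    """

    height: int = 480
    width: int = 640
    n_leaves: int = 8
    occluded_fraction: float = 0.75
    leaf_depth_mm: tuple[float, float] = (700.0, 1000.0)
    background_depth_mm: float = 1600.0
    inter_leaf_offset_mm: float = 30.0
    leaf_scale_px: tuple[float, float] = (40.0, 90.0)
    depth_noise_sd_mm: float = 3.0
    dropout_rate_edge: float = 0.3
    seed: int = 0

    def validate(self):
        near, far = self.leaf_depth_mm
        if self.n_leaves < 1:
            raise ConfigError("n_leaves must be >= 1")
        if not 0.0 <= self.occluded_fraction <= 1.0:
            raise ConfigError("occluded_fraction must be in [0, 1]")
        if not (0 < near < far < self.background_depth_mm):
            raise ConfigError("need 0 < near < far < background depth")
        if self.background_depth_mm - far < 10.0 * self.depth_noise_sd_mm:
            raise ConfigError(
                "background must sit >= 10 noise sd behind the farthest leaf")
        if self.inter_leaf_offset_mm < 0:
            raise ConfigError("inter_leaf_offset_mm must be >= 0")
        if not 0.0 <= self.dropout_rate_edge <= 1.0:
            raise ConfigError("dropout_rate_edge must be in [0, 1]")
        if self.height < 8 or self.width < 8:
            raise ConfigError("scene must be at least 8x8")
        return self


@dataclass
class GroundTruth:
    """Per-leaf truth for one generated scene.

    instance_masks are the *visible* (post z-buffer, valid-depth) pixels of
    each leaf; silhouettes are the full pre-occlusion shapes, from which
    the occluded flags and occlusion partners are derived.
    """

    instance_masks: list[np.ndarray]
    occluded_flags: list[bool]
    visible_area_px: list[int]
    silhouettes: list[np.ndarray] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(self.instance_masks)

    def partners_of(self, k: int) -> list[int]:
        """Indices of leaves whose silhouettes intersect leaf k's."""
        sk = self.silhouettes[k]
        return [j for j in range(self.n_leaves)
                if j != k and np.any(sk & self.silhouettes[j])]


def _superellipse_mask(shape, center, a, b, exponent, theta,
                       perturb_amp, perturb_k, perturb_phase):
    """Rasterize a perturbed superellipse: |x'/(a s)|^m + |y'/(b s)|^m <= 1
    with the radial modulation s(phi) = 1 + amp * sin(k phi + phase)."""
    h, w = shape
    cx, cy = center
    r = int(np.ceil(max(a, b) * (1.0 + perturb_amp))) + 2
    x0, x1 = max(int(cx) - r, 0), min(int(cx) + r + 1, w)
    y0, y1 = max(int(cy) - r, 0), min(int(cy) + r + 1, h)
    if x0 >= x1 or y0 >= y1:
        return np.zeros(shape, dtype=bool)
    xs = np.arange(x0, x1) - cx
    ys = np.arange(y0, y1) - cy
    X, Y = np.meshgrid(xs, ys)
    ct, st = np.cos(theta), np.sin(theta)
    Xr = ct * X + st * Y
    Yr = -st * X + ct * Y
    phi = np.arctan2(Yr, Xr)
    s = 1.0 + perturb_amp * np.sin(perturb_k * phi + perturb_phase)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (np.abs(Xr / (a * s)) ** exponent
               + np.abs(Yr / (b * s)) ** exponent)
    mask = np.zeros(shape, dtype=bool)
    mask[y0:y1, x0:x1] = rho <= 1.0
    return mask


def _overlap_fraction(m1, m2):
    inter = np.count_nonzero(m1 & m2)
    denom = min(np.count_nonzero(m1), np.count_nonzero(m2))
    return inter / denom if denom else 0.0


class _LeafSpec:
    """One placed leaf before compositing."""

    __slots__ = ("mask", "center", "base_depth", "gx", "gy", "color", "group")

    def __init__(self, mask, center, base_depth, gx, gy, color, group):
        self.mask = mask
        self.center = center
        self.base_depth = base_depth
        self.gx = gx
        self.gy = gy
        self.color = color
        self.group = group


def _occlusion_group_sizes(n_leaves: int, occluded_fraction: float) -> list[int]:
    """Sizes of the occluding groups. k = round(n * fraction) leaves are
    occluded, built from pairs; an odd remainder extends one pair to a
    chain of three; k == 1 is promoted to a minimal pair."""
    k = int(round(n_leaves * occluded_fraction))
    if k == 1 and n_leaves >= 2:
        k = 2
    k = min(k, n_leaves)
    groups = []
    while k >= 2:
        if k == 3:
            groups.append(3)
            k = 0
        else:
            groups.append(2)
            k -= 2
    return groups


def _sample_leaf_geometry(rng, params):
    lo, hi = params.leaf_scale_px
    a = rng.uniform(lo, hi) / 2.0
    b = a * rng.uniform(0.55, 0.9)
    exponent = rng.uniform(1.7, 3.0)
    theta = rng.uniform(0.0, np.pi)
    amp = rng.uniform(0.0, 0.08)
    k = rng.integers(3, 7)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    return a, b, exponent, theta, amp, k, phase


def _leaf_color(rng):
    g = int(rng.integers(130, 201))
    r = int(rng.integers(30, 81))
    b = int(rng.integers(30, 86))
    return np.array([r, g, b], dtype=np.float64)


def generate_scene(params: SceneParams) -> tuple[RGBDFrame, GroundTruth]:
    """Generate one seeded scene and its per-leaf ground truth."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width
    shape = (h, w)
    near, far = params.leaf_depth_mm
    offset = params.inter_leaf_offset_mm

    group_sizes = _occlusion_group_sizes(params.n_leaves, params.occluded_fraction)
    n_grouped = sum(group_sizes)
    n_single = params.n_leaves - n_grouped

    # depth margin so the tilted plane never leaves [near, far]
    tilt_max = 0.15  # mm per px
    margin = tilt_max * (params.leaf_scale_px[1] * 0.75 + 2)

    leaves: list[_LeafSpec] = []
    occupied = np.zeros(shape, dtype=bool)

    def place_single(group_id, min_base=None):
        lo = near + margin if min_base is None else min_base
        if lo >= far - margin:
            raise GenerationError("leaf depth band too narrow for the "
                                  "requested occlusion chain")
        for _ in range(_MAX_TRIES):
            a, b, exponent, theta, amp, k, phase = _sample_leaf_geometry(rng, params)
            ext = max(a, b) * 1.1
            cx = rng.uniform(ext, w - 1 - ext)
            cy = rng.uniform(ext, h - 1 - ext)
            mask = _superellipse_mask(shape, (cx, cy), a, b, exponent, theta,
                                      amp, k, phase)
            if np.any(mask & occupied):
                continue
            base = rng.uniform(lo, far - margin)
            gx = rng.uniform(-tilt_max, tilt_max)
            gy = rng.uniform(-tilt_max, tilt_max)
            leaf = _LeafSpec(mask, (cx, cy), base, gx, gy, _leaf_color(rng), group_id)
            return leaf
        raise GenerationError("could not place a leaf without forbidden overlap")

    def place_partner(prev: _LeafSpec, group_id, depth_above):
        """Place a leaf overlapping `prev` by 20-60% of the smaller
        silhouette, nearer the camera by `depth_above` mm."""
        others = occupied & ~prev.mask
        pa = np.count_nonzero(prev.mask)
        for _ in range(_MAX_TRIES):
            a, b, exponent, theta, amp, k, phase = _sample_leaf_geometry(rng, params)
            ext = max(a, b)
            dist = rng.uniform(0.5, 1.1) * ext
            ang = rng.uniform(0.0, 2.0 * np.pi)
            cx = prev.center[0] + dist * np.cos(ang)
            cy = prev.center[1] + dist * np.sin(ang)
            if not (ext <= cx <= w - 1 - ext and ext <= cy <= h - 1 - ext):
                continue
            mask = _superellipse_mask(shape, (cx, cy), a, b, exponent, theta,
                                      amp, k, phase)
            if np.any(mask & others):
                continue
            frac = _overlap_fraction(mask, prev.mask)
            if not 0.2 <= frac <= 0.6:
                continue
            base = prev.base_depth - depth_above
            if base < near + margin:
                continue
            leaf = _LeafSpec(mask, (cx, cy), base, prev.gx, prev.gy,
                             _leaf_color(rng), group_id)
            return leaf
        raise GenerationError("could not place an occluding partner leaf")

    group_id = 0
    for size in group_sizes:
        # the bottom leaf of a chain must leave depth room for the leaves above
        chain_room = 1.3 * offset * (size - 1)
        bottom = place_single(group_id, min_base=near + margin + chain_room)
        occupied |= bottom.mask
        leaves.append(bottom)
        prev = bottom
        for _ in range(size - 1):
            step = offset * rng.uniform(1.0, 1.3) if offset > 0 else 0.0
            nxt = place_partner(prev, group_id, step)
            occupied |= nxt.mask
            leaves.append(nxt)
            prev = nxt
        group_id += 1

    for _ in range(n_single):
        leaf = place_single(group_id)
        occupied |= leaf.mask
        leaves.append(leaf)
        group_id += 1

    # ---- composite: z-buffer over the background plane ----
    depth = np.full(shape, params.background_depth_mm, dtype=np.float64)
    owner = np.full(shape, -1, dtype=np.int32)
    yy, xx = np.mgrid[0:h, 0:w]
    for idx, leaf in enumerate(leaves):
        plane = (leaf.base_depth
                 + leaf.gx * (xx - leaf.center[0])
                 + leaf.gy * (yy - leaf.center[1]))
        sel = leaf.mask & (plane < depth)
        depth[sel] = plane[sel]
        owner[sel] = idx

    # ---- color ----
    bg_color = np.array([115.0, 95.0, 70.0])
    color = (bg_color[None, None, :]
             + rng.normal(0.0, 8.0, size=(h, w, 3)))
    shade = np.clip(rng.normal(1.0, 0.05, size=shape), 0.85, 1.15)
    for idx, leaf in enumerate(leaves):
        sel = owner == idx
        color[sel] = leaf.color[None, :] * shade[sel][:, None]
    color = np.clip(np.rint(color), 0, 255).astype(np.uint8)

    # ---- depth noise + edge dropout ----
    clean = depth.copy()
    if params.depth_noise_sd_mm > 0:
        depth = depth + rng.normal(0.0, params.depth_noise_sd_mm, size=shape)
    if params.dropout_rate_edge > 0:
        step = np.zeros(shape, dtype=bool)
        step[:, :-1] |= np.abs(np.diff(clean, axis=1)) > _EDGE_STEP_MM
        step[:, 1:] |= np.abs(np.diff(clean, axis=1)) > _EDGE_STEP_MM
        step[:-1, :] |= np.abs(np.diff(clean, axis=0)) > _EDGE_STEP_MM
        step[1:, :] |= np.abs(np.diff(clean, axis=0)) > _EDGE_STEP_MM
        band = ndimage.binary_dilation(step, structure=np.ones((5, 5), bool))
        drop = band & (rng.random(shape) < params.dropout_rate_edge)
        depth[drop] = 0.0
    depth = np.clip(np.rint(depth), 1, 65535).astype(np.uint16)
    if params.dropout_rate_edge > 0:
        depth[drop] = 0  # dropout survives the >=1 clamp; noise never creates zeros

    frame = RGBDFrame(color=color, depth=depth,
                      frame_id=f"scene-{params.seed:08d}")

    valid = depth > 0
    masks = [(owner == idx) & valid for idx in range(len(leaves))]
    sils = [leaf.mask for leaf in leaves]
    flags = []
    for idx in range(len(leaves)):
        inter = any(np.any(sils[idx] & sils[j])
                    for j in range(len(leaves)) if j != idx)
        flags.append(bool(inter))
    gt = GroundTruth(
        instance_masks=masks,
        occluded_flags=flags,
        visible_area_px=[int(np.count_nonzero(m)) for m in masks],
        silhouettes=sils,
    )
    return frame, gt


def scene_batch(params: SceneParams, n_scenes: int,
                base_seed: int) -> list[tuple[RGBDFrame, GroundTruth]]:
    """Generate n_scenes scenes with seeds base_seed, base_seed+1, ..."""
    if n_scenes < 1:
        raise ConfigError("n_scenes must be >= 1")
    out = []
    for k in range(n_scenes):
        p = dataclasses.replace(params, seed=base_seed + k)
        try:
            out.append(generate_scene(p))
        except GenerationError as exc:
            raise GenerationError(f"scene {k} (seed {base_seed + k}): {exc}") from exc
    return out
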