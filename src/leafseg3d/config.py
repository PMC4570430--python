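"""Pipeline configuration: parameter blocks for every stage, YAML round-trip.

Defaults follow the method's conventional operating point (mean-shift
spatial radius sp = 12 px, range radius sr = 6 gray levels); everything
else (GVF weights, snake weights, CoD thresholds, vegetation color
thresholds) is exposed here as ordinary configuration.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .errors import ConfigError

_DEPTH_NORMS = ("raw_mm", "scale_8bit")
_VEG_MODES = ("rgb_threshold", "excess_green")
_PRUNE_MODES = ("merge", "literal")


@dataclass
class MeanShiftParams:
    """Spatial/range windowed mean shift on the depth image.

    sp : spatial window radius in pixels.
    sr : range window radius in depth units *after* normalization
         (gray levels for scale_8bit, millimetres for raw_mm).
    depth_norm : 'scale_8bit' min-max rescales valid depths to 0..255 so sr
         keeps its gray-level meaning; 'raw_mm' clusters metric depth.
    min_region_px : segments smaller than this are merged into the
         depth-nearest neighbouring segment (speckle absorption).
    """

    sp: int = 12
    sr: float = 6.0
    max_iter: int = 50
    eps: float = 1e-3
    min_region_px: int = 50
    depth_norm: str = "scale_8bit"

    def validate(self):
        bad = []
        if self.sp < 1:
            bad.append("mean_shift.sp (radius must be positive)")
        if self.sr <= 0:
            bad.append("mean_shift.sr (radius must be positive)")
        if self.max_iter < 1:
            bad.append("mean_shift.max_iter")
        if self.eps <= 0:
            bad.append("mean_shift.eps")
        if self.min_region_px < 0:
            bad.append("mean_shift.min_region_px")
        if self.depth_norm not in _DEPTH_NORMS:
            bad.append(f"mean_shift.depth_norm (one of {_DEPTH_NORMS})")
        return bad


@dataclass
class VegetationParams:
    """Color rule deciding which depth segments are green vegetation.

    rgb_threshold mode keeps a segment when its mean G >= g_min and mean G
    exceeds max(mean R, mean B) by g_margin; excess_green uses the
    ExG index mean(2G - R - B) >= exg_min.
    """

    mode: str = "rgb_threshold"
    g_min: int = 100
    g_margin: int = 20
    exg_min: int = 40

    def validate(self):
        bad = []
        if self.mode not in _VEG_MODES:
            bad.append(f"vegetation.mode (one of {_VEG_MODES})")
        if not 0 <= self.g_min <= 255:
            bad.append("vegetation.g_min")
        if not 0 <= self.g_margin <= 255:
            bad.append("vegetation.g_margin")
        if not -510 <= self.exg_min <= 510:
            bad.append("vegetation.exg_min")
        return bad


@dataclass
class GVFParams:
    """Gradient vector flow diffusion of the depth edge map.

    The explicit scheme is stable for dt <= 1 / (4 mu); for edge maps in
    [0, 1] it is additionally a strict energy descent for
    dt <= 1 / (4 mu + 1/2), which the default dt = 0.75 satisfies at
    mu = 0.2. grad_clip (mm/px)
    saturates the depth-gradient magnitude before normalization so that the
    small inter-leaf depth step is as visible in the edge map as the large
    leaf/background step.
    """

    mu: float = 0.2
    n_iter: int = 320
    dt: float = 0.75
    presmooth_sd: float = 1.5
    grad_clip: float = 6.0

    def validate(self):
        bad = []
        if self.mu < 0:
            bad.append("gvf.mu")
        if self.n_iter < 0:
            bad.append("gvf.n_iter")
        if self.dt <= 0:
            bad.append("gvf.dt")
        if self.mu > 0 and self.dt > 1.0 / (4.0 * self.mu) + 1e-12:
            bad.append("gvf.dt (explicit scheme requires dt <= 1/(4*mu))")
        if self.presmooth_sd < 0:
            bad.append("gvf.presmooth_sd")
        if self.grad_clip <= 0:
            bad.append("gvf.grad_clip")
        return bad


@dataclass
class CoDParams:
    """Center-of-divergence detection and pruning.

    dist_threshold : two retained centers are never closer than this (px).
    init_radius : radius of the initial circular contours (px).
    min_field_mag : field magnitudes below this are treated as "no field"
        when scanning for divergence centers.
    prune_mode : 'merge' (proximity merging, the default) or 'literal'
        (remove one of any pair *farther* apart than the threshold; the
        inverse rule, kept for comparison).
    """

    dist_threshold: float = 15.0
    init_radius: float = 5.0
    min_field_mag: float = 1e-6
    n_vertices: int = 40
    prune_mode: str = "merge"

    def validate(self):
        bad = []
        if self.dist_threshold <= 0:
            bad.append("cod.dist_threshold")
        if self.init_radius < 2:
            bad.append("cod.init_radius")
        if self.min_field_mag < 0:
            bad.append("cod.min_field_mag")
        if self.n_vertices < 8:
            bad.append("cod.n_vertices")
        if self.prune_mode not in _PRUNE_MODES:
            bad.append(f"cod.prune_mode (one of {_PRUNE_MODES})")
        return bad


@dataclass
class SnakeParams:
    """Active contour (snake) evolution under the GVF external force.

    alpha/beta weight elasticity and rigidity in the internal (pentadiagonal)
    operator, gamma is the viscosity step, kappa scales the external force.
    normalize_field replaces the external force by its unit direction above
    a small magnitude floor, which keeps the inflation speed roughly
    constant deep inside large leaves where the diffused field is weak.
    """

    alpha: float = 0.1
    beta: float = 0.1
    gamma: float = 1.0
    kappa: float = 2.0
    n_iter: int = 600
    resample_spacing: float = 2.0
    converge_eps: float = 0.05
    balloon: float = 0.5
    normalize_field: bool = True

    def validate(self):
        bad = []
        if self.alpha < 0 or self.beta < 0:
            bad.append("snake.alpha/beta")
        if self.gamma <= 0:
            bad.append("snake.gamma")
        if self.n_iter < 1:
            bad.append("snake.n_iter")
        if self.resample_spacing <= 0:
            bad.append("snake.resample_spacing")
        if self.converge_eps <= 0:
            bad.append("snake.converge_eps")
        return bad


@dataclass
class EvalParams:
    """Matching thresholds for the four-way outcome classification."""

    iou_correct: float = 0.5
    cover_min: float = 0.2
    min_gt_area_px: int = 100

    def validate(self):
        bad = []
        if not 0 < self.iou_correct <= 1:
            bad.append("eval.iou_correct")
        if not 0 <= self.cover_min <= 1:
            bad.append("eval.cover_min")
        if self.min_gt_area_px < 0:
            bad.append("eval.min_gt_area_px")
        return bad


_SECTIONS = {
    "mean_shift": MeanShiftParams,
    "vegetation": VegetationParams,
    "gvf": GVFParams,
    "cod": CoDParams,
    "snake": SnakeParams,
    "eval": EvalParams,
}


@dataclass
class PipelineConfig:
    """All stage parameters; serializes to/from a YAML mapping."""

    mean_shift: MeanShiftParams = field(default_factory=MeanShiftParams)
    vegetation: VegetationParams = field(default_factory=VegetationParams)
    gvf: GVFParams = field(default_factory=GVFParams)
    cod: CoDParams = field(default_factory=CoDParams)
    snake: SnakeParams = field(default_factory=SnakeParams)
    eval: EvalParams = field(default_factory=EvalParams)

    def validate(self):
        bad = []
        for name in _SECTIONS:
            bad.extend(getattr(self, name).validate())
        if bad:
            raise ConfigError(f"invalid configuration values: {bad}", keys=bad)
        return self

    def to_dict(self) -> dict:
        return {name: dataclasses.asdict(getattr(self, name))
                for name in _SECTIONS}

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = data or {}
        if not isinstance(data, dict):
            raise ConfigError("config root must be a mapping", keys=["<root>"])
        unknown = [k for k in data if k not in _SECTIONS]
        if unknown:
            raise ConfigError(f"unknown config sections: {unknown}", keys=unknown)
        kwargs = {}
        bad_keys = []
        for name, klass in _SECTIONS.items():
            section = data.get(name, {}) or {}
            if not isinstance(section, dict):
                bad_keys.append(name)
                continue
            known = {f.name for f in dataclasses.fields(klass)}
            extra = [f"{name}.{k}" for k in section if k not in known]
            bad_keys.extend(extra)
            kwargs[name] = klass(**{k: v for k, v in section.items() if k in known})
        if bad_keys:
            raise ConfigError(f"unknown config keys: {bad_keys}", keys=bad_keys)
        return cls(**kwargs).validate()


def load_config(path) -> PipelineConfig:
    """Load a YAML config file; missing keys fall back to defaults."""
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config file {path}: {exc}",
                          keys=["<parse>"]) from exc
    return PipelineConfig.from_dict(data or {})


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
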