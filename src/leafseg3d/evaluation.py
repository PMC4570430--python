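"""Outcome classification and segmentation-rate reporting.

Every ground-truth leaf is assigned exactly one of four outcomes:

* correct — a predicted segment matches it well (IoU above threshold);
* failure — no predicted segment covers a meaningful part of it;
* unseparated — its best-matching prediction also swallows a substantial
  part of an occluding partner leaf (the occlusion was not split);
* oversegmented — it is covered only by several partial segments.

Counts are stratified into single vs. occluded leaves and reported as
percentages of the stratum total, rounded half-up to two decimals.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

from .config import EvalParams
from .errors import InputError
from .synthetic import GroundTruth

OUTCOMES = ("correct", "failure", "unseparated", "oversegmented")


def rate_pct(numerator: int, denominator: int) -> float:
    """100 * numerator / denominator, rounded half-up to 2 decimals."""
    if denominator <= 0:
        raise InputError("rate_pct: denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise InputError("rate_pct: numerator must be in [0, denominator]")
    q = Decimal(100 * numerator) / Decimal(denominator)
    return float(q.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class StratumStats:
    """Counts and percentage rates for one stratum of leaves."""

    n_total: int = 0
    n_correct: int = 0
    n_failure: int = 0
    n_unseparated: int = 0
    n_oversegmented: int = 0

    def add(self, outcome: str):
        self.n_total += 1
        setattr(self, f"n_{outcome}", getattr(self, f"n_{outcome}") + 1)

    def rate(self, outcome: str) -> float:
        if self.n_total == 0:
            return 0.0
        return rate_pct(getattr(self, f"n_{outcome}"), self.n_total)

    def to_dict(self) -> dict:
        d = {"n_total": self.n_total}
        for o in OUTCOMES:
            d[f"n_{o}"] = getattr(self, f"n_{o}")
            d[f"{o}_rate_pct"] = self.rate(o)
        return d


@dataclass
class EvalReport:
    """Per-stratum outcome counts and rates, plus per-scene rates."""

    single: StratumStats = field(default_factory=StratumStats)
    occluded: StratumStats = field(default_factory=StratumStats)
    overall: StratumStats = field(default_factory=StratumStats)
    per_scene: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "single": self.single.to_dict(),
            "occluded": self.occluded.to_dict(),
            "overall": self.overall.to_dict(),
            "per_scene": [
                {"scene": s, "n_leaves": n, "segmentation_rate_pct": r}
                for (s, n, r) in self.per_scene],
        }


def _cover(pred_mask: np.ndarray, gt_mask: np.ndarray, gt_area: int) -> float:
    return np.count_nonzero(pred_mask & gt_mask) / gt_area if gt_area else 0.0


def _iou(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.count_nonzero(a & b)
    union = np.count_nonzero(a | b)
    return inter / union if union else 0.0


def classify_leaf(gt_mask: np.ndarray, predictions: list,
                  gt_partner_masks: list, params: EvalParams) -> str:
    """Classify one ground-truth leaf against the predicted segments.

    Decision order: failure (nothing covers it) -> unseparated (its best
    match also covers an occluding partner) -> correct (IoU above
    threshold) -> oversegmented (several partial covers) -> failure.
    """
    gt_mask = np.asarray(gt_mask, dtype=bool)
    gt_area = int(np.count_nonzero(gt_mask))
    pred_masks = [np.asarray(p.mask if hasattr(p, "mask") else p, dtype=bool)
                  for p in predictions]
    covers = [_cover(pm, gt_mask, gt_area) for pm in pred_masks]
    candidates = [k for k, c in enumerate(covers) if c >= params.cover_min]
    if not candidates:
        return "failure"
    ious = {k: _iou(pred_masks[k], gt_mask) for k in candidates}
    best = max(candidates, key=lambda k: (ious[k], -k))
    for partner in gt_partner_masks:
        partner = np.asarray(partner, dtype=bool)
        p_area = int(np.count_nonzero(partner))
        if p_area and _cover(pred_masks[best], partner, p_area) >= params.cover_min:
            return "unseparated"
    if ious[best] >= params.iou_correct:
        return "correct"
    if len(candidates) >= 2:
        return "oversegmented"
    return "failure"


def evaluate_batch(scenes: list[tuple[list, GroundTruth]],
                   params: EvalParams | None = None) -> EvalReport:
    """Classify every ground-truth leaf of every scene and build the report.

    `scenes` pairs the predicted LeafSegments of each scene with its
    GroundTruth. Leaves smaller than min_gt_area_px visible pixels are
    ignored (emulating the exclusion of tiny leaves the sensor cannot
    resolve). Occlusion partners are derived from silhouette overlaps.
    """
    if params is None:
        params = EvalParams()
    bad = params.validate()
    if bad:
        raise InputError(f"invalid evaluation parameters: {bad}")
    if not scenes:
        raise InputError("evaluate_batch needs at least one scene")
    report = EvalReport()
    for s_idx, (predictions, gt) in enumerate(scenes):
        n_scene = 0
        n_scene_correct = 0
        for k in range(gt.n_leaves):
            if gt.visible_area_px[k] < params.min_gt_area_px:
                continue
            partners = [gt.instance_masks[j] for j in gt.partners_of(k)]
            outcome = classify_leaf(gt.instance_masks[k], predictions,
                                    partners, params)
            stratum = report.occluded if gt.occluded_flags[k] else report.single
            stratum.add(outcome)
            report.overall.add(outcome)
            n_scene += 1
            n_scene_correct += outcome == "correct"
        rate = rate_pct(n_scene_correct, n_scene) if n_scene else 0.0
        report.per_scene.append((s_idx, n_scene, rate))
    return report
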