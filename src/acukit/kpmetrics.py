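"""Acupoint-accuracy metrics: per-image pixel error (APE), its physical
conversion (APDE), sample-level means (mAPE / mAPDE), effective-region hit
classification and recall.

A predicted acupoint counts as an effective recognition (TP) when its
10 mm effective circular region overlaps the ground-truth region — two
equal circles overlap iff their centers are closer than one diameter.
Recall is the mean of per-image recalls, not a pooled count ratio.

The per-image pixel error optionally subtracts a tolerance before
averaging; default 0 (plain mean pixel error).  The pixel-to-millimeter
scale ``scale_k`` defaults to 1.3 mm/px.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .types import Keypoint, KeypointSet

__all__ = [
    "EvalConfig",
    "HitReport",
    "ape_image",
    "apde",
    "summarize",
    "classify_hits",
    "recall",
]


@dataclass(frozen=True)
class EvalConfig:
    """Evaluation constants.

    ``scale_k``: millimeters per pixel at the working distance;
    ``tolerance_px``: per-pair slack subtracted from each pixel distance
    before averaging (0 disables it); ``region_diameter_mm``: diameter of
    the effective acupoint region.
    """

    scale_k: float = 1.3
    tolerance_px: float = 0.0
    region_diameter_mm: float = 10.0

    def __post_init__(self) -> None:
        if self.scale_k <= 0:
            raise ValueError("scale_k must be positive")
        if self.tolerance_px < 0:
            raise ValueError("tolerance_px must be >= 0")
        if self.region_diameter_mm <= 0:
            raise ValueError("region_diameter_mm must be positive")


@dataclass
class HitReport:
    """Per-label hit/miss classification for one image."""

    distances_mm: Dict[str, float] = field(default_factory=dict)
    verdicts: Dict[str, str] = field(default_factory=dict)  # "TP" | "FN"
    errors_mm: Dict[str, float] = field(default_factory=dict)  # FN only

    @property
    def tp(self) -> int:
        return sum(1 for v in self.verdicts.values() if v == "TP")

    @property
    def fn(self) -> int:
        return sum(1 for v in self.verdicts.values() if v == "FN")


def _matched_pairs(pred: KeypointSet, truth: KeypointSet
                   ) -> List[Tuple[str, Keypoint, Keypoint]]:
    """Labels visible in both sets, matched by label (labels are authoritative)."""
    out = []
    for label, g in truth.items():
        if not g.visible or label not in pred:
            continue
        p = pred[label]
        if p.visible:
            out.append((label, p, g))
    return out


def ape_image(pred: KeypointSet, truth: KeypointSet,
              cfg: EvalConfig = EvalConfig()) -> float:
    """Average pixel error over label-matched visible pairs in one image.

    Each pair contributes ``max(||P - G|| - tolerance_px, 0)``.
    """
    pairs = _matched_pairs(pred, truth)
    if not pairs:
        raise ValueError("no matched visible keypoint pairs")
    errs = [max(np.hypot(p.x - g.x, p.y - g.y) - cfg.tolerance_px, 0.0)
            for _, p, g in pairs]
    return float(np.mean(errs))


def apde(ape_px: float, cfg: EvalConfig = EvalConfig()) -> float:
    """Convert a pixel error to millimeters via the scale factor."""
    if ape_px < 0:
        raise ValueError("ape_px must be >= 0")
    return float(ape_px * cfg.scale_k)


def summarize(per_image_ape: Sequence[float],
              cfg: EvalConfig = EvalConfig()) -> Tuple[float, float, float]:
    """(mAPE px, mAPDE mm, sample variance px^2) over per-image errors."""
    vals = np.asarray(list(per_image_ape), float)
    if vals.size == 0:
        raise ValueError("empty per-image APE list")
    m_ape = float(vals.mean())
    m_apde = apde(m_ape, cfg)
    var = float(vals.var(ddof=1)) if vals.size > 1 else 0.0
    return m_ape, m_apde, var


def classify_hits(pred: KeypointSet, truth: KeypointSet,
                  cfg: EvalConfig = EvalConfig()) -> HitReport:
    """TP/FN verdict per ground-truth label.

    TP iff the center distance in millimeters is strictly below the region
    diameter (equal 10 mm circles overlap iff centers are < 10 mm apart);
    a missing or invisible prediction is FN.
    """
    report = HitReport()
    for label, g in truth.items():
        if not g.visible:
            continue
        p = pred[label] if label in pred else None
        if p is None or not p.visible:
            report.verdicts[label] = "FN"
            continue
        dist_mm = float(np.hypot(p.x - g.x, p.y - g.y) * cfg.scale_k)
        report.distances_mm[label] = dist_mm
        if dist_mm < cfg.region_diameter_mm:
            report.verdicts[label] = "TP"
        else:
            report.verdicts[label] = "FN"
            report.errors_mm[label] = dist_mm
    return report


def recall(reports: Sequence[HitReport]) -> float:
    """Mean of per-image recalls, in percent."""
    if not reports:
        raise ValueError("no reports")
    vals = []
    for rep in reports:
        n = rep.tp + rep.fn
        if n == 0:
            raise ValueError("report with zero keypoints")
        vals.append(rep.tp / n)
    return float(np.mean(vals) * 100.0)
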