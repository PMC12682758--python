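"""Restoration-quality and processing-efficiency metrics.

PSNR is offered in two forms: the three-channel *sum* of per-channel log
terms (``channel_sum``, roughly three times a conventional PSNR) and its
third (``channel_mean``, the conventional per-channel-average PSNR, the
reporting default).  SSIM is the global (single-window) structural
similarity with the usual stabilizers c1 = (k1 L)^2, c2 = (k2 L)^2,
k1 = 0.01, k2 = 0.03.

Processing efficiency is tracked per image: the per-acupoint processing
time (seconds per marker) and the relative speed-up of one algorithm over
another in percent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "PSNR_INF",
    "QualityReport",
    "EfficiencyRecord",
    "psnr3",
    "ssim_global",
    "per_marker_time",
    "efficiency_gain",
]

#: Sentinel for a zero-MSE (identical) comparison.
PSNR_INF = float("inf")


@dataclass(frozen=True)
class QualityReport:
    psnr: float
    ssim: float
    psnr_per_channel: Tuple[float, float, float]
    ssim_per_channel: Tuple[float, float, float]
    region: str = "whole-image"


@dataclass
class EfficiencyRecord:
    """Per-image processing times (seconds) and marker counts."""

    times: List[float]
    marker_counts: List[int]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.marker_counts):
            raise ValueError("times and marker_counts must have equal length")
        if any(t <= 0 for t in self.times):
            raise ValueError("times must be positive")
        if any(c < 1 for c in self.marker_counts):
            raise ValueError("marker counts must be >= 1")


def _check_pair(a: np.ndarray, b: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.ndim != 3 or a.shape[2] != 3:
        raise ValueError("expected H x W x 3 images")
    return a, b


def psnr3(a: np.ndarray, b: np.ndarray, mask: Optional[np.ndarray] = None,
          variant: str = "channel_mean", peak: float = 255.0) -> float:
    """Three-channel peak signal-to-noise ratio in decibels.

    ``channel_sum`` adds the three per-channel terms
    ``10 log10(peak^2 / MSE_c)``; ``channel_mean`` divides that sum by 3
    (the conventional PSNR).  A zero MSE in any channel yields the +inf
    sentinel.  With ``mask``, statistics are restricted to the region.
    """
    if variant not in ("channel_sum", "channel_mean"):
        raise ValueError("variant must be 'channel_sum' or 'channel_mean'")
    a, b = _check_pair(a, b)
    sel = slice(None) if mask is None else np.asarray(mask, bool)
    total = 0.0
    for c in range(3):
        diff = a[:, :, c][sel] - b[:, :, c][sel]
        mse = float(np.mean(diff ** 2))
        if mse == 0.0:
            return PSNR_INF
        total += 10.0 * np.log10(peak ** 2 / mse)
    return total if variant == "channel_sum" else total / 3.0


def _ssim_channel(x: np.ndarray, y: np.ndarray, L: float,
                  k1: float, k2: float) -> float:
    c1 = (k1 * L) ** 2
    c2 = (k2 * L) ** 2
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cov = np.mean((x - mx) * (y - my))
    return float(((2 * mx * my + c1) * (2 * cov + c2))
                 / ((mx ** 2 + my ** 2 + c1) * (vx + vy + c2)))


def ssim_global(a: np.ndarray, b: np.ndarray, mask: Optional[np.ndarray] = None,
                L: float = 255.0, k1: float = 0.01, k2: float = 0.03) -> float:
    """Global (single-window) SSIM, channels averaged."""
    a, b = _check_pair(a, b)
    sel = slice(None) if mask is None else np.asarray(mask, bool)
    vals = [_ssim_channel(a[:, :, c][sel].ravel(), b[:, :, c][sel].ravel(),
                          L, k1, k2) for c in range(3)]
    return float(np.mean(vals))


def quality_report(a: np.ndarray, b: np.ndarray,
                   mask: Optional[np.ndarray] = None) -> QualityReport:
    """Channel-mean PSNR and global SSIM plus per-channel terms."""
    a_, b_ = _check_pair(a, b)
    sel = slice(None) if mask is None else np.asarray(mask, bool)
    psnr_c = []
    for c in range(3):
        diff = a_[:, :, c][sel] - b_[:, :, c][sel]
        mse = float(np.mean(diff ** 2))
        psnr_c.append(PSNR_INF if mse == 0 else 10 * np.log10(255.0 ** 2 / mse))
    ssim_c = tuple(_ssim_channel(a_[:, :, c][sel].ravel(), b_[:, :, c][sel].ravel(),
                                 255.0, 0.01, 0.03) for c in range(3))
    return QualityReport(
        psnr=psnr3(a, b, mask=mask, variant="channel_mean"),
        ssim=float(np.mean(ssim_c)),
        psnr_per_channel=tuple(psnr_c),
        ssim_per_channel=ssim_c,
        region="whole-image" if mask is None else "masked",
    )


def per_marker_time(records: EfficiencyRecord, convention: str = "per_marker") -> float:
    """Average processing time in seconds.

    ``per_image`` is the plain mean of the per-image times; ``per_marker``
    (default) averages each image's time divided by its marker count,
    honouring the seconds-per-acupoint unit.
    """
    if convention not in ("per_image", "per_marker"):
        raise ValueError("convention must be 'per_image' or 'per_marker'")
    if not records.times:
        raise ValueError("no records")
    times = np.asarray(records.times, float)
    if convention == "per_image":
        return float(times.mean())
    counts = np.asarray(records.marker_counts, float)
    return float(np.mean(times / counts))


def efficiency_gain(baseline_times: Sequence[float],
                    improved_times: Sequence[float],
                    convention: str = "mean_of_ratios") -> float:
    """Relative speed-up of the improved algorithm, in percent.

    ``mean_of_ratios`` averages the per-image improvements
    ``(1 - T_improved / T_baseline) * 100`` over matched pairs;
    ``ratio_of_means`` compares the two mean times directly.
    """
    if convention not in ("mean_of_ratios", "ratio_of_means"):
        raise ValueError("convention must be 'mean_of_ratios' or 'ratio_of_means'")
    tc = np.asarray(list(baseline_times), float)
    tp = np.asarray(list(improved_times), float)
    if tc.shape != tp.shape or tc.size == 0:
        raise ValueError("time lists must be non-empty and matched")
    if np.any(tc == 0):
        raise ValueError("baseline times must be non-zero")
    if convention == "mean_of_ratios":
        return float(np.mean(1.0 - tp / tc) * 100.0)
    return float((1.0 - tp.mean() / tc.mean()) * 100.0)
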