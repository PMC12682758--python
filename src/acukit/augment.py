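"""Keypoint-consistent single-image augmentation: random scale, random
crop and random horizontal flip with left/right label swapping.

Mirroring a back image exchanges anatomical sides, so the flip renames
labels through an involutive swap map (L_i <-> R_i; midline M_i fixed).
Keypoint x mirrors as ``W - 1 - x`` under the 0-based pixel-center
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from skimage.transform import resize

from .types import AnnotatedImage, Keypoint, KeypointSet

__all__ = [
    "AugmentConfig",
    "default_swap_map",
    "scale",
    "crop",
    "hflip",
    "random_augment",
]


def default_swap_map(n_pairs: int = 14) -> Dict[str, str]:
    """L_i <-> R_i for i = 1..n_pairs; midline labels are fixed points."""
    m: Dict[str, str] = {}
    for i in range(1, n_pairs + 1):
        m[f"L{i}"] = f"R{i}"
        m[f"R{i}"] = f"L{i}"
    return m


def _check_involution(swap_map: Dict[str, str]) -> None:
    for a, b in swap_map.items():
        if swap_map.get(b, b) != a:
            raise ValueError(f"swap map is not involutive at {a!r} -> {b!r}")


@dataclass(frozen=True)
class AugmentConfig:
    """Random-augmentation parameters (all draws are seeded)."""

    scale_range: Tuple[float, float] = (0.7, 1.3)
    crop_size: Optional[Tuple[int, int]] = None  # (width, height); None = 80%
    min_visible_fraction: float = 0.5
    flip_prob: float = 0.5
    swap_map: Dict[str, str] = field(default_factory=default_swap_map)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.scale_range
        if not (0 < lo <= hi):
            raise ValueError("scale_range must satisfy 0 < lo <= hi")
        if not (0.0 <= self.flip_prob <= 1.0):
            raise ValueError("flip_prob must be a probability")
        _check_involution(self.swap_map)


def scale(img: AnnotatedImage, factor: float) -> AnnotatedImage:
    """Resample by ``factor`` (bilinear image, nearest mask), scale keypoints."""
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    h, w = img.shape
    nh, nw = int(round(h * factor)), int(round(w * factor))
    if nh < 1 or nw < 1:
        raise ValueError("scaled image would be smaller than 1 px")
    if factor == 1.0:
        pixels = img.pixels.copy()
        mask = None if img.marker_mask is None else img.marker_mask.copy()
    else:
        pixels = resize(img.pixels, (nh, nw), order=1, preserve_range=True,
                        anti_aliasing=factor < 1.0).astype(img.pixels.dtype)
        mask = None
        if img.marker_mask is not None:
            mask = resize(img.marker_mask.astype(float), (nh, nw), order=0,
                          preserve_range=True, anti_aliasing=False) > 0.5
    kps = KeypointSet({
        label: Keypoint(kp.x * factor, kp.y * factor, kp.visible)
        for label, kp in img.keypoints.items()
    })
    return AnnotatedImage(pixels=pixels, keypoints=kps, marker_mask=mask)


def crop(img: AnnotatedImage, origin: Tuple[int, int],
         size: Tuple[int, int]) -> AnnotatedImage:
    """Crop a window (clamped to bounds); keypoints shift by -origin.

    Keypoints falling outside the window become invisible but keep their
    shifted coordinates for audit.
    """
    h, w = img.shape
    ox, oy = origin
    sw, sh = size
    x0, y0 = max(0, int(ox)), max(0, int(oy))
    x1, y1 = min(w, int(ox) + int(sw)), min(h, int(oy) + int(sh))
    if x0 >= x1 or y0 >= y1:
        raise ValueError("crop window does not intersect the image")
    pixels = img.pixels[y0:y1, x0:x1].copy()
    mask = None if img.marker_mask is None else img.marker_mask[y0:y1, x0:x1].copy()
    kps = KeypointSet()
    for label, kp in img.keypoints.items():
        nx, ny = kp.x - x0, kp.y - y0
        inside = (0 <= nx < (x1 - x0)) and (0 <= ny < (y1 - y0))
        kps[label] = Keypoint(nx, ny, kp.visible and inside)
    return AnnotatedImage(pixels=pixels, keypoints=kps, marker_mask=mask)


def hflip(img: AnnotatedImage,
          swap_map: Optional[Dict[str, str]] = None) -> AnnotatedImage:
    """Mirror about the vertical axis and rename labels via the swap map."""
    swap_map = default_swap_map() if swap_map is None else swap_map
    _check_involution(swap_map)
    w = img.width
    pixels = img.pixels[:, ::-1].copy()
    mask = None if img.marker_mask is None else img.marker_mask[:, ::-1].copy()
    kps = KeypointSet()
    for label, kp in img.keypoints.items():
        kps[swap_map.get(label, label)] = Keypoint(w - 1 - kp.x, kp.y, kp.visible)
    return AnnotatedImage(pixels=pixels, keypoints=kps, marker_mask=mask)


def random_augment(img: AnnotatedImage, cfg: AugmentConfig,
                   index: int = 0) -> AnnotatedImage:
    """One seeded scale -> crop -> flip draw.

    The crop is resampled (up to 10 tries) until at least
    ``min_visible_fraction`` of the visible keypoints stay inside.
    """
    rng = np.random.default_rng((cfg.seed, index))
    factor = float(rng.uniform(*cfg.scale_range))
    out = scale(img, factor)

    h, w = out.shape
    if cfg.crop_size is None:
        cw, ch = max(1, int(round(w * 0.8))), max(1, int(round(h * 0.8)))
    else:
        cw, ch = cfg.crop_size
    cw, ch = min(cw, w), min(ch, h)
    n_visible = max(1, len(out.keypoints.visible_labels()))
    best = None
    for _ in range(10):
        ox = int(rng.integers(0, w - cw + 1))
        oy = int(rng.integers(0, h - ch + 1))
        cand = crop(out, (ox, oy), (cw, ch))
        frac = len(cand.keypoints.visible_labels()) / n_visible
        if best is None or frac > best[0]:
            best = (frac, cand)
        if frac >= cfg.min_visible_fraction:
            break
    out = best[1]

    if rng.random() < cfg.flip_prob:
        out = hflip(out, cfg.swap_map)
    return out
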