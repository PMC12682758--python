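"""Synthetic prone-back fixtures: skin-toned images with circular adhesive
markers, smooth depth surfaces, and noisy mock keypoint predictions.

The generator emulates the study conditions of a marker-based acupoint
dataset: a smooth skin-toned back under mild shading, dark round labels
stuck on 34 named points (M1–M6 along the spine midline, L1–L14 / R1–R14
mirrored on either side), and a registered depth frame from a camera about
a metre above the bed.  Everything is seeded and byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .types import AnnotatedImage, DepthFrame, Keypoint, KeypointSet

__all__ = [
    "FixtureSpec",
    "default_keypoint_layout",
    "make_back_image",
    "make_depth_frame",
    "mock_predictions",
]

#: Default canvas matches the camera resolution used in the study setup.
DEFAULT_WIDTH = 640
DEFAULT_HEIGHT = 480
#: Default marker disc radius in pixels (label size is a fixture choice).
DEFAULT_MARKER_RADIUS = 8
#: Skin-ish base tone (R, G, B) in 8-bit units.
DEFAULT_BASE_TONE = (214, 172, 148)


def default_keypoint_layout(
    width: int = DEFAULT_WIDTH,
    height: int = DEFAULT_HEIGHT,
) -> Dict[str, Tuple[float, float]]:
    """34 named points: 6 midline (M1–M6) plus 14 mirrored pairs (L/R 1–14).

    A regular grid loosely shaped like a prone back: midline points down the
    vertical center, lateral columns offset symmetrically.  Coordinates are
    fixture parameters, not anatomical claims.
    """
    cx = width / 2.0
    top, bottom = 0.12 * height, 0.88 * height
    layout: Dict[str, Tuple[float, float]] = {}
    for i in range(6):
        y = top + (bottom - top) * i / 5.0
        layout[f"M{i + 1}"] = (cx, y)
    # Two lateral columns per side, 7 rows each -> 14 per side.
    offsets = (0.12 * width, 0.24 * width)
    for side, sign in (("L", -1.0), ("R", +1.0)):
        idx = 1
        for off in offsets:
            for row in range(7):
                y = top + (bottom - top) * (row + 0.5) / 7.0
                layout[f"{side}{idx}"] = (cx + sign * off, y)
                idx += 1
    return layout


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic back image.

    ``shading_amplitude`` and ``noise_sd`` are in 8-bit intensity units; the
    shading is a sum of two low-frequency cosines so the inpainter sees
    non-trivial texture.
    """

    width: int = DEFAULT_WIDTH
    height: int = DEFAULT_HEIGHT
    keypoint_positions: Optional[Dict[str, Tuple[float, float]]] = None
    marker_radius: float = DEFAULT_MARKER_RADIUS
    base_tone: Tuple[int, int, int] = DEFAULT_BASE_TONE
    shading_amplitude: float = 18.0
    noise_sd: float = 2.5
    seed: int = 0

    def positions(self) -> Dict[str, Tuple[float, float]]:
        if self.keypoint_positions is None:
            return default_keypoint_layout(self.width, self.height)
        return dict(self.keypoint_positions)

    def validate(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("width and height must be positive")
        if self.marker_radius < 1:
            raise ValueError("marker_radius must be >= 1")
        for label, (x, y) in self.positions().items():
            if not (0 <= x < self.width and 0 <= y < self.height):
                raise ValueError(f"keypoint {label!r} lies outside the image")


def _disc_coverage(height: int, width: int, cx: float, cy: float, radius: float,
                   supersample: int = 4) -> np.ndarray:
    """Anti-aliased disc coverage in [0, 1] by supersampled rasterization."""
    y0 = max(0, int(np.floor(cy - radius - 1)))
    y1 = min(height, int(np.ceil(cy + radius + 2)))
    x0 = max(0, int(np.floor(cx - radius - 1)))
    x1 = min(width, int(np.ceil(cx + radius + 2)))
    cov = np.zeros((height, width))
    if y0 >= y1 or x0 >= x1:
        return cov
    s = supersample
    sub = (np.arange(s) + 0.5) / s - 0.5
    yy = (np.arange(y0, y1)[:, None] + sub[None, :]).ravel()
    xx = (np.arange(x0, x1)[:, None] + sub[None, :]).ravel()
    inside = ((yy[:, None] - cy) ** 2 + (xx[None, :] - cx) ** 2) <= radius ** 2
    block = inside.reshape(y1 - y0, s, x1 - x0, s).mean(axis=(1, 3))
    cov[y0:y1, x0:x1] = block
    return cov


def make_back_image(spec: FixtureSpec) -> AnnotatedImage:
    """Render a synthetic back image with dark marker discs on each keypoint.

    The raster is base tone + two low-frequency cosine shading fields +
    seeded Gaussian noise, with anti-aliased dark discs of
    ``spec.marker_radius`` centered on every keypoint.  The marker mask is
    true exactly where a disc covers at least half a pixel.
    """
    spec.validate()
    h, w = spec.height, spec.width
    rng = np.random.default_rng(spec.seed)

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    shade = (
        np.cos(2 * np.pi * xx / max(w, 1) * 1.3 + 0.7)
        + np.cos(2 * np.pi * yy / max(h, 1) * 0.9 + 1.9)
    ) * (spec.shading_amplitude / 2.0)

    img = np.empty((h, w, 3))
    for c, tone in enumerate(spec.base_tone):
        img[:, :, c] = tone + shade
    img += rng.normal(0.0, spec.noise_sd, size=img.shape)

    positions = spec.positions()
    mask = np.zeros((h, w), bool)
    marker_tone = np.array([30.0, 28.0, 30.0])  # dark adhesive label
    for label, (cx, cy) in positions.items():
        cov = _disc_coverage(h, w, cx, cy, spec.marker_radius)
        mask |= cov >= 0.5
        img = img * (1 - cov[:, :, None]) + cov[:, :, None] * marker_tone[None, None, :]

    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    kps = KeypointSet({label: Keypoint(x, y) for label, (x, y) in positions.items()})
    return AnnotatedImage(pixels=pixels, keypoints=kps, marker_mask=mask)


def pristine_back_image(spec: FixtureSpec) -> AnnotatedImage:
    """The same render as :func:`make_back_image` but without marker discs.

    Serves as restoration ground truth: identical seed, shading and noise,
    so the two images differ only on marker pixels.
    """
    bare = FixtureSpec(
        width=spec.width, height=spec.height, keypoint_positions={},
        marker_radius=spec.marker_radius, base_tone=spec.base_tone,
        shading_amplitude=spec.shading_amplitude, noise_sd=spec.noise_sd,
        seed=spec.seed,
    )
    clean = make_back_image(bare)
    kps = KeypointSet({l: Keypoint(x, y) for l, (x, y) in spec.positions().items()})
    return AnnotatedImage(pixels=clean.pixels, keypoints=kps,
                          marker_mask=np.zeros((spec.height, spec.width), bool))


def make_depth_frame(
    spec: FixtureSpec,
    color_to_depth_ratio: Tuple[float, float] = (1.0, 1.0),
    plane_depth: float = 800.0,
    bump_amplitude: float = 0.0,
) -> DepthFrame:
    """Smooth depth surface (plane + cosine bump), millimeters.

    ``color_to_depth_ratio`` = (s_w, s_h) gives the depth raster resolution
    relative to the color canvas; (0.5, 0.5) on 640x480 yields 320x240.
    """
    s_w, s_h = color_to_depth_ratio
    if s_w <= 0 or s_h <= 0:
        raise ValueError("resolution ratios must be positive")
    if plane_depth <= 0:
        raise ValueError("plane_depth must be positive")
    dw = int(round(spec.width * s_w))
    dh = int(round(spec.height * s_h))
    yy, xx = np.mgrid[0:dh, 0:dw].astype(float)
    depth = plane_depth + bump_amplitude * (
        np.cos(np.pi * (xx / max(dw - 1, 1) - 0.5))
        * np.cos(np.pi * (yy / max(dh - 1, 1) - 0.5))
    )
    if bump_amplitude == 0:
        depth = np.full((dh, dw), float(plane_depth))
    return DepthFrame(depth=depth, s_w=s_w, s_h=s_h)


def mock_predictions(
    truth: KeypointSet,
    sigma: float,
    miss_rate: float = 0.0,
    seed: int = 0,
) -> KeypointSet:
    """Perturb ground-truth keypoints with isotropic Gaussian pixel noise.

    Each visible point is displaced by N(0, sigma^2) independently in x and
    y (radial error therefore follows a Rayleigh(sigma) law) and is dropped
    (marked invisible) with probability ``miss_rate``.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if not (0.0 <= miss_rate <= 1.0):
        raise ValueError("miss_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = KeypointSet()
    for label, kp in truth.items():
        if not kp.visible:
            out[label] = kp
            continue
        dx, dy = rng.normal(0.0, sigma, 2) if sigma > 0 else (0.0, 0.0)
        missed = rng.random() < miss_rate
        if missed:
            out[label] = Keypoint(kp.x + dx, kp.y + dy, visible=False)
        else:
            out[label] = Keypoint(kp.x + dx, kp.y + dy, visible=True)
    return out
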