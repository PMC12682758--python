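"""SimCC sub-pixel coordinate coding and the two-stage detection harness.

SimCC represents each keypoint coordinate as a classification distribution
over sub-pixel bins along one image axis: an axis of ``extent`` pixels is
split into ``round(extent * ratio)`` bins (``ratio`` bins per pixel), the
training target is a truncated, renormalized Gaussian bump centered on the
true coordinate, the loss is a KL divergence between distributions, and
decoding takes the normalized expectation of bin centers (sub-pixel
accurate; argmax decoding is available).

The two-stage harness mirrors a top-down pose pipeline: a detector returns
the subject bounding box, the box is expanded and warped to a fixed-size
region of interest (ROI), a localizer predicts keypoints in ROI
coordinates, and the inverse affine maps them back to image coordinates.
Neural inference is out of scope — detector and localizer are injected
callables; oracle and noisy mocks ship with the package.
"""

from __future__ import annotations

import inspect
from dataclasses import dataclass
from typing import Callable, Optional, Tuple

import numpy as np
from skimage.transform import AffineTransform, warp

from .types import AnnotatedImage, BoundingBox, Keypoint, KeypointSet

__all__ = [
    "SimCCLabel",
    "RoiTransform",
    "DetectorError",
    "LocalizerError",
    "simcc_encode",
    "simcc_decode",
    "kl_divergence",
    "roi_transform",
    "run_pipeline",
    "oracle_detector",
    "OracleLocalizer",
    "NoisyLocalizer",
]

DEFAULT_SPLITTING_RATIO = 2.0
DEFAULT_SIGMA_BINS = 6.0
DEFAULT_PADDING = 1.25
DEFAULT_OUT_SIZE = (256, 192)  # (width, height)


class DetectorError(RuntimeError):
    """First-stage failure: no subject bounding box."""


class LocalizerError(RuntimeError):
    """Second-stage failure: keypoint localization did not produce output."""


@dataclass(frozen=True)
class SimCCLabel:
    """Per-axis classification targets for one keypoint."""

    x_vector: np.ndarray
    y_vector: np.ndarray
    splitting_ratio: float
    sigma_bins: float


def simcc_encode(coord: float, extent: float,
                 ratio: float = DEFAULT_SPLITTING_RATIO,
                 sigma_bins: float = DEFAULT_SIGMA_BINS) -> np.ndarray:
    """Gaussian classification target over sub-pixel bins for one axis.

    Bin ``b`` represents coordinate ``b / ratio``; the bump is centered at
    ``coord * ratio``, truncated at the axis borders and renormalized to
    sum 1.
    """
    if not (0 <= coord < extent):
        raise ValueError(f"coordinate {coord} outside [0, {extent})")
    if ratio <= 0 or sigma_bins <= 0:
        raise ValueError("ratio and sigma_bins must be positive")
    n_bins = int(round(extent * ratio))
    bins = np.arange(n_bins, dtype=float)
    mu = coord * ratio
    w = np.exp(-0.5 * ((bins - mu) / sigma_bins) ** 2)
    total = w.sum()
    if total == 0:
        raise ValueError("degenerate encoding (no support)")
    return w / total


def simcc_decode(vector: np.ndarray, ratio: float = DEFAULT_SPLITTING_RATIO,
                 mode: str = "expectation") -> float:
    """Coordinate from a bin-weight vector.

    ``expectation`` (default) takes the mean of bin centers under the
    normalized weights — sub-pixel accurate; ``argmax`` returns the center
    of the heaviest bin.
    """
    v = np.asarray(vector, float)
    if np.any(v < 0):
        raise ValueError("weights must be non-negative")
    total = v.sum()
    if total == 0:
        raise ValueError("all-zero weight vector")
    if mode == "argmax":
        return float(np.argmax(v) / ratio)
    if mode != "expectation":
        raise ValueError("mode must be 'expectation' or 'argmax'")
    bins = np.arange(v.size, dtype=float)
    return float((bins @ v) / total / ratio)


def encode_label(x: float, y: float, width: float, height: float,
                 ratio: float = DEFAULT_SPLITTING_RATIO,
                 sigma_bins: float = DEFAULT_SIGMA_BINS) -> SimCCLabel:
    return SimCCLabel(
        x_vector=simcc_encode(x, width, ratio, sigma_bins),
        y_vector=simcc_encode(y, height, ratio, sigma_bins),
        splitting_ratio=ratio,
        sigma_bins=sigma_bins,
    )


def kl_divergence(pred: np.ndarray, target: np.ndarray,
                  epsilon: float = 1e-12) -> float:
    """KL(target || pred) with epsilon flooring; >= 0, zero iff equal."""
    p = np.asarray(pred, float)
    t = np.asarray(target, float)
    if p.shape != t.shape:
        raise ValueError("length mismatch")
    p = np.clip(p, epsilon, None)
    t = np.clip(t, epsilon, None)
    p = p / p.sum()
    t = t / t.sum()
    return float(np.sum(t * np.log(t / p)))


@dataclass(frozen=True)
class RoiTransform:
    """Affine image->ROI mapping and its inverse.

    ``matrix`` maps homogeneous image coordinates to ROI-input coordinates;
    ``out_size`` is (width, height) of the ROI raster.
    """

    matrix: np.ndarray          # 3x3 forward (image -> ROI)
    inverse_matrix: np.ndarray  # 3x3 inverse (ROI -> image)
    out_size: Tuple[int, int]
    padding: float

    def forward(self, x: float, y: float) -> Tuple[float, float]:
        p = self.matrix @ np.array([x, y, 1.0])
        return float(p[0]), float(p[1])

    def inverse(self, x: float, y: float) -> Tuple[float, float]:
        p = self.inverse_matrix @ np.array([x, y, 1.0])
        return float(p[0]), float(p[1])


def roi_transform(bbox: BoundingBox, padding: float = DEFAULT_PADDING,
                  out_size: Tuple[int, int] = DEFAULT_OUT_SIZE) -> RoiTransform:
    """Aspect-preserving affine from a padded bounding box to the ROI raster.

    The box is expanded about its center by ``padding``, then the shorter
    side is widened so the box aspect matches ``out_size``; a uniform scale
    plus shift maps it onto the output raster.
    """
    if padding <= 0:
        raise ValueError("padding must be positive")
    out_w, out_h = out_size
    if out_w < 1 or out_h < 1:
        raise ValueError("out_size must be at least 1 x 1")
    cx, cy = bbox.center
    w = bbox.width * padding
    h = bbox.height * padding
    if w <= 0 or h <= 0:
        raise ValueError("degenerate bounding box")
    aspect = out_w / out_h
    if w / h > aspect:
        h = w / aspect
    else:
        w = h * aspect
    s = out_w / w  # == out_h / h
    fwd = np.array([
        [s, 0.0, out_w / 2.0 - s * cx],
        [0.0, s, out_h / 2.0 - s * cy],
        [0.0, 0.0, 1.0],
    ])
    inv = np.linalg.inv(fwd)
    return RoiTransform(matrix=fwd, inverse_matrix=inv,
                        out_size=(int(out_w), int(out_h)), padding=float(padding))


def extract_roi(image: np.ndarray, t: RoiTransform) -> np.ndarray:
    """Warp the image into the ROI raster (bilinear, edge padding)."""
    out_w, out_h = t.out_size
    # skimage's warp wants the ROI->image map
    inv = AffineTransform(matrix=t.inverse_matrix)
    roi = warp(np.asarray(image, float), inv, output_shape=(out_h, out_w),
               order=1, mode="edge", preserve_range=True)
    return roi


def _call_localizer(localizer, roi: np.ndarray, t: RoiTransform) -> KeypointSet:
    try:
        n_params = len(inspect.signature(localizer).parameters)
    except (TypeError, ValueError):
        n_params = 1
    return localizer(roi, t) if n_params >= 2 else localizer(roi)


def run_pipeline(image: AnnotatedImage,
                 detector: Callable[[AnnotatedImage], Optional[BoundingBox]],
                 localizer,
                 padding: float = DEFAULT_PADDING,
                 out_size: Tuple[int, int] = DEFAULT_OUT_SIZE) -> KeypointSet:
    """Detect -> crop -> localize -> map back to image coordinates.

    Keypoints the localizer places outside the ROI raster are marked
    invisible (their back-projected coordinates are kept for audit).
    """
    bbox = detector(image)
    if bbox is None:
        raise DetectorError("detector returned no bounding box")
    t = roi_transform(bbox, padding, out_size)
    roi = extract_roi(image.pixels, t)
    try:
        roi_kps = _call_localizer(localizer, roi, t)
    except Exception as exc:  # noqa: BLE001 — re-tag the failure stage
        raise LocalizerError(f"localizer failed: {exc}") from exc
    out_w, out_h = t.out_size
    out = KeypointSet()
    for label, kp in roi_kps.items():
        inside = (0 <= kp.x < out_w) and (0 <= kp.y < out_h)
        ix, iy = t.inverse(kp.x, kp.y)
        out[label] = Keypoint(ix, iy, kp.visible and inside)
    return out


# ---------------------------------------------------------------------------
# Mock stage implementations (the repo ships no neural networks)


def oracle_detector(image: AnnotatedImage, pad_px: float = 10.0
                    ) -> Optional[BoundingBox]:
    """Ground-truth detector: tight box around the visible keypoints."""
    labels = image.keypoints.visible_labels()
    if not labels:
        return None
    xy = image.keypoints.as_array(labels)
    box = BoundingBox(
        float(xy[:, 0].min() - pad_px), float(xy[:, 1].min() - pad_px),
        float(xy[:, 0].max() + pad_px), float(xy[:, 1].max() + pad_px),
    )
    return box.clamped(image.width, image.height)


class OracleLocalizer:
    """Ground-truth localizer: maps the true keypoints into ROI coordinates."""

    def __init__(self, truth: KeypointSet) -> None:
        self.truth = truth

    def __call__(self, roi: np.ndarray, t: RoiTransform) -> KeypointSet:
        out = KeypointSet()
        for label, kp in self.truth.items():
            rx, ry = t.forward(kp.x, kp.y)
            out[label] = Keypoint(rx, ry, kp.visible)
        return out


class NoisyLocalizer(OracleLocalizer):
    """Oracle localizer plus isotropic Gaussian noise in *image* pixels.

    ``sigma_px`` is expressed in original-image pixels and scaled into ROI
    units through the affine, so downstream metrics in image coordinates
    see exactly that noise level.
    """

    def __init__(self, truth: KeypointSet, sigma_px: float, seed: int = 0) -> None:
        super().__init__(truth)
        self.sigma_px = float(sigma_px)
        self.rng = np.random.default_rng(seed)

    def __call__(self, roi: np.ndarray, t: RoiTransform) -> KeypointSet:
        scale = float(t.matrix[0, 0])
        base = super().__call__(roi, t)
        out = KeypointSet()
        for label, kp in base.items():
            dx, dy = self.rng.normal(0.0, self.sigma_px * scale, 2)
            out[label] = Keypoint(kp.x + dx, kp.y + dy, kp.visible)
        return out
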