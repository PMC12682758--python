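"""Pixel-to-robot-base 3-D localization chain.

Three steps take a detected acupoint from color-image pixels to the robot
base frame:

1. depth registration — the color pixel (u, v) is scaled by the
   resolution ratios (s_w, s_h) into the depth raster and the depth value
   z (mm) is read there;
2. back-projection — under the central perspective (pinhole) model,
   ``x_c = (u - u0) * rho_w * z / f`` and ``y_c = (v - v0) * rho_h * z / f``
   with focal length f (mm), pixel pitch rho (mm/px) and principal point
   (u0, v0);
3. rigid transform — the homogeneous camera->base matrix T_cb maps
   P_camera to P_base.

Zero depth encodes "no return"; keypoints over such holes are reported in
a separate invalid list, never silently dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .types import DepthFrame, KeypointSet

__all__ = [
    "CameraModel",
    "RigidTransform",
    "Point3D",
    "InvalidDepthError",
    "register_depth",
    "pixel_to_camera",
    "camera_to_base",
    "localize_keypoints",
    "load_intrinsics",
    "load_extrinsics",
]


class InvalidDepthError(ValueError):
    """The registered depth pixel holds no return (zero depth)."""


@dataclass(frozen=True)
class CameraModel:
    """Pinhole intrinsics: focal length (mm), pixel pitch (mm/px), principal
    point (px)."""

    f: float
    rho_w: float
    rho_h: float
    u0: float
    v0: float

    def __post_init__(self) -> None:
        if self.f <= 0 or self.rho_w <= 0 or self.rho_h <= 0:
            raise ValueError("focal length and pixel pitch must be positive")

    @property
    def fx(self) -> float:
        """Focal length in horizontal pixels, f / rho_w."""
        return self.f / self.rho_w

    @property
    def fy(self) -> float:
        return self.f / self.rho_h

    @property
    def K(self) -> np.ndarray:
        """3x3 intrinsic matrix diag(f/rho_w, f/rho_h, 1) with the principal
        point in the last column."""
        return np.array([
            [self.fx, 0.0, self.u0],
            [0.0, self.fy, self.v0],
            [0.0, 0.0, 1.0],
        ])

    @classmethod
    def from_pixel_focal(cls, fx_px: float, fy_px: float,
                         u0: float, v0: float) -> "CameraModel":
        """Build from pixel-unit focals; a nominal 1 mm focal length is used
        (only the ratios f/rho enter the projection)."""
        return cls(f=1.0, rho_w=1.0 / fx_px, rho_h=1.0 / fy_px, u0=u0, v0=v0)


@dataclass(frozen=True)
class RigidTransform:
    """Homogeneous 4x4 camera->base transform with a proper rotation block."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, float)
        if m.shape != (4, 4):
            raise ValueError("transform must be 4x4")
        if not np.allclose(m[3], [0, 0, 0, 1], atol=1e-9):
            raise ValueError("last row must be (0, 0, 0, 1)")
        r = m[:3, :3]
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation block is not orthonormal")
        if not np.isclose(np.linalg.det(r), 1.0, atol=1e-6):
            raise ValueError("rotation block must have determinant +1")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rotation_translation(cls, rotation: np.ndarray,
                                  translation) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = rotation
        m[:3, 3] = translation
        return cls(m)

    def inverse(self) -> "RigidTransform":
        m = np.eye(4)
        r = self.matrix[:3, :3]
        m[:3, :3] = r.T
        m[:3, 3] = -r.T @ self.matrix[:3, 3]
        return RigidTransform(m)


@dataclass(frozen=True)
class Point3D:
    """A 3-D point in millimeters, tagged with its frame."""

    x: float
    y: float
    z: float
    frame: str = "camera"

    def __post_init__(self) -> None:
        if self.frame not in ("camera", "base"):
            raise ValueError("frame must be 'camera' or 'base'")
        if not all(np.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValueError("coordinates must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


def register_depth(u: float, v: float, frame: DepthFrame,
                   interpolate: bool = False) -> float:
    """Depth (mm) at color pixel (u, v) via resolution-ratio registration.

    The color coordinates are scaled by (s_w, s_h) into the depth raster
    and read at the nearest depth pixel (or bilinearly when
    ``interpolate``).  Zero depth raises :class:`InvalidDepthError`.
    """
    dh, dw = frame.depth.shape
    w = dw / frame.s_w
    h = dh / frame.s_h
    if not (0 <= u < w and 0 <= v < h):
        raise ValueError(f"pixel ({u}, {v}) outside color bounds {w} x {h}")
    up = u * frame.s_w
    vp = v * frame.s_h
    if interpolate:
        x0, y0 = int(np.floor(up)), int(np.floor(vp))
        x1, y1 = min(x0 + 1, dw - 1), min(y0 + 1, dh - 1)
        fx, fy = up - x0, vp - y0
        patch = frame.depth[[y0, y0, y1, y1], [x0, x1, x0, x1]]
        if np.any(patch == 0):
            raise InvalidDepthError(f"no depth return near ({u}, {v})")
        z = (patch[0] * (1 - fx) * (1 - fy) + patch[1] * fx * (1 - fy)
             + patch[2] * (1 - fx) * fy + patch[3] * fx * fy)
    else:
        ui = min(int(round(up)), dw - 1)
        vi = min(int(round(vp)), dh - 1)
        z = frame.depth[vi, ui]
    if z == 0:
        raise InvalidDepthError(f"no depth return at ({u}, {v})")
    return float(z)


def pixel_to_camera(u: float, v: float, z: float, cam: CameraModel) -> Point3D:
    """Back-project a pixel with known depth into the camera frame."""
    if z <= 0:
        raise ValueError("depth must be positive")
    x_c = (u - cam.u0) * cam.rho_w * z / cam.f
    y_c = (v - cam.v0) * cam.rho_h * z / cam.f
    return Point3D(x_c, y_c, float(z), frame="camera")


def camera_to_project(p: Point3D, cam: CameraModel) -> Tuple[float, float]:
    """Forward projection (the algebraic inverse of back-projection)."""
    if p.z <= 0:
        raise ValueError("point must be in front of the camera")
    x = p.x * cam.f / p.z
    y = p.y * cam.f / p.z
    return x / cam.rho_w + cam.u0, y / cam.rho_h + cam.v0


def camera_to_base(p: Point3D, t: RigidTransform) -> Point3D:
    """Apply the homogeneous camera->base transform."""
    if p.frame != "camera":
        raise ValueError("point must be in the camera frame")
    vec = t.matrix @ np.array([p.x, p.y, p.z, 1.0])
    return Point3D(float(vec[0]), float(vec[1]), float(vec[2]), frame="base")


def localize_keypoints(kps: KeypointSet, frame: DepthFrame, cam: CameraModel,
                       t: RigidTransform, interpolate: bool = False
                       ) -> Tuple[Dict[str, Point3D], List[str]]:
    """Full chain per visible keypoint; returns (located, invalid labels).

    A keypoint over a zero-depth hole lands in the invalid list with its
    label; invisible keypoints are skipped.
    """
    located: Dict[str, Point3D] = {}
    invalid: List[str] = []
    for label, kp in kps.items():
        if not kp.visible:
            continue
        try:
            z = register_depth(kp.x, kp.y, frame, interpolate=interpolate)
        except InvalidDepthError:
            invalid.append(label)
            continue
        located[label] = camera_to_base(pixel_to_camera(kp.x, kp.y, z, cam), t)
    return located, invalid


# ---------------------------------------------------------------------------
# Config I/O


def load_intrinsics(path) -> CameraModel:
    """Read intrinsics JSON: either {f_mm, rho_w_mm, rho_h_mm, u0, v0} or
    {fx_px, fy_px, u0, v0}."""
    doc = json.loads(Path(path).read_text())
    if "f_mm" in doc:
        return CameraModel(f=doc["f_mm"], rho_w=doc["rho_w_mm"],
                           rho_h=doc["rho_h_mm"], u0=doc["u0"], v0=doc["v0"])
    return CameraModel.from_pixel_focal(doc["fx_px"], doc["fy_px"],
                                        doc["u0"], doc["v0"])


def load_extrinsics(path) -> RigidTransform:
    """Read a camera->base transform JSON: a 4x4 row-major array."""
    doc = json.loads(Path(path).read_text())
    return RigidTransform(np.asarray(doc, float))
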