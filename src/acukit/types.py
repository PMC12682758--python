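"""Shared containers for images, keypoints, depth frames and boxes.

Coordinate convention throughout the package: 0-based pixel indices,
x rightward, y downward, sub-pixel floats allowed, pixel-center sampling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, Mapping, Optional, Tuple

import numpy as np

__all__ = [
    "Keypoint",
    "KeypointSet",
    "AnnotatedImage",
    "DepthFrame",
    "BoundingBox",
    "read_labelme",
    "write_labelme",
]


@dataclass(frozen=True)
class Keypoint:
    """A named 2-D point in pixel units with a visibility flag."""

    x: float
    y: float
    visible: bool = True

    def __post_init__(self) -> None:
        if self.visible and not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("visible keypoint must have finite coordinates")


class KeypointSet:
    """Ordered mapping of unique labels to :class:`Keypoint` entries."""

    def __init__(self, entries: Optional[Mapping[str, Keypoint]] = None) -> None:
        self._entries: Dict[str, Keypoint] = {}
        if entries:
            for label, kp in entries.items():
                self[label] = kp

    def __setitem__(self, label: str, kp: Keypoint) -> None:
        self._entries[str(label)] = kp

    def __getitem__(self, label: str) -> Keypoint:
        return self._entries[label]

    def __contains__(self, label: str) -> bool:
        return label in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KeypointSet):
            return NotImplemented
        return self._entries == other._entries

    def __repr__(self) -> str:
        return f"KeypointSet({len(self)} points)"

    def items(self):
        return self._entries.items()

    def labels(self) -> Tuple[str, ...]:
        return tuple(self._entries)

    def visible_labels(self) -> Tuple[str, ...]:
        return tuple(l for l, kp in self._entries.items() if kp.visible)

    def copy(self) -> "KeypointSet":
        return KeypointSet(dict(self._entries))

    def as_array(self, labels=None) -> np.ndarray:
        """(n, 2) float array of x, y for the given (default: all) labels."""
        labels = self.labels() if labels is None else labels
        return np.array([[self[l].x, self[l].y] for l in labels], float).reshape(-1, 2)

    @classmethod
    def from_arrays(cls, labels, xy, visible=None) -> "KeypointSet":
        xy = np.asarray(xy, float).reshape(-1, 2)
        if visible is None:
            visible = np.ones(len(xy), bool)
        out = cls()
        for label, (x, y), vis in zip(labels, xy, visible):
            out[label] = Keypoint(float(x), float(y), bool(vis))
        return out


@dataclass
class AnnotatedImage:
    """RGB raster plus named keypoints and an optional binary marker mask."""

    pixels: np.ndarray
    keypoints: KeypointSet
    marker_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("pixels must be an H x W x 3 raster")
        self.pixels = px
        if self.marker_mask is not None:
            m = np.asarray(self.marker_mask, bool)
            if m.shape != px.shape[:2]:
                raise ValueError("marker_mask shape must match image shape")
            self.marker_mask = m

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]


@dataclass
class DepthFrame:
    """Depth raster in millimeters with the color→depth resolution factors.

    ``s_w = W'/W`` and ``s_h = H'/H`` relate the depth raster (W', H') to the
    paired color image (W, H); zero depth encodes "no return".
    """

    depth: np.ndarray
    s_w: float
    s_h: float

    def __post_init__(self) -> None:
        d = np.asarray(self.depth, float)
        if d.ndim != 2:
            raise ValueError("depth must be a 2-D raster")
        if np.any(d < 0):
            raise ValueError("depth values must be >= 0")
        if self.s_w <= 0 or self.s_h <= 0:
            raise ValueError("registration factors must be positive")
        self.depth = d


@dataclass(frozen=True)
class BoundingBox:
    """Half-open axis-aligned pixel box [x_min, x_max) x [y_min, y_max)."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError("bounding box must have positive extent")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def center(self) -> Tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    def clamped(self, width: int, height: int) -> "BoundingBox":
        return BoundingBox(
            max(0.0, self.x_min),
            max(0.0, self.y_min),
            min(float(width), self.x_max),
            min(float(height), self.y_max),
        )


# ---------------------------------------------------------------------------
# Labelme-style point annotation I/O


def write_labelme(path, keypoints: KeypointSet, width: int, height: int) -> None:
    """Write a Labelme-style point-annotation JSON file.

    Only visible points are written; coordinates are 0-based floats.
    """
    shapes = [
        {"label": label, "points": [[kp.x, kp.y]], "shape_type": "point"}
        for label, kp in keypoints.items()
        if kp.visible
    ]
    doc = {"imageHeight": int(height), "imageWidth": int(width), "shapes": shapes}
    Path(path).write_text(json.dumps(doc, indent=2))


def read_labelme(path) -> Tuple[KeypointSet, int, int]:
    """Read a Labelme-style point JSON; returns (keypoints, width, height)."""
    doc = json.loads(Path(path).read_text())
    kps = KeypointSet()
    for shape in doc.get("shapes", []):
        if shape.get("shape_type", "point") != "point":
            continue
        (x, y), = shape["points"]
        kps[shape["label"]] = Keypoint(float(x), float(y), True)
    return kps, int(doc["imageWidth"]), int(doc["imageHeight"])
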