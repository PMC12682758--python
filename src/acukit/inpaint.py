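"""Exemplar-based marker removal (de-labeling) for skin images.

Two variants of patch-based object removal are provided:

* ``baseline`` — the classical exemplar scheme: fill-front priority is the
  product of a confidence term C(p) and a data (isophote) term D(p), and the
  best-matching source patch is searched over the whole image.
* ``improved`` — priority becomes the exponential sum ``P(p) = exp(C(p) +
  D(p))`` with the confidence floored at ``k_thr``, so the priority stays
  informative even when confidence or isophote strength decays to zero; the
  source-patch search is restricted to an elliptic band around each marker
  (markers are near-elliptic adhesive labels), split into four quadrants
  along the symmetry axes, with a whole-image fallback when the band offers
  too few candidates.

Both variants share the same fill loop: extract the fill front, score
priorities, copy the best-matching patch into the unknown pixels of the
top-priority patch, propagate confidence, repeat until nothing remains.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "FillState",
    "InpaintParams",
    "EllipseRegion",
    "IterationLog",
    "NoCandidatesError",
    "extract_front",
    "fill_mask",
    "priority_terms",
    "elliptic_region",
    "match_patch",
    "inpaint_image",
]

_LUMA = np.array([0.299, 0.587, 0.114])  # Rec.601


class NoCandidatesError(RuntimeError):
    """No valid source patch exists in the requested search region."""


@dataclass
class InpaintParams:
    """Tunable parameters of the fill loop.

    ``alpha`` normalizes the data term (255 for 8-bit luminance);
    ``k_thr`` is the confidence floor of the improved priority;
    ``ellipse_margin`` scales the elliptic search band relative to the
    marker's moment ellipse; a band offering fewer than ``min_candidates``
    source patches triggers a whole-image fallback.
    """

    patch_radius: int = 4
    k_thr: float = 0.2
    alpha: float = 255.0
    mode: str = "improved"
    ellipse_margin: float = 2.5
    min_candidates: int = 50
    seed: int = 0  # reserved; the algorithm is deterministic

    def __post_init__(self) -> None:
        if self.patch_radius < 1:
            raise ValueError("patch_radius must be >= 1")
        if not (0.0 < self.k_thr < 1.0):
            raise ValueError("k_thr must lie in (0, 1)")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.ellipse_margin < 1:
            raise ValueError("ellipse_margin must be >= 1")
        if self.mode not in ("baseline", "improved"):
            raise ValueError("mode must be 'baseline' or 'improved'")


@dataclass
class FillState:
    """Bookkeeping of one in-progress fill.

    ``confidence`` is 1 on the original source region and 0 on the region to
    fill; ``remaining`` marks the yet-unfilled pixels (the region Omega).
    """

    confidence: np.ndarray
    remaining: np.ndarray
    patch_radius: int

    @classmethod
    def initial(cls, mask: np.ndarray, patch_radius: int) -> "FillState":
        remaining = np.asarray(mask, bool).copy()
        return cls(
            confidence=(~remaining).astype(float),
            remaining=remaining,
            patch_radius=int(patch_radius),
        )

    @property
    def front(self) -> np.ndarray:
        return extract_front(self.remaining)


@dataclass
class IterationLog:
    """Per-run record: per-iteration fill events plus wall time and marker count."""

    fills: List[Tuple[Tuple[int, int], Tuple[int, int], int]] = field(default_factory=list)
    elapsed_seconds: float = 0.0
    marker_count: int = 0
    fallback_count: int = 0
    mode: str = "improved"

    @property
    def iterations(self) -> int:
        return len(self.fills)

    def fill_order(self) -> List[Tuple[int, int]]:
        """Sequence of chosen front pixels (x, y), one per iteration."""
        return [p for p, _, _ in self.fills]


def fill_mask(marker_mask: np.ndarray, grow: int = 1) -> np.ndarray:
    """Region to fill from a marker mask: the mask dilated by ``grow`` px.

    Physical adhesive labels have soft rasterized boundaries; pixels just
    outside the at-least-half-covered mask are still partially darkened.
    Growing the fill region by one pixel covers the full label footprint,
    which is the standard de-labeling practice (a mask that stops at the
    half-coverage contour leaves a visible dark ring).
    """
    if grow < 0:
        raise ValueError("grow must be >= 0")
    m = np.asarray(marker_mask, bool)
    if grow == 0:
        return m.copy()
    return ndimage.binary_dilation(m, np.ones((3, 3), bool), iterations=grow)


def extract_front(remaining: np.ndarray) -> np.ndarray:
    """Boolean map of fill-front pixels: Omega pixels with a 4-neighbor in Phi."""
    rem = np.asarray(remaining, bool)
    known = ~rem
    has_known = np.zeros_like(rem)
    has_known[1:, :] |= known[:-1, :]
    has_known[:-1, :] |= known[1:, :]
    has_known[:, 1:] |= known[:, :-1]
    has_known[:, :-1] |= known[:, 1:]
    # image border counts as no neighbour, not as known
    return rem & has_known


def _window(p_yx: Tuple[int, int], radius: int, shape: Tuple[int, int]):
    y, x = p_yx
    return (slice(max(0, y - radius), min(shape[0], y + radius + 1)),
            slice(max(0, x - radius), min(shape[1], x + radius + 1)))


def _confidence_term(state: FillState, y: int, x: int) -> float:
    """Mean confidence over the patch window, normalized by full patch area."""
    win = _window((y, x), state.patch_radius, state.remaining.shape)
    area = (2 * state.patch_radius + 1) ** 2
    return float(state.confidence[win].sum() / area)


def _front_normal(remaining: np.ndarray, y: int, x: int) -> np.ndarray:
    """Unit normal of the fill-front at (y, x), from a box-smoothed indicator."""
    win = _window((y, x), 2, remaining.shape)
    smooth = ndimage.uniform_filter(remaining[win].astype(float), size=3)
    yy, xx = y - win[0].start, x - win[1].start
    gy = np.gradient(smooth, axis=0)[yy, xx]
    gx = np.gradient(smooth, axis=1)[yy, xx]
    norm = np.hypot(gy, gx)
    if norm == 0:
        return np.zeros(2)
    return np.array([gy, gx]) / norm


def _masked_gradient(lum: np.ndarray, known: np.ndarray):
    """Per-pixel luminance gradient using known neighbours only.

    Central differences where both lateral neighbours are known, one-sided
    where only one is, zero otherwise; gradients are attributed to known
    pixels only.
    """
    h, w = lum.shape
    gx = np.zeros((h, w))
    gy = np.zeros((h, w))
    kl = np.zeros((h, w), bool); kl[:, 1:] = known[:, :-1]
    kr = np.zeros((h, w), bool); kr[:, :-1] = known[:, 1:]
    ku = np.zeros((h, w), bool); ku[1:, :] = known[:-1, :]
    kd = np.zeros((h, w), bool); kd[:-1, :] = known[1:, :]
    left = np.zeros((h, w)); left[:, 1:] = lum[:, :-1]
    right = np.zeros((h, w)); right[:, :-1] = lum[:, 1:]
    up = np.zeros((h, w)); up[1:, :] = lum[:-1, :]
    down = np.zeros((h, w)); down[:-1, :] = lum[1:, :]

    both = kl & kr
    gx[both] = (right[both] - left[both]) / 2.0
    onlyr = kr & ~kl
    gx[onlyr] = right[onlyr] - lum[onlyr]
    onlyl = kl & ~kr
    gx[onlyl] = lum[onlyl] - left[onlyl]
    both = ku & kd
    gy[both] = (down[both] - up[both]) / 2.0
    onlyd = kd & ~ku
    gy[onlyd] = down[onlyd] - lum[onlyd]
    onlyu = ku & ~kd
    gy[onlyu] = lum[onlyu] - up[onlyu]
    gx[~known] = 0.0
    gy[~known] = 0.0
    return gy, gx


def _data_term(lum, known, state: FillState, y: int, x: int,
               alpha: float, grad_fields=None) -> float:
    """|isophote . normal| / alpha at the strongest known isophote in the patch."""
    win = _window((y, x), state.patch_radius, state.remaining.shape)
    if grad_fields is None:
        gy, gx = _masked_gradient(lum[win], known[win])
        wy, wx = gy, gx
    else:
        gy, gx = grad_fields
        wy, wx = gy[win], gx[win]
    mag2 = wy ** 2 + wx ** 2
    if not np.any(mag2 > 0):
        return 0.0
    iy, ix = np.unravel_index(int(np.argmax(mag2)), mag2.shape)
    # isophote = 90deg-rotated gradient
    iso = np.array([-wx[iy, ix], wy[iy, ix]])  # (dy, dx) of the level line
    n = _front_normal(state.remaining, y, x)
    return float(abs(iso @ n) / alpha)


def priority_terms(image: np.ndarray, state: FillState, p: Tuple[float, float],
                   params: InpaintParams) -> Tuple[float, float, float]:
    """Confidence, data and priority terms for front pixel ``p`` = (x, y).

    Improved mode floors the confidence at ``k_thr`` and returns the
    exponential-sum priority ``exp(C + D)``; baseline mode returns the
    classical product ``C * D`` with unfloored confidence.
    """
    x, y = int(round(p[0])), int(round(p[1]))
    front = state.front
    if not front[y, x]:
        raise ValueError(f"pixel ({x}, {y}) is not on the fill front")
    img = np.asarray(image, float)
    lum = img @ _LUMA
    known = ~state.remaining
    c_raw = _confidence_term(state, y, x)
    d = _data_term(lum, known, state, y, x, params.alpha)
    if params.mode == "improved":
        c = max(c_raw, params.k_thr)
        return c, d, float(np.exp(c + d))
    return c_raw, d, c_raw * d


@dataclass
class EllipseRegion:
    """Moment ellipse of a marker component with a scaled search band.

    ``axes`` are the half-lengths (major, minor) of the unscaled moment
    ellipse (twice the second-moment radii); the search band is the ellipse
    scaled by ``margin``, minus the component, split into four quadrants
    along the symmetry axes.
    """

    center: Tuple[float, float]  # (x, y)
    axes: Tuple[float, float]    # (major, minor) half-lengths, pixels
    orientation: float           # radians, major axis vs +x
    margin: float
    component: np.ndarray        # snapshot of Omega at construction

    def _uv(self, x, y):
        ct, st = np.cos(self.orientation), np.sin(self.orientation)
        dx = np.asarray(x, float) - self.center[0]
        dy = np.asarray(y, float) - self.center[1]
        return dx * ct + dy * st, -dx * st + dy * ct

    def contains(self, x, y) -> np.ndarray:
        """True where (x, y) lies inside the margin-scaled ellipse."""
        if not np.isfinite(self.margin):
            return np.ones(np.broadcast(np.asarray(x), np.asarray(y)).shape, bool)
        u, v = self._uv(x, y)
        a, b = (self.axes[0] * self.margin, self.axes[1] * self.margin)
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0

    def band(self) -> np.ndarray:
        """Pixel mask of the search band: scaled ellipse minus the component."""
        h, w = self.component.shape
        yy, xx = np.mgrid[0:h, 0:w]
        return self.contains(xx, yy) & ~self.component

    def quadrant_of(self, x: float, y: float) -> int:
        """Quadrant index 0..3 (counterclockwise from +u, +v) of a point."""
        u, v = self._uv(x, y)
        if u >= 0 and v >= 0:
            return 0
        if u < 0 and v >= 0:
            return 1
        if u < 0 and v < 0:
            return 2
        return 3

    def quadrant_masks(self) -> List[np.ndarray]:
        """Four disjoint masks partitioning the band along the symmetry axes."""
        h, w = self.component.shape
        yy, xx = np.mgrid[0:h, 0:w]
        band = self.band()
        u, v = self._uv(xx, yy)
        quads = [
            band & (u >= 0) & (v >= 0),
            band & (u < 0) & (v >= 0),
            band & (u < 0) & (v < 0),
            band & (u >= 0) & (v < 0),
        ]
        return quads


def elliptic_region(component: np.ndarray, margin: float = 2.5) -> EllipseRegion:
    """Fit the moment ellipse of a connected marker component.

    Center = centroid; half-axes = twice the square roots of the second
    central moments' eigenvalues (so a rasterized disc of radius r maps to
    half-axes ~ r); orientation = direction of the leading eigenvector.
    """
    comp = np.asarray(component, bool)
    ys, xs = np.nonzero(comp)
    if ys.size == 0:
        raise ValueError("component is empty")
    cx, cy = xs.mean(), ys.mean()
    dx, dy = xs - cx, ys - cy
    cov = np.array([[np.mean(dx * dx), np.mean(dx * dy)],
                    [np.mean(dx * dy), np.mean(dy * dy)]])
    evals, evecs = np.linalg.eigh(cov)  # ascending
    minor = max(2.0 * np.sqrt(max(evals[0], 0.0)), 1.0)
    major = max(2.0 * np.sqrt(max(evals[1], 0.0)), minor)
    vec = evecs[:, 1]  # (x, y) of major axis
    orientation = float(np.arctan2(vec[1], vec[0]))
    return EllipseRegion(center=(float(cx), float(cy)), axes=(major, minor),
                         orientation=orientation, margin=float(margin),
                         component=comp.copy())


def _valid_centers(remaining: np.ndarray, radius: int) -> np.ndarray:
    """Centers whose full patch lies in bounds and contains no Omega pixel."""
    occupied = ndimage.maximum_filter(
        remaining.astype(np.uint8), size=2 * radius + 1,
        mode="constant", cval=1,
    )
    return occupied == 0


def _ssd_at(img: np.ndarray, p_yx, cand_yx, offsets, targets) -> np.ndarray:
    cy, cx = cand_yx
    ssd = np.zeros(cy.shape, float)
    for (dy, dx), tval in zip(offsets, targets):
        vals = img[cy + dy, cx + dx, :]
        diff = vals - tval
        ssd += np.einsum("ij,ij->i", diff, diff)
    return ssd


def match_patch(image: np.ndarray, state: FillState, p: Tuple[float, float],
                region: Optional[EllipseRegion] = None) -> Tuple[int, int]:
    """Best source-patch center q = (x, y) for front pixel ``p``.

    Minimizes the sum of squared color differences over the already-known
    pixels of the patch around p; ties break toward smaller Euclidean
    distance to p, then row-major order.  With a region, candidates are
    restricted to its margin-scaled ellipse (quadrants are screened starting
    from the one containing p, then counterclockwise — the deterministic
    tie-break makes the final choice independent of screening order).
    """
    img = np.asarray(image, float)
    x, y = int(round(p[0])), int(round(p[1]))
    r = state.patch_radius
    h, w = state.remaining.shape
    valid = _valid_centers(state.remaining, r)
    if region is not None:
        yy, xx = np.nonzero(valid)
        keep = region.contains(xx, yy)
        valid = np.zeros_like(valid)
        valid[yy[keep], xx[keep]] = True
    cy, cx = np.nonzero(valid)
    if cy.size == 0:
        raise NoCandidatesError(f"no source patch available for ({x}, {y})")

    win = _window((y, x), r, (h, w))
    known = ~state.remaining
    offsets, targets = [], []
    for wy in range(win[0].start, win[0].stop):
        for wx in range(win[1].start, win[1].stop):
            if known[wy, wx]:
                offsets.append((wy - y, wx - x))
                targets.append(img[wy, wx, :])
    if not offsets:
        raise NoCandidatesError(f"patch around ({x}, {y}) has no known pixels")

    ssd = _ssd_at(img, (y, x), (cy, cx), offsets, targets)
    dist2 = (cy - y) ** 2 + (cx - x) ** 2
    order = np.lexsort((np.arange(cy.size), dist2, ssd))
    best = order[0]
    return int(cx[best]), int(cy[best])


def inpaint_image(image: np.ndarray, mask: np.ndarray,
                  params: Optional[InpaintParams] = None
                  ) -> Tuple[np.ndarray, IterationLog]:
    """Fill the masked region by exemplar-based patch copying.

    Returns the restored 8-bit image and an :class:`IterationLog`.  Pixels
    outside the mask are returned bit-identical to the input.
    """
    params = params or InpaintParams()
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3 or img.dtype != np.uint8:
        raise ValueError("image must be an 8-bit H x W x 3 raster")
    msk = np.asarray(mask, bool)
    if msk.shape != img.shape[:2]:
        raise ValueError("mask shape must match image shape")
    if msk.all():
        raise ValueError("mask covers the whole image; no source region")

    t0 = time.perf_counter()
    labels, ncomp = ndimage.label(msk, structure=np.ones((3, 3), int))
    log = IterationLog(marker_count=int(ncomp), mode=params.mode)
    work = img.astype(float)
    state = FillState.initial(msk, params.patch_radius)
    regions: dict = {}
    if params.mode == "improved":
        for cid in range(1, ncomp + 1):
            regions[cid] = elliptic_region(labels == cid, params.ellipse_margin)

    r = params.patch_radius
    area = (2 * r + 1) ** 2
    max_iter = int(msk.sum()) + 1
    for _ in range(max_iter):
        if not state.remaining.any():
            break
        front = extract_front(state.remaining)
        fy, fx = np.nonzero(front)
        lum = work @ _LUMA
        known = ~state.remaining
        grad_fields = _masked_gradient(lum, known)
        best_p, best_prio, best_craw = None, -np.inf, 0.0
        for yy, xx in zip(fy, fx):
            win = _window((yy, xx), r, msk.shape)
            c_raw = float(state.confidence[win].sum() / area)
            d = _data_term(lum, known, state, yy, xx, params.alpha, grad_fields)
            if params.mode == "improved":
                prio = float(np.exp(max(c_raw, params.k_thr) + d))
            else:
                prio = c_raw * d
            if prio > best_prio:
                best_p, best_prio, best_craw = (yy, xx), prio, c_raw
        assert best_p is not None
        py, px = best_p

        region = None
        if params.mode == "improved":
            cid = int(labels[py, px])
            region = regions.get(cid)
            if region is not None and np.isfinite(region.margin):
                # honour the minimum-candidate floor of the band
                valid = _valid_centers(state.remaining, r)
                vy, vx = np.nonzero(valid)
                if int(region.contains(vx, vy).sum()) < params.min_candidates:
                    region = None
                    log.fallback_count += 1
        try:
            qx, qy = match_patch(work, state, (px, py), region)
        except NoCandidatesError:
            if region is not None:
                log.fallback_count += 1
                qx, qy = match_patch(work, state, (px, py), None)
            else:
                raise

        win = _window((py, px), r, msk.shape)
        sub_rem = state.remaining[win]
        n_fill = int(sub_rem.sum())
        oy, ox = win[0].start - py, win[1].start - px
        src = work[qy + oy:qy + oy + sub_rem.shape[0],
                   qx + ox:qx + ox + sub_rem.shape[1], :]
        target = work[win[0], win[1], :]
        target[sub_rem] = src[sub_rem]
        conf = state.confidence[win]
        conf[sub_rem] = min(best_craw, 1.0)
        state.remaining[win] = False
        log.fills.append(((int(px), int(py)), (int(qx), int(qy)), n_fill))
    else:
        if state.remaining.any():
            raise RuntimeError(
                f"fill did not converge; {int(state.remaining.sum())} pixels remain")

    log.elapsed_seconds = time.perf_counter() - t0
    restored = np.clip(np.rint(work), 0, 255).astype(np.uint8)
    restored[~msk] = img[~msk]
    return restored, log
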