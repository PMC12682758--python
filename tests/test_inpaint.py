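"""Exemplar inpainting: fill front, priorities, elliptic search, matching,
and the full fill loop."""

import numpy as np
import pytest
from scipy import ndimage

from acukit import fixtures, inpaint
from acukit.inpaint import (
    EllipseRegion,
    FillState,
    InpaintParams,
    NoCandidatesError,
    elliptic_region,
    extract_front,
    fill_mask,
    inpaint_image,
    match_patch,
    priority_terms,
)

from conftest import small_spec


def _rand_image(rng, h, w):
    return rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8)


class TestExtractFront:
    def test_empty_region(self):
        assert extract_front(np.zeros((10, 10), bool)).sum() == 0

    def test_single_pixel(self):
        rem = np.zeros((10, 10), bool)
        rem[4, 5] = True
        front = extract_front(rem)
        assert front[4, 5] and front.sum() == 1

    def test_solid_block_border(self):
        """3x3 block: front = the 8 border pixels (enumerated oracle)."""
        rem = np.zeros((20, 20), bool)
        rem[8:11, 8:11] = True
        front = extract_front(rem)
        oracle = np.zeros_like(rem)
        for y, x in zip(*np.nonzero(rem)):
            for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ny, nx = y + dy, x + dx
                if 0 <= ny < 20 and 0 <= nx < 20 and not rem[ny, nx]:
                    oracle[y, x] = True
        assert np.array_equal(front, oracle)
        assert front.sum() == 8 and not front[9, 9]


class TestPriorityTerms:
    def _state_with_corner_known(self, h=32, w=32, radius=4, known_cols=1):
        rem = np.ones((h, w), bool)
        rem[:, :known_cols] = False  # known strip on the left
        return FillState.initial(rem, radius)

    def test_floor_applies_in_improved_mode(self):
        """Patch confidence far below k_thr (9 known of 81 patch pixels =
        0.111) floors to k_thr; with a constant image D = 0, so
        P = exp(k_thr)."""
        state = self._state_with_corner_known()
        img = np.full((32, 32, 3), 128, np.uint8)
        p = (1, 16)  # on the front, patch holds few known pixels
        params = InpaintParams(mode="improved", k_thr=0.2)
        c, d, prio = priority_terms(img, state, p, params)
        assert c == pytest.approx(0.2)
        assert d == 0.0
        assert prio == pytest.approx(np.exp(0.2), abs=1e-12)

    def test_baseline_product_can_vanish(self):
        state = self._state_with_corner_known()
        img = np.full((32, 32, 3), 128, np.uint8)
        params = InpaintParams(mode="baseline")
        c, d, prio = priority_terms(img, state, (1, 16), params)
        assert d == 0.0 and prio == 0.0
        assert c < 0.2  # raw, unfloored

    def test_constant_image_zero_data_term_everywhere(self):
        state = self._state_with_corner_known()
        img = np.full((32, 32, 3), 77, np.uint8)
        front = state.front
        for y, x in zip(*np.nonzero(front)):
            _, d, _ = priority_terms(img, state, (x, y), InpaintParams())
            assert d == 0.0

    def test_off_front_pixel_rejected(self):
        state = self._state_with_corner_known()
        img = np.full((32, 32, 3), 0, np.uint8)
        with pytest.raises(ValueError):
            priority_terms(img, state, (0, 0), InpaintParams())


class TestEllipticRegion:
    def test_disc_axes_match_radius(self):
        """Moment ellipse of a rasterized disc: both half-axes ~ r
        (brute-force moments of the pixel set)."""
        r = 10
        yy, xx = np.mgrid[0:64, 0:64]
        comp = (yy - 32) ** 2 + (xx - 32) ** 2 <= r ** 2
        region = elliptic_region(comp, margin=2.0)
        assert region.axes[0] == pytest.approx(r, rel=0.08)
        assert region.axes[1] == pytest.approx(r, rel=0.08)
        assert region.center[0] == pytest.approx(32.0, abs=0.01)

    def test_margin_one_band_nearly_empty(self):
        r = 10
        yy, xx = np.mgrid[0:64, 0:64]
        comp = (yy - 32) ** 2 + (xx - 32) ** 2 <= r ** 2
        band1 = elliptic_region(comp, margin=1.0).band()
        band25 = elliptic_region(comp, margin=2.5).band()
        assert band1.sum() <= 0.15 * comp.sum()
        assert band25.sum() > 5 * band1.sum()

    def test_quadrants_partition_band(self):
        """Quadrants are pairwise disjoint and union to the band (set
        algebra on pixel masks)."""
        yy, xx = np.mgrid[0:48, 0:48]
        comp = ((yy - 24) / 6.0) ** 2 + ((xx - 20) / 9.0) ** 2 <= 1.0
        region = elliptic_region(comp, margin=2.0)
        quads = region.quadrant_masks()
        union = np.zeros_like(comp)
        total = 0
        for q in quads:
            assert not np.any(union & q)  # disjoint
            union |= q
            total += q.sum()
        assert np.array_equal(union, region.band())
        assert total == region.band().sum()

    def test_empty_component_rejected(self):
        with pytest.raises(ValueError):
            elliptic_region(np.zeros((8, 8), bool))


class TestMatchPatch:
    def test_exact_duplicate_found(self, rng):
        img = _rand_image(rng, 24, 24)
        # duplicate the neighbourhood of (6, 6) at (16, 16)
        img[12:21, 12:21] = img[2:11, 2:11]
        rem = np.zeros((24, 24), bool)
        rem[6, 6] = True
        state = FillState.initial(rem, 2)
        q = match_patch(img, state, (6, 6))
        ssd = ((img[14:19, 14:19].astype(float)
                - img[4:9, 4:9].astype(float)) ** 2).sum()
        assert ssd == 0.0
        assert q == (16, 16)

    def test_tie_break_prefers_nearer(self):
        img = np.zeros((30, 30, 3), np.uint8)  # all candidates SSD 0
        rem = np.zeros((30, 30), bool)
        rem[14, 14] = True
        state = FillState.initial(rem, 2)
        q = match_patch(img, state, (14, 14))
        # nearest valid center: patch must avoid the remaining pixel
        dist = np.hypot(q[0] - 14, q[1] - 14)
        assert dist <= np.hypot(5, 0) + 1e-9

    def test_matches_exhaustive_ssd_oracle(self, rng):
        """On a 20x20 toy image the matcher equals a brute-force SSD scan
        with the same tie-breaks at every front pixel."""
        img = _rand_image(rng, 20, 20)
        rem = np.zeros((20, 20), bool)
        rem[8:13, 9:14] = True
        state = FillState.initial(rem, 1)
        r = 1
        front = extract_front(rem)
        for py, px in zip(*np.nonzero(front)):
            got = match_patch(img, state, (px, py))
            best = None
            for cy in range(r, 20 - r):
                for cx in range(r, 20 - r):
                    if rem[cy - r:cy + r + 1, cx - r:cx + r + 1].any():
                        continue
                    ssd = 0.0
                    for dy in range(-r, r + 1):
                        for dx in range(-r, r + 1):
                            ty, tx = py + dy, px + dx
                            if 0 <= ty < 20 and 0 <= tx < 20 and not rem[ty, tx]:
                                diff = (img[cy + dy, cx + dx].astype(float)
                                        - img[ty, tx].astype(float))
                                ssd += float((diff ** 2).sum())
                    key = (ssd, (cy - py) ** 2 + (cx - px) ** 2, cy, cx)
                    if best is None or key < best[0]:
                        best = (key, (cx, cy))
            assert got == best[1], f"mismatch at front pixel ({px}, {py})"

    def test_no_candidates_signalled(self):
        img = np.zeros((9, 9, 3), np.uint8)
        rem = np.ones((9, 9), bool)
        rem[0, 0] = False
        state = FillState.initial(rem, 2)
        with pytest.raises(NoCandidatesError):
            match_patch(img, state, (1, 0))


class TestInpaintImage:
    def test_empty_mask_is_identity(self, rng):
        img = _rand_image(rng, 16, 16)
        out, log = inpaint_image(img, np.zeros((16, 16), bool))
        assert np.array_equal(out, img)
        assert log.iterations == 0

    def test_outside_mask_untouched_and_terminates(self, small_image):
        mask = fill_mask(small_image.marker_mask)
        for mode in ("baseline", "improved"):
            out, log = inpaint_image(small_image.pixels, mask,
                                     InpaintParams(mode=mode))
            assert out.dtype == np.uint8
            assert np.array_equal(out[~mask], small_image.pixels[~mask])
            assert log.iterations <= int(mask.sum())
            assert all(n > 0 for _, _, n in log.fills)  # strict shrinkage
            assert log.marker_count == 5

    def test_full_mask_rejected(self):
        img = np.zeros((8, 8, 3), np.uint8)
        with pytest.raises(ValueError):
            inpaint_image(img, np.ones((8, 8), bool))

    def test_improved_priority_strictly_positive(self):
        """The exponential-sum priority never vanishes, unlike the product
        form that collapses once confidence or isophote strength hits 0."""
        rem = np.ones((32, 32), bool)
        rem[:, :2] = False
        state = FillState.initial(rem, 4)
        img = np.full((32, 32, 3), 100, np.uint8)
        front = state.front
        for y, x in zip(*np.nonzero(front)):
            _, _, p_imp = priority_terms(img, state, (x, y),
                                         InpaintParams(mode="improved"))
            _, _, p_base = priority_terms(img, state, (x, y),
                                          InpaintParams(mode="baseline"))
            assert p_imp > 0.0
            assert p_base == 0.0

    def test_unbounded_band_equals_whole_image_search(self, rng):
        """Limit equivalence: improved mode with an infinite search band
        reproduces the fill order and output of an exhaustive whole-image
        search under the same exponential priority."""
        spec = fixtures.FixtureSpec(
            width=48, height=48, marker_radius=4, seed=6,
            keypoint_positions={"A": (14.0, 14.0), "B": (32.0, 30.0)})
        img = fixtures.make_back_image(spec)
        mask = fill_mask(img.marker_mask)
        unbounded = InpaintParams(mode="improved", ellipse_margin=np.inf,
                                  min_candidates=0)
        # min_candidates larger than the image forces the whole-image
        # fallback on every iteration: an exhaustive-search reference run
        whole = InpaintParams(mode="improved", min_candidates=10 ** 9)
        out_a, log_a = inpaint_image(img.pixels, mask, unbounded)
        out_b, log_b = inpaint_image(img.pixels, mask, whole)
        assert log_a.fill_order() == log_b.fill_order()
        assert np.array_equal(out_a, out_b)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            InpaintParams(patch_radius=0)
        with pytest.raises(ValueError):
            InpaintParams(k_thr=1.5)
        with pytest.raises(ValueError):
            InpaintParams(mode="fancy")
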