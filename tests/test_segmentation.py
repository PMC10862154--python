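"""Cortical masking and triangle-method thresholding."""

import numpy as np
import pytest

from canalmorph.image_io import ContourSet, Microradiograph
from canalmorph.segmentation import (
    binarize_pores,
    cortical_mask,
    masked_histogram,
    threshold_section,
    triangle_threshold,
)


def oracle_triangle(hist):
    """Exhaustive perpendicular-distance oracle for the Zack construction.

    Scalar re-derivation: normalise both axes to [0, 1], take the line from
    the peak to the farthest nonzero bin on the longer-tail side, and scan
    every bin between them with the point-to-line distance formula.
    """
    hist = np.asarray(hist, float)
    nz = np.nonzero(hist)[0]
    if len(nz) == 1:
        return int(nz[0])
    peak = int(np.argmax(hist))
    lo, hi = int(nz[0]), int(nz[-1])
    if peak - lo > hi - peak:
        ext = lo
    elif hi - peak > peak - lo:
        ext = hi
    else:
        ext = lo if hist[lo:peak].sum() <= hist[peak + 1:hi + 1].sum() else hi
    if ext == peak:
        return peak
    ymax = hist[peak]
    x1, y1 = peak / 255.0, 1.0
    x2, y2 = ext / 255.0, hist[ext] / ymax
    best_bin, best_d = None, -1.0
    for b in range(min(peak, ext), max(peak, ext) + 1):
        px, py = b / 255.0, hist[b] / ymax
        num = abs((y2 - y1) * px - (x2 - x1) * py + x2 * y1 - y2 * x1)
        d = num / np.hypot(x2 - x1, y2 - y1)
        if d > best_d + 1e-15 or (abs(d - best_d) <= 1e-15
                                  and abs(b - peak) < abs(best_bin - peak)):
            best_bin, best_d = b, d
    return best_bin


class TestCorticalMask:
    def test_square_annulus_exact_area(self, square_annulus_contours):
        m = cortical_mask(square_annulus_contours, (120, 120), 100.0)
        # 10000 - 400 pixels at 0.01 mm^2 each
        assert m.area_mm2 == pytest.approx(96.0)
        assert m.pixel_count == 9600

    def test_circle_annulus_matches_pixel_counting_oracle(
            self, circle_annulus_contours):
        m = cortical_mask(circle_annulus_contours, (441, 441), 10.0)
        expected = np.pi * (200**2 - 100**2)
        assert abs(m.pixel_count - expected) / expected < 0.01
        # brute-force point-in-circle scan
        yy, xx = np.mgrid[0:441, 0:441]
        rho2 = (xx - 220.0) ** 2 + (yy - 220.0) ** 2
        brute = (rho2 <= 200**2) & ~(rho2 <= 100**2)
        agree = (m.mask == brute).mean()
        assert agree > 0.999  # differ only on polygon-vs-circle edge pixels

    def test_no_endosteal_polygon_full_interior(self):
        cs = ContourSet(periosteal=[[0, 0], [50, 0], [50, 50], [0, 50]])
        m = cortical_mask(cs, (60, 60), 10.0)
        assert m.pixel_count == 2500

    def test_translation_invariance_of_ct_ar(self, square_annulus_contours):
        m0 = cortical_mask(square_annulus_contours, (120, 120), 100.0)
        shifted = ContourSet(
            periosteal=square_annulus_contours.periosteal + [7, 11],
            endosteal=[square_annulus_contours.endosteal[0] + [7, 11]])
        m1 = cortical_mask(shifted, (130, 130), 100.0)
        assert m1.area_mm2 == m0.area_mm2

    def test_polygon_outside_bounds_errors(self, square_annulus_contours):
        with pytest.raises(ValueError, match="outside"):
            cortical_mask(square_annulus_contours, (60, 60), 100.0)

    def test_centroid_inside_bounding_box(self, circle_annulus_contours):
        m = cortical_mask(circle_annulus_contours, (441, 441), 10.0)
        assert 0 <= m.centroid[0] <= 440 and 0 <= m.centroid[1] <= 440
        assert m.centroid == pytest.approx((220, 220), abs=1.0)


class TestTriangleThreshold:
    def test_single_nonzero_bin_fallback(self):
        h = np.zeros(256)
        h[77] = 10
        assert triangle_threshold(h) == 77

    def test_convex_decaying_tail_matches_oracle(self):
        b = np.arange(256)
        h = np.where(b <= 200, np.floor((b / 200.0) ** 3 * 1000), 0.0)
        assert triangle_threshold(h) == oracle_triangle(h)

    def test_mirrored_histogram_gives_mirrored_threshold(self):
        b = np.arange(256)
        h = np.where(b <= 200, np.floor((b / 200.0) ** 3 * 1000), 0.0)
        assert triangle_threshold(h[::-1].copy()) == 255 - triangle_threshold(h)

    def test_agrees_with_oracle_on_random_histograms(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            h = rng.integers(0, 50, 256).astype(float)
            peak = rng.integers(30, 226)
            h[peak] += 500  # unique, unambiguous peak
            assert triangle_threshold(h) == oracle_triangle(h)

    def test_close_to_reference_implementation_on_bimodal_histogram(self):
        # independent cross-check against scikit-image's triangle threshold
        from skimage.filters import threshold_triangle

        rng = np.random.default_rng(7)
        img = np.clip(rng.normal(180, 5, (200, 200)), 0, 255)
        img[:40] = np.clip(rng.normal(60, 5, (40, 200)), 0, 255)
        img = img.astype(np.uint8)
        ours = triangle_threshold(np.bincount(img.ravel(), minlength=256))
        ref = threshold_triangle(img, nbins=256)
        assert abs(ours - ref) <= 3

    def test_empty_histogram_errors(self):
        with pytest.raises(ValueError):
            triangle_threshold(np.zeros(256))


class TestBinarize:
    def _flat_section(self, value=200):
        cs = ContourSet(periosteal=[[0, 0], [50, 0], [50, 50], [0, 50]])
        micro = Microradiograph(np.full((60, 60), value, np.uint8), 10.0)
        return micro, cortical_mask(cs, (60, 60), 10.0)

    def test_all_bone_section_has_zero_pores(self):
        micro, cmask = self._flat_section()
        thr = threshold_section(micro, cmask)
        pores = binarize_pores(micro, cmask, thr.level, thr.side)
        assert not pores.any()

    def test_dark_disc_pixel_count_recovered(self):
        micro, cmask = self._flat_section()
        px = micro.pixels.copy()
        yy, xx = np.mgrid[0:60, 0:60]
        disc = (xx - 25) ** 2 + (yy - 25) ** 2 <= 8**2
        px[disc] = 40
        micro = Microradiograph(px, 10.0)
        thr = threshold_section(micro, cmask)
        pores = binarize_pores(micro, cmask, thr.level, thr.side)
        assert pores.sum() == disc.sum()

    def test_dark_pixels_outside_mask_stay_false(self):
        micro, cmask = self._flat_section()
        px = micro.pixels.copy()
        px[:, 55:] = 0  # dark strip outside the periosteal square
        px[10, 10] = 0  # one dark pixel inside, to give the histogram two bins
        micro = Microradiograph(px, 10.0)
        thr = threshold_section(micro, cmask)
        pores = binarize_pores(micro, cmask, thr.level, thr.side)
        assert pores[10, 10]
        assert not pores[:, 55:].any()

    def test_partition_of_masked_pixels(self):
        micro, cmask = self._flat_section()
        px = micro.pixels.copy()
        px[5:15, 5:15] = 30
        micro = Microradiograph(px, 10.0)
        thr = threshold_section(micro, cmask)
        pores = binarize_pores(micro, cmask, thr.level, thr.side)
        bone = cmask.mask & ~pores
        assert pores.sum() + bone.sum() == cmask.pixel_count

    def test_histogram_counts_sum_to_masked_pixels(self):
        micro, cmask = self._flat_section()
        hist = masked_histogram(micro, cmask)
        assert hist.sum() == cmask.pixel_count
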