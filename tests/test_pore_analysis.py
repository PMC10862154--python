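"""Pore labelling, measurement, retention filtering and classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canalmorph.image_io import ContourSet
from canalmorph.pore_analysis import (
    FilterConfig,
    PoreRecord,
    classify_canal,
    exclude_endosteal,
    filter_pores,
    label_pores,
    measure_pore,
)


def flood_fill_components(grid):
    """Independent 8-connected component oracle (explicit stack flood fill)."""
    grid = np.asarray(grid, bool)
    seen = np.zeros_like(grid)
    comps = []
    h, w = grid.shape
    for r0 in range(h):
        for c0 in range(w):
            if grid[r0, c0] and not seen[r0, c0]:
                stack, comp = [(r0, c0)], []
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    comp.append((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (0 <= rr < h and 0 <= cc < w and grid[rr, cc]
                                    and not seen[rr, cc]):
                                seen[rr, cc] = True
                                stack.append((rr, cc))
                comps.append(frozenset(comp))
    return comps


class TestLabelPores:
    def test_diagonal_touch_is_one_component(self):
        g = np.zeros((4, 4), bool)
        g[1, 1] = g[2, 2] = True
        assert len(label_pores(g)) == 1

    def test_empty_grid(self):
        assert label_pores(np.zeros((5, 5), bool)) == []

    def test_matches_flood_fill_oracle_on_random_grids(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            g = rng.random((40, 40)) < 0.25
            ours = [frozenset(map(tuple, c)) for c in label_pores(g)]
            oracle = flood_fill_components(g)
            assert set(ours) == set(oracle)

    def test_deterministic_raster_ordering(self):
        g = np.zeros((10, 10), bool)
        g[7, 1] = True
        g[2, 8] = True
        g[2, 2] = True
        comps = label_pores(g)
        firsts = [tuple(c[0]) for c in comps]
        assert firsts == [(2, 2), (2, 8), (7, 1)]


class TestMeasurePore:
    def test_single_pixel_area_definition(self):
        rec = measure_pore(np.array([[5, 5]]), 25.0)
        assert rec.area_mm2 == pytest.approx(6.25e-4)
        assert rec.circularity == 1.0  # degenerate chain, clipped

    def test_disc_area_and_circularity(self):
        yy, xx = np.mgrid[0:50, 0:50]
        disc = np.argwhere((xx - 25) ** 2 + (yy - 25) ** 2 <= 20**2)
        rec = measure_pore(disc, 10.0)
        true_area = np.pi * 0.2**2  # r = 200 um = 0.2 mm
        assert abs(rec.area_mm2 - true_area) / true_area < 0.02
        assert rec.circularity >= 0.85
        assert rec.centroid == pytest.approx((25, 25), abs=0.1)

    def test_thin_line_circularity_below_retention(self):
        line = np.column_stack([np.full(50, 3), np.arange(50)])
        rec = measure_pore(line, 10.0)
        # chain runs down one side and back: 2*(50-1) unit steps
        assert rec.perimeter_um == pytest.approx(98 * 10.0)
        assert rec.circularity < 0.3
        assert rec.feret_um == pytest.approx(490.0)

    def test_interior_hole_filled_before_measurement(self):
        ring = np.zeros((9, 9), bool)
        ring[2:7, 2:7] = True
        ring[4, 4] = False  # central bone island
        rec = measure_pore(np.argwhere(ring), 10.0)
        assert rec.n_px == 25  # full lumen, hole filled

    def test_eq_diameter_consistent_with_area(self):
        rec = measure_pore(np.array([[0, 0], [0, 1], [1, 0], [1, 1]]), 25.0)
        assert rec.eq_diameter_um == pytest.approx(
            2000 * np.sqrt(rec.area_mm2 / np.pi))


from conftest import make_pore_record as _record  # noqa: E402


class TestFilterPores:
    def test_small_area_excluded_as_mature(self):
        (rec,) = filter_pores([_record(0.001, circ=0.9)])
        assert rec.excluded_by == ("min_area",)

    def test_low_circularity_excluded(self):
        (rec,) = filter_pores([_record(0.01, circ=0.2)])
        assert rec.excluded_by == ("circularity",)

    def test_boundary_area_is_strictly_excluded(self):
        (rec,) = filter_pores([_record(0.002, circ=0.9)])
        assert rec.excluded_by == ("min_area",)

    def test_retained_record_has_no_flags(self):
        (rec,) = filter_pores([_record(0.01, circ=0.9)])
        assert rec.retained

    def test_idempotent_and_preserves_measurements(self):
        recs = [_record(0.001), _record(0.01, circ=0.2), _record(0.01)]
        once = filter_pores(recs)
        twice = filter_pores(once)
        assert [r.excluded_by for r in once] == [r.excluded_by for r in twice]
        assert [r.area_mm2 for r in once] == [r.area_mm2 for r in recs]


class TestClassifyCanal:
    @pytest.mark.parametrize("area,expected", [
        (0.05, "cutting_cone"),
        (0.01, "closing_cone"),
        (0.0015, "mature"),
        (0.002, "mature"),        # inclusive upper bound of mature
        (0.04, "closing_cone"),   # inclusive upper bound of closing cone
        (0.040001, "cutting_cone"),
    ])
    def test_stage_boundaries(self, area, expected):
        assert classify_canal(area) == expected

    def test_non_positive_area_errors(self):
        with pytest.raises(ValueError):
            classify_canal(0.0)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(min_value=1e-9, max_value=10.0,
                     allow_nan=False, allow_infinity=False))
    def test_partition_every_positive_area_has_one_class(self, area):
        assert classify_canal(area) in ("mature", "closing_cone", "cutting_cone")


class TestExcludeEndosteal:
    @pytest.fixture
    def contours(self):
        return ContourSet(
            periosteal=[[0, 0], [400, 0], [400, 400], [0, 400]],
            endosteal=[[[150, 150], [250, 150], [250, 250], [150, 250]]],
        )

    def _touching_record(self, feret_um, rid=0):
        # boundary pixels adjacent to the endosteal contour at x=150
        boundary = np.array([[200, 148], [201, 148], [202, 148]])
        rec = _record(0.5, feret_um=feret_um, rid=rid, centroid=(140.0, 200.0))
        rec.boundary_px = boundary
        return rec

    def _far_record(self, feret_um, rid=1):
        boundary = np.array([[30, 30], [30, 31]])
        rec = _record(0.5, feret_um=feret_um, rid=rid, centroid=(30.0, 30.0))
        rec.boundary_px = boundary
        return rec

    def test_wide_pore_touching_contour_excluded(self, contours):
        (rec,) = exclude_endosteal([self._touching_record(700.0)], contours)
        assert "endosteal" in rec.excluded_by

    def test_wide_pore_far_from_contour_retained(self, contours):
        (rec,) = exclude_endosteal([self._far_record(700.0)], contours)
        assert "endosteal" not in rec.excluded_by

    def test_narrow_pore_at_contour_retained(self, contours):
        (rec,) = exclude_endosteal([self._touching_record(100.0)], contours)
        assert "endosteal" not in rec.excluded_by

    def test_manual_id_list_and_additivity(self, contours):
        rec = self._far_record(100.0, rid=9)
        rec = filter_pores([rec])[0]
        (out,) = exclude_endosteal([rec], contours, manual_ids={9})
        assert "endosteal" in out.excluded_by
        assert out.area_mm2 == rec.area_mm2  # flags never change measurements


class TestFilterConfig:
    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            FilterConfig(circ_min=0.5, circ_max=0.3)
        with pytest.raises(ValueError):
            FilterConfig(area_min_mm2=0.05, cutting_min_mm2=0.04)
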