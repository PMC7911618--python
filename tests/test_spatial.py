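"""Classification, areas, range change, centroids, MESS."""

import numpy as np
import pytest

from geomaxent import (
    AreaSummary,
    GridSpec,
    RasterLayer,
    RasterStack,
    area_summary,
    binarize,
    cell_area_km2,
    centroid,
    centroid_shift,
    classify,
    mean_mess_at_points,
    mess,
    percent_change,
    range_change,
)
from geomaxent.spatial import EARTH_RADIUS_KM, ClassifiedMap, haversine_km


def layer_of(values, spec=None):
    values = np.asarray(values, dtype=float)
    spec = spec or GridSpec(values.shape[0], values.shape[1], 100.0, 20.0, 0.5)
    return RasterLayer("x", spec, values)


class TestClassify:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.05, 0), (0.1, 1), (0.25, 1), (0.3, 2), (0.59, 2), (0.6, 3), (1.0, 3)],
    )
    def test_threshold_bins_lower_closed(self, p, expected):
        cm = classify(layer_of([[p]]))
        assert cm.layer.values[0, 0] == expected

    def test_values_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="lie in"):
            classify(layer_of([[1.2]]))

    def test_nodata_preserved(self):
        cm = classify(layer_of([[0.5, np.nan]]))
        assert np.isnan(cm.layer.values[0, 1])


class TestCellArea:
    def test_half_degree_equator_cell(self):
        spec = GridSpec(2, 2, 0.0, -0.5, 0.5)  # row 0 spans 0..0.5 N
        # cell centered on the equator: rows straddle it; use row covering 0..0.5
        area = float(cell_area_km2(spec, 0))
        # independent spherical evaluation for a cell touching the equator
        lam = np.deg2rad(0.5)
        expect = EARTH_RADIUS_KM**2 * lam * (np.sin(np.deg2rad(0.5)) - 0.0)
        assert area == pytest.approx(expect)
        assert area == pytest.approx(3091.1, abs=0.5)

    def test_area_decreases_toward_poles(self):
        spec = GridSpec(180, 1, 0.0, -90.0, 1.0)
        areas = np.asarray(cell_area_km2(spec, np.arange(180)))
        equator_rows = (89, 90)
        assert areas.argmax() in equator_rows
        north = areas[:90]
        assert np.all(np.diff(north) > 0)  # increasing from pole to equator

    def test_global_grid_sums_to_sphere_area(self):
        spec = GridSpec(180, 360, -180.0, -90.0, 1.0)
        rows = np.asarray(cell_area_km2(spec, np.arange(180)))
        total = (rows * 360).sum()
        sphere = 4 * np.pi * EARTH_RADIUS_KM**2
        assert abs(total - sphere) / sphere < 1e-4


class TestAreaSummary:
    def test_all_unsuitable_is_zero(self):
        s = area_summary(classify(layer_of(np.zeros((3, 4)))))
        assert s.total == 0.0

    def test_single_high_cell_area(self):
        vals = np.zeros((3, 4))
        vals[1, 2] = 0.9
        spec = GridSpec(3, 4, 100.0, 20.0, 0.5)
        s = area_summary(classify(layer_of(vals, spec)))
        assert s.highly == pytest.approx(float(cell_area_km2(spec, 1)) / 1e4)
        assert s.moderately == 0.0 and s.poorly == 0.0

    def test_binary_area_equals_summary_total(self, truth):
        cm = classify(truth)
        s = area_summary(cm)
        mask = binarize(cm, min_class=1)
        from geomaxent.spatial import _mask_area_1e4km2

        assert _mask_area_1e4km2(mask, truth.spec) == pytest.approx(s.total)


class TestPercentChange:
    def test_published_area_table_percentages(self):
        current = AreaSummary("current", highly=3.96, moderately=10.59, poorly=29.36)
        future = AreaSummary("2030-low", highly=5.44, moderately=14.75, poorly=43.43)
        tab = percent_change(current, future).set_index("class")
        assert tab.percent_change["total"] == 44.89
        assert tab.percent_change["highly"] == 37.37
        assert tab.percent_change["moderately"] == 39.28
        assert tab.percent_change["poorly"] == 47.92

    def test_decline_reported_negative(self):
        current = AreaSummary("c", 3.96, 10.59, 29.36)
        future = AreaSummary("f", 3.75, 16.75, 51.28)
        tab = percent_change(current, future).set_index("class")
        assert tab.percent_change["highly"] == -5.30

    def test_equal_areas_zero_change(self):
        a = AreaSummary("a", 1.0, 2.0, 3.0)
        tab = percent_change(a, AreaSummary("b", 1.0, 2.0, 3.0))
        assert (tab.percent_change == 0).all()

    def test_zero_current_class_reports_absolute_only(self):
        a = AreaSummary("a", 0.0, 2.0, 3.0)
        tab = percent_change(a, AreaSummary("b", 1.5, 2.0, 3.0)).set_index("class")
        assert np.isnan(tab.percent_change["highly"])
        assert tab.absolute_change["highly"] == 1.5


class TestRangeChange:
    def test_identical_masks(self, small_spec):
        mask = np.zeros(small_spec.shape, dtype=bool)
        mask[1:3, 1:4] = True
        rc = range_change(mask, mask, small_spec)
        assert rc.gain_area == 0.0 and rc.loss_area == 0.0
        assert rc.unchanged_area == pytest.approx(rc.current_area)

    def test_disjoint_masks_no_stable_area(self, small_spec):
        a = np.zeros(small_spec.shape, dtype=bool)
        b = np.zeros(small_spec.shape, dtype=bool)
        a[0, :2] = True
        b[3, 3:] = True
        rc = range_change(a, b, small_spec)
        assert rc.unchanged_area == 0.0

    def test_random_masks_match_brute_force_and_identities(self):
        spec = GridSpec(20, 20, 100.0, 20.0, 0.1)
        rng = np.random.default_rng(0)
        from geomaxent.spatial import _mask_area_1e4km2

        for _ in range(20):
            cur = rng.uniform(size=spec.shape) < 0.4
            fut = rng.uniform(size=spec.shape) < 0.4
            rc = range_change(cur, fut, spec)
            # brute-force per-cell masks
            gain = np.array(
                [[fut[i, j] and not cur[i, j] for j in range(20)] for i in range(20)]
            )
            np.testing.assert_array_equal(rc.gain_mask, gain)
            # cell-exact area identities
            assert rc.unchanged_area + rc.loss_area == pytest.approx(
                _mask_area_1e4km2(cur, spec)
            )
            assert rc.unchanged_area + rc.gain_area == pytest.approx(
                _mask_area_1e4km2(fut, spec)
            )

    def test_misaligned_masks_rejected(self, small_spec):
        with pytest.raises(ValueError):
            range_change(
                np.zeros((2, 2), dtype=bool), np.zeros((2, 2), dtype=bool), small_spec
            )


class TestCentroid:
    def test_symmetric_mask_centered(self):
        spec = GridSpec(4, 4, 0.0, 0.0, 0.25)
        mask = np.ones((4, 4), dtype=bool)
        lon, lat = centroid(mask, spec)
        assert lon == pytest.approx(0.5)
        # area weighting pulls latitude slightly toward the equatorward rows
        assert lat == pytest.approx(0.5, abs=0.001)

    def test_identical_masks_zero_shift(self, small_spec):
        mask = np.zeros(small_spec.shape, dtype=bool)
        mask[1, 1] = True
        c = centroid(mask, small_spec)
        shift = centroid_shift(c, c)
        assert shift.distance_km == 0.0 and shift.delta_lat == 0.0

    def test_one_degree_latitude_haversine(self):
        spec = GridSpec(3, 1, 10.0, 20.0, 1.0)
        a = np.array([[0], [0], [1]], dtype=bool)  # row 2: lat 20.5
        b = np.array([[0], [1], [0]], dtype=bool)  # row 1: lat 21.5
        shift = centroid_shift(centroid(a, spec), centroid(b, spec))
        assert shift.delta_lat == pytest.approx(1.0)
        assert shift.distance_km == pytest.approx(111.19, abs=0.01)

    def test_empty_mask_rejected(self, small_spec):
        with pytest.raises(ValueError, match="empty"):
            centroid(np.zeros(small_spec.shape, dtype=bool), small_spec)


class TestMess:
    @pytest.fixture
    def reference(self):
        # 8 reference values per variable; medians are 4.5 and 45
        return {
            "a": np.arange(1.0, 9.0),
            "b": np.arange(10.0, 90.0, 10.0),
        }

    def mess_value(self, reference, a_val, b_val):
        spec = GridSpec(1, 1, 0.0, 0.0, 1.0)
        stack = RasterStack(
            [RasterLayer("a", spec, [[a_val]]), RasterLayer("b", spec, [[b_val]])]
        )
        return mess(reference, stack).similarity.values[0, 0]

    def test_multivariate_median_scores_100(self, reference):
        assert self.mess_value(reference, 4.5, 45.0) == pytest.approx(100.0)

    def test_below_reference_minimum_negative(self, reference):
        assert self.mess_value(reference, 0.5, 45.0) < 0

    def test_above_reference_maximum_negative(self, reference):
        assert self.mess_value(reference, 4.5, 95.0) < 0

    def test_quartile_value_scores_50(self, reference):
        # a = 2.5: exactly 2 of 8 reference values strictly below -> f = 25 -> S = 50
        assert self.mess_value(reference, 2.5, 45.0) == pytest.approx(50.0)

    def test_similarity_never_exceeds_100(self, reference, environment):
        ref = {
            "temp1": np.sort(environment["temp1"].values.ravel()[::7]),
            "precip1": np.sort(environment["precip1"].values.ravel()[::7]),
        }
        mm = mess(ref, environment)
        vals = mm.similarity.values[np.isfinite(mm.similarity.values)]
        assert vals.max() <= 100.0

    def test_negative_exactly_on_extrapolation_cells(self, environment):
        sub = environment.subset(["temp1", "precip1"])
        X, rows, cols = sub.cell_table()
        ref = {"temp1": X[::5, 0], "precip1": X[::5, 1]}
        mm = mess(ref, sub)
        s = mm.similarity.values[rows, cols]
        outside = (
            (X[:, 0] < ref["temp1"].min())
            | (X[:, 0] > ref["temp1"].max())
            | (X[:, 1] < ref["precip1"].min())
            | (X[:, 1] > ref["precip1"].max())
        )
        np.testing.assert_array_equal(s < 0, outside)

    def test_invariant_to_reference_reordering(self, reference):
        shuffled = {k: v[::-1].copy() for k, v in reference.items()}
        assert self.mess_value(reference, 3.3, 37.0) == self.mess_value(
            shuffled, 3.3, 37.0
        )

    def test_constant_reference_variable_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            self.mess_value({"a": np.ones(5), "b": np.arange(5.0)}, 1.0, 2.0)

    def test_most_dissimilar_variable_recorded(self, reference):
        spec = GridSpec(1, 1, 0.0, 0.0, 1.0)
        stack = RasterStack(
            [RasterLayer("a", spec, [[4.5]]), RasterLayer("b", spec, [[95.0]])]
        )
        mm = mess(reference, stack)
        assert mm.most_dissimilar[0, 0] == "b"


class TestMeanMessAtPoints:
    def test_single_point_reads_its_cell(self, small_spec):
        vals = np.arange(20.0).reshape(4, 5)
        from geomaxent.spatial import MESSMap

        mm = MESSMap(layer_of(vals, small_spec), np.full((4, 5), None))
        lon, lat = small_spec.cell_center(2, 3)
        assert mean_mess_at_points(mm, [(lon, lat)]) == vals[2, 3]

    def test_mean_of_constant_map_is_constant(self, small_spec):
        from geomaxent.spatial import MESSMap

        mm = MESSMap(layer_of(np.full((4, 5), 7.5), small_spec), np.full((4, 5), None))
        pts = [small_spec.cell_center(i, i) for i in range(3)]
        assert mean_mess_at_points(mm, pts) == pytest.approx(7.5)

    def test_matches_brute_force_lookup(self, small_spec):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(4, 5))
        from geomaxent.spatial import MESSMap

        mm = MESSMap(layer_of(vals, small_spec), np.full((4, 5), None))
        pts = np.column_stack(
            [rng.uniform(100.0, 102.5, 30), rng.uniform(20.0, 22.0, 30)]
        )
        expect = []
        for lon, lat in pts:
            r, c, inside = small_spec.locate([lon], [lat])
            if inside[0]:
                expect.append(vals[r[0], c[0]])
        assert mean_mess_at_points(mm, pts) == pytest.approx(np.mean(expect))

    def test_all_points_invalid_rejected(self, small_spec):
        from geomaxent.spatial import MESSMap

        mm = MESSMap(layer_of(np.zeros((4, 5)), small_spec), np.full((4, 5), None))
        with pytest.raises(ValueError):
            mean_mess_at_points(mm, [(0.0, 0.0)])
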