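"""Factor detector: natural breaks, q-statistic, fishnet, screening."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from geomaxent import (
    GridSpec,
    OccurrenceSet,
    build_fishnet,
    factor_q,
    jenks_breaks,
    presence_response,
    q_significance,
    screen_variables,
    stratify,
)
from geomaxent.geodetector import KM_PER_DEGREE, DegenerateVarianceError


# ---------------------------------------------------------------------------
# oracles

def jenks_cost_oracle(values, L):
    """Minimal within-class SSD over all contiguous partitions, by enumeration."""
    vals = np.sort(np.asarray(values, dtype=float))
    n = len(vals)

    def ssd(seg):
        return ((seg - seg.mean()) ** 2).sum()

    best = np.inf
    best_parts = None
    for cuts in itertools.combinations(range(1, n), L - 1):
        bounds = (0, *cuts, n)
        cost = sum(ssd(vals[bounds[i] : bounds[i + 1]]) for i in range(L))
        if cost < best - 1e-12:
            best = cost
            best_parts = bounds
    return best, best_parts


def grouped_variance_q(y, h):
    """Brute-force q via per-group population variances."""
    y = np.asarray(y, dtype=float)
    h = np.asarray(h)
    sst = len(y) * y.var()
    ssw = sum(len(y[h == g]) * y[h == g].var() for g in np.unique(h))
    return 1 - ssw / sst


def assigned_cost(values, breaks):
    vals = np.asarray(values, dtype=float)
    a = stratify(vals, breaks).assignment
    return sum(
        ((vals[a == g] - vals[a == g].mean()) ** 2).sum() for g in np.unique(a)
    )


# ---------------------------------------------------------------------------

class TestJenksBreaks:
    def test_obvious_two_cluster_split(self):
        breaks = jenks_breaks([1, 2, 10, 11], 2)
        np.testing.assert_array_equal(stratify([1, 2, 10, 11], breaks).assignment, [1, 1, 2, 2])

    def test_single_class_has_no_breaks(self):
        assert jenks_breaks([3, 1, 2], 1).size == 0

    def test_fewer_distinct_values_than_classes_errors(self):
        with pytest.raises(ValueError, match="distinct"):
            jenks_breaks([1.0, 1.0, 2.0], 3)

    @pytest.mark.parametrize("n,L", [(6, 2), (9, 3), (12, 4)])
    def test_matches_exhaustive_partition_enumeration(self, n, L):
        rng = np.random.default_rng(n * 100 + L)
        for _ in range(30):
            vals = rng.normal(size=n) * rng.uniform(0.5, 20)
            best, _ = jenks_cost_oracle(vals, L)
            got = assigned_cost(vals, jenks_breaks(vals, L))
            assert got == pytest.approx(best, abs=1e-9)

    def test_tied_values_share_a_stratum(self):
        rng = np.random.default_rng(3)
        vals = rng.integers(0, 6, size=60).astype(float)  # heavy ties
        strata = stratify(vals, jenks_breaks(vals, 4)).assignment
        for v in np.unique(vals):
            assert len(np.unique(strata[vals == v])) == 1


class TestStratify:
    def test_strict_lower_closed_boundary_rule(self):
        np.testing.assert_array_equal(
            stratify([1, 5, 9], [5]).assignment, [1, 2, 2]
        )

    def test_no_breaks_single_stratum(self):
        assert set(stratify([1.0, 2.0], []).assignment) == {1}

    @given(st.lists(st.floats(-50, 50), min_size=8, max_size=40), st.integers(2, 4))
    @settings(max_examples=50, deadline=None)
    def test_equal_values_always_equal_strata(self, vals, L):
        vals = np.round(np.asarray(vals), 1)  # force ties
        if len(np.unique(vals)) < L:
            return
        a = stratify(vals, jenks_breaks(vals, L)).assignment
        for v in np.unique(vals):
            assert len(set(a[vals == v])) == 1


class TestFactorQ:
    def test_pure_strata_give_q_one(self):
        res = factor_q([1, 1, 5, 5, 9, 9], [1, 1, 2, 2, 3, 3])
        assert res.q == pytest.approx(1.0)
        assert res.ssw == pytest.approx(0.0)

    def test_single_stratum_gives_q_zero(self):
        assert factor_q([1.0, 2.0, 5.0], [1, 1, 1]).q == pytest.approx(0.0)

    def test_printed_worked_example(self):
        res = factor_q([0, 0, 1, 1, 1, 0], [1, 1, 1, 2, 2, 2])
        assert res.sst == pytest.approx(1.5)
        assert res.ssw == pytest.approx(4 / 3)
        assert res.q == pytest.approx(1 / 9)

    def test_constant_response_raises(self):
        with pytest.raises(DegenerateVarianceError):
            factor_q([2.0, 2.0, 2.0], [1, 1, 2])

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            n = rng.integers(4, 30)
            y = rng.normal(size=n)
            h = rng.integers(1, rng.integers(2, 6), size=n)
            assert factor_q(y, h).q == pytest.approx(
                np.clip(grouped_variance_q(y, h), 0, 1), abs=1e-10
            )

    def test_affine_invariance_of_q(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=40)
        h = rng.integers(1, 4, size=40)
        q0 = factor_q(y, h).q
        assert factor_q(3.5 * y - 7.0, h).q == pytest.approx(q0)

    def test_merging_strata_never_increases_q(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            y = rng.normal(size=30)
            h = rng.integers(1, 5, size=30)
            q_fine = factor_q(y, h).q
            merged = np.where(h == h.max(), 1, h)  # merge two strata
            assert factor_q(y, merged).q <= q_fine + 1e-10


class TestSignificance:
    def test_perfect_separation_attains_permutation_floor(self):
        y = np.repeat([0.0, 1.0], 10)
        h = np.repeat([1, 2], 10)
        p = q_significance(y, h, n_permutations=999, seed=0)
        assert p == pytest.approx(1 / 1000, abs=2e-3)

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(8)
        rejections = 0
        runs = 200
        for _ in range(runs):
            y = rng.normal(size=40)
            h = rng.integers(1, 5, size=40)
            if q_significance(y, h, n_permutations=99, seed=rng.integers(2**31)) <= 0.05:
                rejections += 1
        # ~5% nominal level; allow 3 binomial SEs
        assert rejections / runs < 0.05 + 3 * np.sqrt(0.05 * 0.95 / runs)

    def test_invariant_to_stratum_relabeling(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=30)
        h = rng.integers(1, 4, size=30)
        relabeled = np.choose(h - 1, [7, 2, 5])
        assert q_significance(y, h, 199, seed=3) == q_significance(
            y, relabeled, 199, seed=3
        )


class TestFishnet:
    def test_lattice_count_on_square_extent(self):
        # 100 km x 100 km extent at the equator, 10 km spacing -> 10 x 10 points
        side = 100 / KM_PER_DEGREE
        spec = GridSpec(10, 10, 0.0, -side / 2, side / 10)
        pts = build_fishnet(spec, 10.0)
        assert len(pts) == 100

    def test_spacing_equal_to_extent_single_point(self):
        side = 50 / KM_PER_DEGREE
        spec = GridSpec(5, 5, 0.0, -side / 2, side / 5)
        pts = build_fishnet(spec, 50.0)
        assert len(pts) == 1

    def test_spacing_beyond_extent_errors(self, small_spec):
        with pytest.raises(ValueError, match="spacing"):
            build_fishnet(small_spec, 1e5)

    def test_all_points_on_valid_cells(self, environment):
        mask = environment.valid_mask().copy()
        mask[:, ::3] = False
        pts = build_fishnet(environment.spec, 10.0, valid_mask=mask)
        row, col, inside = environment.spec.locate(pts[:, 0], pts[:, 1])
        assert inside.all()
        assert mask[row, col].all()


class TestPresenceResponse:
    def test_no_occurrences_all_zero(self, small_spec):
        pts = build_fishnet(small_spec, 30.0)
        y = presence_response(pts, OccurrenceSet("x", np.empty((0, 2))), small_spec, 30.0)
        assert not y.any()

    def test_occurrence_at_fishnet_point_marks_cell(self, small_spec):
        pts = build_fishnet(small_spec, 30.0)
        occ = OccurrenceSet("x", pts[3:4])
        y = presence_response(pts, occ, small_spec, 30.0)
        assert y[3] == 1 and y.sum() == 1

    def test_matches_brute_force_double_loop(self, small_spec):
        rng = np.random.default_rng(5)
        spec = small_spec
        pts = build_fishnet(spec, 25.0)
        occ_pts = np.column_stack(
            [rng.uniform(spec.x_ll, spec.x_ur, 40), rng.uniform(spec.y_ll, spec.y_ur, 40)]
        )
        y = presence_response(pts, OccurrenceSet("x", occ_pts), spec, 25.0, counts=True)
        dlat = 25.0 / KM_PER_DEGREE
        dlon = dlat / np.cos(np.deg2rad((spec.y_ll + spec.y_ur) / 2))
        for j, (px, py) in enumerate(pts):
            count = sum(
                1
                for ox, oy in occ_pts
                if -dlon / 2 <= ox - px < dlon / 2 and -dlat / 2 <= oy - py < dlat / 2
            )
            assert y[j] == count


class TestScreening:
    def test_threshold_is_strict_greater_than(self, environment, occurrences, monkeypatch):
        import geomaxent.geodetector as gdmod

        fake_q = iter([0.15, 0.05, 0.1])

        def fake_factor_q(y, sm, variable=None):
            from geomaxent.geodetector import FactorDetectionResult

            return FactorDetectionResult(
                variable=sm.variable, q=next(fake_q), N=len(y),
                n_h=np.array([len(y)]), var_h=np.array([0.0]),
                var_total=1.0, ssw=0.0, sst=1.0,
            )

        monkeypatch.setattr(gdmod, "factor_q", fake_factor_q)
        sel, tab = gdmod.screen_variables(
            environment.subset(["temp1", "temp2", "precip1"]),
            occurrences,
            n_permutations=0,
        )
        assert sel == ["temp1"]  # 0.15 kept; 0.05 dropped; exactly 0.1 dropped
        assert tab.retained.tolist() == [True, False, False]

    def test_signal_variables_outscore_noise(self, environment, occurrences):
        sel, tab = screen_variables(environment, occurrences, n_permutations=0)
        q = tab.set_index("variable")["q"]
        assert min(q[["temp1", "temp2", "precip1", "precip2"]]) > max(
            q[["noise1", "noise2", "noise3"]]
        )
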