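"""Environmental-space metrics: envelopes, hulls, Gower's distance, extents."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import envgap as eg
from envgap.gap import MonthlySummary, Ranges, monthly_summary

from conftest import make_env


def hull_oracle(available: np.ndarray, prediction: np.ndarray) -> np.ndarray:
    """Triangulation point-location oracle for hull membership (<= 3-D).

    1-D falls back to the interval test (the hull of a single covariate).
    """
    from scipy.spatial import Delaunay

    if available.shape[1] == 1:
        lo, hi = available.min(), available.max()
        inside = (prediction[:, 0] >= lo) & (prediction[:, 0] <= hi)
    else:
        tri = Delaunay(available)
        inside = tri.find_simplex(prediction) >= 0
    return np.where(inside, "interpolation", "extrapolation")


class TestCovariateRanges:
    def test_enumerated_min_max(self, env_factory):
        r = eg.covariate_ranges(env_factory([2.0, 7.0, 4.0]))
        assert r.min_k[0] == 2 and r.max_k[0] == 7 and r.r_k[0] == 5

    def test_single_record_flagged_degenerate(self, env_factory):
        with pytest.warns(UserWarning, match="zero range"):
            r = eg.covariate_ranges(env_factory([[3.0, 5.0]], names=("a", "b")))
        assert r.degenerate.all()

    def test_interior_record_leaves_ranges_unchanged(self, env_factory):
        r0 = eg.covariate_ranges(env_factory([2.0, 7.0, 4.0]))
        r1 = eg.covariate_ranges(env_factory([2.0, 7.0, 4.0, 5.0]))
        assert r0.min_k == r1.min_k and r0.max_k == r1.max_k

    def test_empty_rejected(self, env_factory):
        ds = env_factory(np.zeros((0, 1)))
        with pytest.raises(ValueError):
            eg.covariate_ranges(ds)


class TestClassifyUnivariate:
    def test_below_within_above(self, env_factory):
        r = eg.covariate_ranges(env_factory([10.0, 2500.0], names=("depth",)))
        pred = env_factory([3000.0, 5.0, 100.0], names=("depth",),
                           role="prediction")
        classes = eg.classify_univariate(r, pred)["depth"].tolist()
        assert classes == ["above", "below", "within"]

    def test_boundary_is_within(self, env_factory):
        r = eg.covariate_ranges(env_factory([10.0, 2500.0], names=("depth",)))
        pred = env_factory([10.0, 2500.0], names=("depth",), role="prediction")
        assert eg.classify_univariate(r, pred)["depth"].tolist() == ["within"] * 2

    def test_point_envelope(self, env_factory):
        with pytest.warns(UserWarning):
            r = eg.covariate_ranges(env_factory([5.0]))
        pred = env_factory([5.0, 5.0 + 1e-9, 5.0 - 1e-9], role="prediction")
        assert eg.classify_univariate(r, pred)["x"].tolist() == \
            ["within", "above", "below"]

    def test_covariate_mismatch_rejected(self, env_factory):
        r = eg.covariate_ranges(env_factory([1.0, 2.0], names=("a",)))
        pred = env_factory([1.0], names=("b",), role="prediction")
        with pytest.raises(ValueError):
            eg.classify_univariate(r, pred)


class TestHullMembership:
    def test_generators_are_interpolation(self, env_factory):
        a = env_factory([(0, 0), (0, 1), (1, 0), (1, 1)], names=("a", "b"))
        p = env_factory([(0, 0), (1, 1)], names=("a", "b"), role="prediction")
        assert eg.hull_membership(a, p).tolist() == ["interpolation"] * 2

    def test_square_interior_exterior_boundary(self, env_factory):
        a = env_factory([(0, 0), (0, 1), (1, 0), (1, 1)], names=("a", "b"))
        p = env_factory([(0.5, 0.5), (1.5, 0.5), (0.5, 1.0)],
                        names=("a", "b"), role="prediction")
        assert eg.hull_membership(a, p).tolist() == \
            ["interpolation", "extrapolation", "interpolation"]

    def test_diamond_univariate_within_multivariate_outside(self, env_factory):
        # the canonical failure of univariate envelopes: (0.2, 0.2) is inside
        # both [0, 2] ranges but below the x + y >= 1 facet of the diamond
        a = env_factory([(0, 1), (1, 0), (2, 1), (1, 2)], names=("a", "b"))
        p = env_factory([(0.2, 0.2)], names=("a", "b"), role="prediction")
        uni = eg.classify_univariate(eg.covariate_ranges(a), p)
        assert (uni.to_numpy() == "within").all()
        assert eg.hull_membership(a, p).tolist() == ["extrapolation"]

    def test_empty_available_rejected(self, env_factory):
        a = make_env(np.zeros((0, 2)), names=("a", "b"))
        p = env_factory([(0, 0)], names=("a", "b"), role="prediction")
        with pytest.raises(ValueError):
            eg.hull_membership(a, p)

    @pytest.mark.parametrize("dim", [1, 2, 3])
    def test_agrees_with_triangulation_oracle(self, dim):
        rng = np.random.default_rng(100 + dim)
        names = tuple("abc"[:dim])
        for _ in range(10):
            a = rng.normal(size=(30, dim))
            p = rng.normal(size=(60, dim)) * 1.5
            got = eg.hull_membership(make_env(a, names),
                                     make_env(p, names, "prediction"))
            want = hull_oracle(a, p)
            assert (got.to_numpy() == want).all()

    def test_degenerate_flat_hull(self, env_factory):
        # all available points on a line in 2-D: hull is the segment
        a = env_factory([(0, 0), (1, 1), (2, 2)], names=("a", "b"))
        p = env_factory([(1.5, 1.5), (1.0, 1.2)], names=("a", "b"),
                        role="prediction")
        assert eg.hull_membership(a, p).tolist() == \
            ["interpolation", "extrapolation"]


class TestGowerDistance:
    def test_identity(self):
        r = Ranges(("a", "b"), np.zeros(2), np.array([4.0, 40.0]))
        assert eg.gower_distance([1, 10], [1, 10], r) == 0.0

    def test_full_range_displacement_is_one(self):
        r = Ranges(("a",), np.array([0.0]), np.array([4.0]))
        assert eg.gower_distance([0.0], [4.0], r) == 1.0

    def test_hand_evaluation(self):
        r = Ranges(("a", "b"), np.zeros(2), np.array([4.0, 40.0]))
        assert eg.gower_distance([1, 10], [3, 30], r) == pytest.approx(0.5)

    def test_zero_range_covariate_dropped_with_warning(self):
        r = Ranges(("a", "b"), np.array([0.0, 5.0]), np.array([4.0, 5.0]))
        with pytest.warns(UserWarning, match="K reduced"):
            d = eg.gower_distance([0, 5], [4, 5], r)
        assert d == 1.0  # only covariate a contributes, K = 1

    @given(st.lists(st.tuples(*[st.floats(-100, 100) for _ in range(3)]),
                    min_size=3, max_size=3))
    @settings(deadline=None, max_examples=50)
    def test_metric_properties(self, pts):
        x, y, z = (np.asarray(p) for p in pts)
        r = Ranges(("a", "b", "c"), np.full(3, -100.0), np.full(3, 100.0))
        dxy = eg.gower_distance(x, y, r)
        dyx = eg.gower_distance(y, x, r)
        dxz = eg.gower_distance(x, z, r)
        dzy = eg.gower_distance(z, y, r)
        assert dxy >= 0 and dxy == dyx
        assert dxy <= dxz + dzy + 1e-12

    def test_affine_rescaling_invariance(self, env_factory):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(20, 3))
        b = rng.normal(size=(10, 3))
        scale, shift = np.array([2.0, 0.5, 10.0]), np.array([5.0, -3.0, 0.0])
        names = ("a", "b", "c")
        r0 = eg.covariate_ranges(make_env(a, names))
        r1 = eg.covariate_ranges(make_env(a * scale + shift, names))
        for i in range(len(b) - 1):
            d0 = eg.gower_distance(b[i], b[i + 1], r0)
            d1 = eg.gower_distance(b[i] * scale + shift,
                                   b[i + 1] * scale + shift, r1)
            assert d1 == pytest.approx(d0, rel=1e-12)


class TestGeometricMeanGower:
    def test_two_records_single_pair(self, env_factory):
        gv = eg.geometric_mean_gower(env_factory([0.0, 1.0]))
        assert gv == pytest.approx(1.0)

    def test_hand_computed_radius(self, env_factory):
        gv = eg.geometric_mean_gower(env_factory([0.0, 1.0, 3.0]))
        assert gv == pytest.approx((2.0 / 9.0) ** (1.0 / 3.0), abs=1e-12)

    def test_duplicate_record_leaves_gv_unchanged(self, env_factory):
        gv0 = eg.geometric_mean_gower(env_factory([0.0, 1.0, 3.0]))
        with pytest.warns(UserWarning, match="zero-distance"):
            gv1 = eg.geometric_mean_gower(env_factory([0.0, 1.0, 3.0, 3.0]))
        assert gv1 == pytest.approx(gv0, abs=1e-12)

    def test_all_duplicates_rejected(self, env_factory):
        with pytest.raises(ValueError):
            eg.geometric_mean_gower(env_factory([[2.0, 3.0], [2.0, 3.0]],
                                                names=("a", "b")))


class TestProportionNearby:
    def test_hand_computed_fraction(self, env_factory):
        a = env_factory([0.0, 1.0, 3.0])
        p = env_factory([2.0], role="prediction")
        frac = eg.proportion_nearby(a, p)
        assert frac.iloc[0] == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_far_point_gets_zero(self, env_factory):
        a = env_factory([0.0, 1.0, 3.0])
        p = env_factory([100.0], role="prediction")
        assert eg.proportion_nearby(a, p).iloc[0] == 0.0

    def test_available_point_sees_itself(self, env_factory):
        a = env_factory([0.0, 1.0, 3.0])
        p = env_factory([0.0, 1.0, 3.0], role="prediction")
        assert (eg.proportion_nearby(a, p) >= 1.0 / 3.0).all()

    def test_in_unit_interval(self, available):
        p = make_env(available.records[:50], available.covariate_names,
                     "prediction")
        frac = eg.proportion_nearby(available, p)
        assert ((frac >= 0) & (frac <= 1)).all()


class TestExtents:
    def test_arithmetic(self):
        labels = ["extrapolation"] * 3 + ["interpolation"] * 7
        assert eg.extrapolation_extent(pd.Series(labels)) == 30.0

    def test_degenerate_all_or_none(self):
        assert eg.extrapolation_extent(["interpolation"] * 4) == 0.0
        assert eg.extrapolation_extent(["extrapolation"] * 4) == 100.0

    def test_monthly_summary_constant(self):
        s = monthly_summary({m: 5.0 for m in range(1, 13)})
        assert (s.mean, s.min, s.max) == (5.0, 5.0, 5.0)

    def test_monthly_summary_arithmetic(self):
        s = monthly_summary({m: float(m) for m in range(1, 13)})
        assert s.mean == 6.5
        assert (s.min, s.min_month) == (1.0, 1)
        assert (s.max, s.max_month) == (12.0, 12)

    def test_monthly_summary_format(self):
        s = MonthlySummary(mean=49.9, min=8.1, min_month=9,
                           max=55.1, max_month=2)
        assert s.format() == "49.9% (8.1% in September - 55.1% in February)"

    def test_missing_months_warn(self):
        with pytest.warns(UserWarning, match="of 12 months"):
            monthly_summary({1: 3.0, 2: 5.0})


class TestStructuralProperties:
    """Cross-metric invariants on random multi-covariate instances."""

    def _random_instance(self, rng, k=4, n=40, m=80):
        names = tuple(f"c{i}" for i in range(k))
        a = rng.normal(size=(n, k))
        p = rng.normal(size=(m, k)) * 1.5
        return (make_env(a, names), make_env(p, names, "prediction"), names)

    def test_projection_monotonicity(self):
        # a record outside any univariate envelope of covariate k is
        # extrapolative for every combination containing k
        rng = np.random.default_rng(21)
        for _ in range(5):
            a, p, names = self._random_instance(rng)
            uni = eg.classify_univariate(eg.covariate_ranges(a), p)
            for combo in [names[:2], names[1:], names]:
                hull = eg.hull_membership(a.select(combo), p.select(combo))
                out_uni = (uni[list(combo)] != "within").any(axis=1)
                assert (hull[out_uni.to_numpy()] == "extrapolation").all()

    def test_extent_nesting_in_covariate_inclusion(self):
        rng = np.random.default_rng(22)
        for _ in range(5):
            a, p, names = self._random_instance(rng)
            prev = np.zeros(p.n, dtype=bool)
            for j in range(1, len(names) + 1):
                combo = names[:j]
                hull = eg.hull_membership(a.select(combo), p.select(combo))
                now = hull.to_numpy() == "extrapolation"
                assert (prev <= now).all()  # set of extrapolations only grows
                prev = now

    def test_generator_inclusion(self):
        rng = np.random.default_rng(23)
        a, _, names = self._random_instance(rng, m=1)
        p = make_env(a.records, names, "prediction")
        assert (eg.hull_membership(a, p) == "interpolation").all()
        assert (eg.proportion_nearby(a, p) >= 1.0 / a.n).all()


class TestAnalyzeCombination:
    def test_multivariate_extent_at_least_univariate_max(self, available, grid,
                                                         static_fields,
                                                         climatology):
        pred = eg.build_prediction_dataset(grid, static_fields, climatology, 1)
        res = eg.analyze_combination(available, pred, ("sst", "pp", "eke"),
                                     month=1)
        assert res.extent_pct >= max(res.univariate_extent_pct.values())

    def test_table_columns_and_ranges(self, available, grid, static_fields,
                                      climatology):
        pred = eg.build_prediction_dataset(grid, static_fields, climatology, 7)
        res = eg.analyze_combination(available, pred, ("depth", "sst"))
        assert set(res.table.columns) == {"cell_id", "class_depth", "class_sst",
                                          "hull_class", "proportion_nearby"}
        assert res.table["proportion_nearby"].between(0, 1).all()
        assert 0 <= res.extent_pct <= 100
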