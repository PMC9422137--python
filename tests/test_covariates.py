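"""Crossing counts, distances, land cover, caps, and the collinearity screen."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, Point

from fenceline import covariates as cov
from fenceline.features import ConfigClass, FeatureLayer
from fenceline.geoio import CategoricalRaster

from .oracles import (
    brute_crossing_count,
    brute_min_distance,
    nearest_rank_percentile_sorted,
)


def _layer(lines, cc=ConfigClass.FENCE):
    return FeatureLayer(cc, [LineString(c) for c in lines])


@pytest.fixture(scope="module")
def random_layer(request):
    rng = np.random.default_rng(5)
    lines = []
    for _ in range(200):
        start = rng.uniform(0, 10_000, 2)
        n_vert = rng.integers(2, 5)
        deltas = rng.uniform(-800, 800, size=(n_vert - 1, 2))
        coords = np.vstack([start, start + np.cumsum(deltas, axis=0)])
        lines.append(coords)
    return lines


class TestCountCrossings:
    def test_single_crossing(self):
        layer = _layer([[(5, -1), (5, 1)]])
        assert cov.count_crossings(LineString([(0, 0), (10, 0)]), layer) == 1

    def test_no_crossing(self):
        layer = _layer([[(20, -1), (20, 1)]])
        assert cov.count_crossings(LineString([(0, 0), (10, 0)]), layer) == 0

    def test_zigzag_counts_each_pass(self):
        fence = _layer([[(0, 0), (100, 0)]])
        zigzag = LineString([(10, -5), (20, 5), (30, -5), (40, 5)])
        assert cov.count_crossings(zigzag, fence) == 3

    def test_collinear_overlap_counts_once(self):
        fence = _layer([[(0, 0), (100, 0)]])
        along = LineString([(10, 0), (50, 0)])
        assert cov.count_crossings(along, fence) == 1

    def test_endpoint_touch_counts_once(self):
        fence = _layer([[(10, -5), (10, 5)]])
        touching = LineString([(0, 0), (10, 0)])
        assert cov.count_crossings(touching, fence) == 1

    def test_zero_length_step(self):
        fence = _layer([[(0, -5), (0, 5)]])
        assert cov.count_crossings(LineString([(0, 0), (0, 0)]), fence) == 0

    def test_matches_brute_force_oracle(self, random_layer):
        rng = np.random.default_rng(6)
        layer = _layer(random_layer)
        index = cov.LayerIndex(layer)
        starts = rng.uniform(0, 10_000, size=(1000, 2))
        ends = starts + rng.uniform(-1500, 1500, size=(1000, 2))
        fast = cov.count_crossings_bulk(starts, ends, index)
        for i in range(1000):
            assert fast[i] == brute_crossing_count(starts[i], ends[i], random_layer)

    def test_reversal_invariance(self, random_layer):
        layer_fwd = _layer(random_layer[:50])
        layer_rev = _layer([c[::-1] for c in random_layer[:50]])
        rng = np.random.default_rng(7)
        for _ in range(100):
            a, b = rng.uniform(0, 10_000, 2), rng.uniform(0, 10_000, 2)
            seg = LineString([a, b])
            ges = LineString([b, a])
            n = cov.count_crossings(seg, layer_fwd)
            assert cov.count_crossings(ges, layer_fwd) == n
            assert cov.count_crossings(seg, layer_rev) == n


class TestDistance:
    def test_simple_distance(self):
        layer = _layer([[(3, -10), (3, 10)]])
        assert cov.distance_to_feature(Point(0, 0), layer) == pytest.approx(3.0)

    def test_cap_applied(self):
        layer = _layer([[(5000, 0), (5000, 10)]])
        assert cov.distance_to_feature(Point(0, 0), layer, cap=1000.0) == 1000.0

    def test_empty_layer_returns_cap(self):
        layer = FeatureLayer(ConfigClass.R2F, [])
        assert cov.distance_to_feature(Point(0, 0), layer, cap=1000.0) == 1000.0

    def test_zero_iff_on_line(self, random_layer):
        layer = _layer(random_layer[:20])
        on = Point(random_layer[0][0])
        assert cov.distance_to_feature(on, layer) <= 1e-9

    def test_matches_brute_force(self, random_layer):
        rng = np.random.default_rng(8)
        layer_index = cov.LayerIndex(_layer(random_layer))
        pts = rng.uniform(0, 10_000, size=(300, 2))
        fast = cov.distance_to_feature_bulk(pts, layer_index, cap=1e9)
        for i, p in enumerate(pts):
            assert fast[i] == pytest.approx(brute_min_distance(p, random_layer), abs=1e-6)

    def test_bad_cap(self):
        with pytest.raises(ValueError):
            cov.distance_to_feature(Point(0, 0), _layer([[(0, 0), (1, 1)]]), cap=0)


class TestCaps:
    def test_all_zero_counts_flagged_constant(self):
        rules = cov.fit_caps({ConfigClass.FENCE: np.zeros(100, dtype=int)})
        rule = rules[ConfigClass.FENCE]
        assert rule.cap_value == 0 and rule.constant

    def test_nearest_rank_matches_sort_oracle(self):
        counts = np.array([0] * 100 + [7])
        got = cov.nearest_rank_percentile(counts, 98)
        assert got == nearest_rank_percentile_sorted(counts, 98)
        rng = np.random.default_rng(9)
        for _ in range(50):
            vals = rng.poisson(2.0, size=rng.integers(5, 400))
            for p in (50, 90, 98, 100):
                assert cov.nearest_rank_percentile(vals, p) == nearest_rank_percentile_sorted(vals, p)

    def test_capping_idempotent(self, rng):
        rule = cov.CapRule(ConfigClass.RNF, 98, 3)
        x = rng.poisson(3.0, size=500)
        once = rule.apply(x)
        assert np.array_equal(rule.apply(once), once)
        assert once.max() <= 3


class TestLandcover:
    @pytest.fixture()
    def checkerboard(self):
        values = np.indices((8, 8)).sum(axis=0) % 2  # 0/1 checkerboard
        legend = {0: "shrub", 1: "water"}
        return CategoricalRaster(values=values, x0=0, y0=0, cell=100.0, legend=legend)

    def test_reclassification(self, checkerboard):
        # row 7 (south edge) col 0 has value (7+0)%2=1 -> water -> OTHER
        assert cov.landcover_at(np.array([[50.0, 50.0]]), checkerboard)[0] == "OTHER"
        assert cov.landcover_at(np.array([[150.0, 50.0]]), checkerboard)[0] == "NATIVE"

    def test_matches_direct_indexing(self, checkerboard, rng):
        xy = rng.uniform(0, 800, size=(1000, 2))
        got = cov.landcover_at(xy, checkerboard)
        col = (xy[:, 0] // 100).astype(int)
        row = 7 - (xy[:, 1] // 100).astype(int)
        expect = np.where(checkerboard.values[row, col] == 0, "NATIVE", "OTHER")
        assert (got == expect).all()

    def test_off_map_falls_back_to_other(self, checkerboard):
        assert cov.landcover_at(np.array([[-1000.0, 50.0]]), checkerboard)[0] == "OTHER"

    def test_default_reclass_table(self):
        assert cov.DEFAULT_RECLASS["shrub"] == "NATIVE"
        assert cov.DEFAULT_RECLASS["wetland"] == "NATIVE"
        assert cov.DEFAULT_RECLASS["water"] == "OTHER"
        assert cov.DEFAULT_RECLASS["developed"] == "OTHER"


class TestScreen:
    def test_perfect_collinearity_flagged(self, rng):
        x = rng.normal(size=100)
        design = pd.DataFrame({"a": x, "b": 2 * x, "c": rng.normal(size=100)})
        report = cov.screen_collinearity(design)
        assert any({p[0], p[1]} == {"a", "b"} for p in report.flagged)

    def test_independent_covariates_not_flagged(self, rng):
        design = pd.DataFrame(rng.normal(size=(10_000, 4)), columns=list("abcd"))
        report = cov.screen_collinearity(design)
        assert not report.flagged
        off_diag = report.r_matrix.to_numpy()[~np.eye(4, dtype=bool)]
        assert np.abs(off_diag).max() < 0.05

    def test_threshold_is_strict(self, rng):
        x = rng.normal(size=2000)
        y = 0.7 * x + np.sqrt(1 - 0.49) * rng.normal(size=2000)
        design = pd.DataFrame({"a": x, "b": y})
        r = float(design.corr().loc["a", "b"])
        # flag exactly when |r| exceeds the threshold — equality is not flagged
        report = cov.screen_collinearity(design, threshold=abs(r))
        assert not report.flagged
        report = cov.screen_collinearity(design, threshold=abs(r) - 1e-12)
        assert report.flagged

    def test_zero_variance_reported_undefined(self, rng):
        design = pd.DataFrame({"a": rng.normal(size=50), "b": np.ones(50)})
        report = cov.screen_collinearity(design)
        assert ("a", "b") in report.undefined

    def test_too_small_input(self):
        with pytest.raises(ValueError):
            cov.screen_collinearity(pd.DataFrame({"a": [1.0, 2.0]}))


def test_covariates_deterministic(small_landscape, rng):
    stacked = cov.StackedLayerIndex(small_landscape.true_layers)
    starts = rng.uniform(0, 12_000, size=(200, 2))
    ends = starts + rng.uniform(-1200, 1200, size=(200, 2))
    a = stacked.count_crossings_by_class(starts, ends)
    b = stacked.count_crossings_by_class(starts, ends)
    for cc in a:
        assert np.array_equal(a[cc], b[cc])
    da = stacked.distances_by_class(starts)
    db = stacked.distances_by_class(starts)
    for cc in da:
        assert np.array_equal(da[cc], db[cc])


def test_stacked_index_matches_per_layer_path(small_landscape, rng):
    """The simulator-facing stacked index and the single-layer API agree."""
    stacked = cov.StackedLayerIndex(small_landscape.true_layers)
    starts = rng.uniform(0, 12_000, size=(100, 2))
    ends = starts + rng.uniform(-1500, 1500, size=(100, 2))
    by_class = stacked.count_crossings_by_class(starts, ends)
    for cc, layer in small_landscape.true_layers.items():
        single = cov.count_crossings_bulk(starts, ends, cov.LayerIndex(layer))
        assert np.array_equal(by_class[cc], single)
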