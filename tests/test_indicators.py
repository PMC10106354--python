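"""Criterion score layers: class boundaries, masks and geometric measures."""

import numpy as np
import pytest
from shapely.geometry import Polygon

from palmsust.grid import GridGeometry, MultiBandRaster, PolygonSet, Polyline, Raster
from palmsust.indicators import (
    IndicatorConfig,
    channel_modification_indicator,
    connectivity_indicator,
    erosion_indicator,
    riparian_river_indicator,
    riparian_standing_indicator,
    sinuosity,
    water_clarity_indicator,
)
from palmsust.landcover import CLASS_IDS, LandCoverMap

CFG = IndicatorConfig()


def lc_from(ids: np.ndarray, cell=1.0) -> LandCoverMap:
    ids = np.asarray(ids, dtype=np.int64)
    geom = GridGeometry(0.0, ids.shape[0] * cell, cell, *ids.shape)
    return LandCoverMap(Raster(geom, ids, nodata=0))


class TestErosion:
    @pytest.mark.parametrize(
        "slope,expected",
        [(0.0, 3), (10.0, 3), (10.001, 2), (15.0, 2), (25.0, 2), (25.001, 1), (30.0, 1)],
    )
    @pytest.mark.parametrize("cover", ["bare_soil", "oil_palm"])
    def test_slope_class_boundaries(self, slope, expected, cover):
        lc = lc_from([[CLASS_IDS[cover]]])
        layer = erosion_indicator(lc, Raster(lc.classes.geometry, [[slope]]), CFG)
        assert layer.scores.values[0, 0] == expected

    def test_non_erodible_cover_is_nodata(self):
        lc = lc_from([[CLASS_IDS["water"]]])
        layer = erosion_indicator(lc, Raster(lc.classes.geometry, [[30.0]]), CFG)
        assert not layer.mask[0, 0]

    def test_score_never_increases_with_slope(self, rng):
        lc = lc_from(np.full((1, 50), CLASS_IDS["oil_palm"]))
        slopes = np.sort(rng.uniform(0, 60, 50)).reshape(1, 50)
        layer = erosion_indicator(lc, Raster(lc.classes.geometry, slopes), CFG)
        assert np.all(np.diff(layer.scores.values[0]) <= 0)


class TestRiparianRiver:
    def make(self, distance_m, cover):
        """One non-water cell at a controlled distance from a vertical channel."""
        n = 200
        ids = np.full((1, n), CLASS_IDS["water"])
        col = int(distance_m)  # cell centres sit at x = col + 0.5
        ids[0, col] = CLASS_IDS[cover]
        lc = lc_from(ids)
        channel = Polyline([(0.5, -10.0), (0.5, n + 10.0)], width_m=2.0)
        return lc, channel, col

    @pytest.mark.parametrize(
        "distance,expected", [(10, 1), (19, 1), (22, 2), (29, 2), (32, 3), (39, 3)]
    )
    def test_distance_bands_for_non_natural_cover(self, distance, expected):
        lc, channel, col = self.make(distance, "oil_palm")
        layer = riparian_river_indicator(lc, channel, CFG)
        assert layer.scores.values[0, col] == expected

    def test_natural_vegetation_scores_high_anywhere_in_buffer(self):
        for distance in (10, 25, 38):
            lc, channel, col = self.make(distance, "other_vegetation")
            layer = riparian_river_indicator(lc, channel, CFG)
            assert layer.scores.values[0, col] == 3

    def test_beyond_forty_metres_is_nodata(self):
        lc, channel, col = self.make(50, "bare_soil")
        layer = riparian_river_indicator(lc, channel, CFG)
        assert not layer.mask[0, col]

    def test_water_cells_excluded_from_mask(self):
        lc, channel, _ = self.make(10, "oil_palm")
        assert not layer_mask_on_water(riparian_river_indicator(lc, channel, CFG), lc)


def layer_mask_on_water(layer, lc):
    return bool((layer.mask & lc.mask_of("water")).any())


class TestRiparianStanding:
    def make(self, distance_m, cover):
        n = 150
        ids = np.full((1, n), CLASS_IDS["crops"])
        col = int(distance_m)
        ids[0, col] = CLASS_IDS[cover]
        lc = lc_from(ids)
        body = PolygonSet(
            {1: Polygon([(0, -5), (0.5, -5), (0.5, 160), (0, 160)])}, role="water_body"
        )
        return lc, body, col

    def test_non_natural_cover_in_buffer_scores_low(self):
        lc, body, col = self.make(50, "crops")
        layer = riparian_standing_indicator(lc, body, CFG)
        assert layer.scores.values[0, col] == 1

    def test_natural_cover_in_buffer_scores_high(self):
        lc, body, col = self.make(50, "other_vegetation")
        layer = riparian_standing_indicator(lc, body, CFG)
        assert layer.scores.values[0, col] == 3

    def test_outside_hundred_metres_is_nodata(self):
        lc, body, col = self.make(120, "crops")
        layer = riparian_standing_indicator(lc, body, CFG)
        assert not layer.mask[0, col]


class TestWaterClarity:
    def make(self, mean_red):
        n = 10
        ids = np.full((n, n), CLASS_IDS["water"])
        lc = lc_from(ids)
        img = MultiBandRaster(
            lc.classes.geometry,
            {
                "red": np.full((n, n), float(mean_red)),
                "green": np.full((n, n), 60.0),
                "nir": np.full((n, n), 20.0),
            },
        )
        body = PolygonSet({1: Polygon([(0, 0), (10, 0), (10, 10), (0, 10)])})
        return lc, img, body

    @pytest.mark.parametrize(
        "mean_red,expected",
        [
            (50.0, 3),  # clearer than the calibrated baseline: clamps high
            (67.1, 3),
            (70.0, 3),
            (104.5, 3),
            (104.6, 2),
            (120.0, 2),
            (142.0, 2),
            (142.1, 1),
            (150.0, 1),
            (179.5, 1),
            (200.0, 1),  # beyond the calibrated range: clamps low
        ],
    )
    def test_turbidity_class_boundaries(self, mean_red, expected):
        lc, img, body = self.make(mean_red)
        layer = water_clarity_indicator(lc, img, body, CFG)
        assert np.all(layer.scores.values[layer.mask] == expected)

    def test_body_without_water_cells_raises(self):
        lc, img, body = self.make(100.0)
        dry = lc_from(np.full((10, 10), CLASS_IDS["bare_soil"]))
        with pytest.raises(ValueError, match="water cells"):
            water_clarity_indicator(dry, img, body, CFG)


class TestSinuosity:
    def test_straight_segment_is_one(self):
        assert sinuosity(Polyline([(0, 0), (5, 5)])) == 1.0

    def test_pythagorean_toy_polyline(self):
        assert sinuosity(Polyline([(0, 0), (3, 4), (6, 0)])) == pytest.approx(10 / 6)

    def test_densified_semicircle_near_half_pi(self):
        t = np.linspace(0, np.pi, 2000)
        arc = Polyline(np.column_stack([np.cos(t), np.sin(t)]))
        assert sinuosity(arc) == pytest.approx(np.pi / 2, rel=1e-3)

    def test_invariant_under_rigid_motion_and_scaling(self, rng):
        verts = rng.uniform(0, 10, (6, 2))
        base = sinuosity(Polyline(verts))
        theta = rng.uniform(0, 2 * np.pi)
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = 3.7 * verts @ rot.T + np.array([100.0, -50.0])
        assert sinuosity(Polyline(moved)) == pytest.approx(base, rel=1e-9)
        assert base >= 1.0

    def test_closed_loop_rejected(self):
        with pytest.raises(ValueError, match="coincide"):
            sinuosity(Polyline([(0, 0), (1, 0), (1, 1), (0, 0)]))


class TestChannelModification:
    def river_scene(self, vertices):
        n = 20
        ids = np.full((n, n), CLASS_IDS["crops"])
        ids[:, 9:11] = CLASS_IDS["water"]
        lc = lc_from(ids)
        return lc, Polyline(vertices, width_m=2.0)

    @pytest.mark.parametrize(
        "sin_value,expected", [(1.0, 1), (1.05, 1), (1.06, 2), (1.11, 2), (1.30, 2), (1.31, 3), (1.6667, 3)]
    )
    def test_sinuosity_class_painted_on_river(self, sin_value, expected):
        # build a channel whose measured sinuosity equals sin_value: a
        # V-shaped detour of controlled depth within the river corridor
        n = 20
        chord = float(n)
        half = chord / 2
        depth = half * np.sqrt(max(sin_value, 1.0) ** 2 - 1.0)
        verts = [(10.0, 0.0), (10.0 + depth, half), (10.0, chord)]
        lc, channel = self.river_scene(verts)
        assert sinuosity(channel) == pytest.approx(sin_value, rel=1e-6)
        # paint over all water cells within the corridor of a straight proxy
        layer = channel_modification_indicator(lc, channel, CFG)
        vals = layer.scores.values[layer.mask]
        assert vals.size > 0 and np.all(vals == expected)

    def test_no_channel_yields_empty_layer(self):
        lc, _ = self.river_scene([(10.0, 0.0), (10.0, 20.0)])
        layer = channel_modification_indicator(lc, None, CFG)
        assert layer.empty


class TestConnectivity:
    def strip_scene(self):
        """Columns of known distance to a natural-vegetation strip at col 0."""
        n = 80
        ids = np.full((1, n), CLASS_IDS["oil_palm"])
        ids[0, 0] = CLASS_IDS["other_vegetation"]
        return ids

    @pytest.mark.parametrize(
        "col,cover,expected",
        [
            (0, "other_vegetation", 3.0),  # distance 0, coefficient 1
            (20, "oil_palm", 3.0 * 0.5),  # <= 25 m
            (30, "oil_palm", 2.0 * 0.5),  # 25-50 m band
            (30, "crops", 1.0),
            (60, "oil_palm", 1.0 * 0.5),  # > 50 m
            (30, "bare_soil", 0.0),
            (60, "built_up", 0.0),
        ],
    )
    def test_band_times_coefficient(self, col, cover, expected):
        ids = self.strip_scene()
        if col > 0:
            ids[0, col] = CLASS_IDS[cover]
        lc = lc_from(ids)
        layer = connectivity_indicator(lc, CFG)
        assert layer.scores.values[0, col] == pytest.approx(expected)

    def test_river_cells_take_full_coefficient(self):
        ids = self.strip_scene()
        ids[0, 30] = CLASS_IDS["water"]
        lc = lc_from(ids)
        river_mask = np.zeros_like(ids, dtype=bool)
        river_mask[0, 30] = True
        layer = connectivity_indicator(lc, CFG, river_mask=river_mask)
        assert layer.scores.values[0, 30] == pytest.approx(2.0)

    def test_all_natural_scene_scores_three_everywhere(self):
        lc = lc_from(np.full((10, 10), CLASS_IDS["other_vegetation"]))
        layer = connectivity_indicator(lc, CFG)
        np.testing.assert_allclose(layer.scores.values, 3.0)

    def test_no_natural_vegetation_raises(self):
        lc = lc_from(np.full((5, 5), CLASS_IDS["bare_soil"]))
        with pytest.raises(ValueError, match="natural"):
            connectivity_indicator(lc, CFG)


class TestScoreSets:
    def test_declared_score_sets_hold_on_synthetic_scene(self, small_bundle):
        from palmsust.grid import slope_degrees
        from palmsust.indicators import all_indicators

        slope = slope_degrees(small_bundle.dtm)
        layers = all_indicators(
            small_bundle.truth,
            small_bundle.ortho,
            slope,
            small_bundle.channel,
            small_bundle.water_bodies,
            CFG,
        )
        allowed = {
            "erosion": {1, 2, 3},
            "riparian_river": {1, 2, 3},
            "riparian_standing": {1, 3},
            "water_clarity": {1, 2, 3},
            "channel_modification": {1, 2, 3},
            "connectivity": {0, 0.5, 1, 1.5, 2, 3},
        }
        for layer in layers:
            vals = set(np.unique(layer.scores.values[layer.mask]).tolist())
            assert vals <= allowed[layer.name], layer.name
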