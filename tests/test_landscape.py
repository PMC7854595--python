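"""Synthetic feature layers, suppression sampling and bearing simulation."""

import numpy as np
import pytest
from scipy import stats

from featureshy import (
    Extent,
    FeatureSpec,
    LandscapeConfig,
    SuppressionFunction,
    generate_features,
    generate_random_points,
    simulate_animal_locations,
    simulate_bearings,
)

EXTENT = Extent(0.0, 0.0, 10_000.0, 10_000.0)


def config(specs, profile=None, seed=0, **kw):
    return LandscapeConfig(
        extent=EXTENT,
        feature_specs=tuple(specs),
        avoidance_profile=profile or {},
        seed=seed,
        **kw,
    )


class TestGenerateFeatures:
    def test_point_count_conservation(self):
        lc = config([FeatureSpec("well", "point", 10)])
        (layer,) = generate_features(lc)
        assert len(layer.geometries) == 10
        xs = [g.x for g in layer.geometries]
        ys = [g.y for g in layer.geometries]
        assert np.all(EXTENT.contains(xs, ys))

    def test_determinism(self):
        lc = config([FeatureSpec("well", "point", 10), FeatureSpec("road", "line", 4)])
        a = generate_features(lc)
        b = generate_features(lc)
        for la, lb in zip(a, b):
            assert [g.wkt for g in la.geometries] == [g.wkt for g in lb.geometries]

    def test_zero_count_empty_layer_infinite_distance(self):
        lc = config([FeatureSpec("well", "point", 0)])
        (layer,) = generate_features(lc)
        assert layer.is_empty
        assert np.isinf(layer.distances([100.0], [100.0])).all()

    def test_chords_span_extent(self):
        lc = config([FeatureSpec("road", "line", 20)])
        (layer,) = generate_features(lc)
        assert len(layer.geometries) == 20
        assert all(g.length > 0 for g in layer.geometries)

    def test_grid_covers_extent_within_half_spacing(self):
        lc = config([FeatureSpec("fence", "grid", spacing_m=1000.0)])
        (layer,) = generate_features(lc)
        pts = generate_random_points(EXTENT, 500, seed=1)
        assert layer.distances(pts.x, pts.y).max() <= 500.0 + 1e-9

    def test_invalid_extent_rejected(self):
        with pytest.raises(ValueError):
            Extent(0, 0, 0, 100)

    def test_threshold_must_fit_extent(self):
        with pytest.raises(ValueError):
            config(
                [FeatureSpec("well", "point", 1)],
                profile={"well": SuppressionFunction(1e9, form="hard")},
            )


class TestRandomPoints:
    def test_count_and_containment(self):
        pts = generate_random_points(EXTENT, 2000, seed=2)
        assert len(pts) == 2000
        assert np.all(EXTENT.contains(pts.x, pts.y))
        assert pts.role == "random"

    def test_mean_near_center(self):
        means = [generate_random_points(EXTENT, 2000, seed=s).x.mean() for s in range(10)]
        se = 10_000 / np.sqrt(12) / np.sqrt(2000 * 10)
        assert abs(np.mean(means) - 5000.0) < 3 * se

    def test_single_point(self):
        assert len(generate_random_points(EXTENT, 1, seed=3)) == 1

    def test_zero_points_rejected(self):
        with pytest.raises(ValueError):
            generate_random_points(EXTENT, 0, seed=4)


class TestSuppression:
    def test_hard_weight_is_step(self):
        sup = SuppressionFunction(500.0, form="hard")
        assert sup.weight([0.0, 499.9, 500.0, 600.0]).tolist() == [0, 0, 1, 1]

    def test_logistic_bounds_and_midpoint(self):
        sup = SuppressionFunction(500.0, softness_m=50.0, form="logistic")
        w = sup.weight([0.0, 500.0, 5000.0])
        assert w[0] < 0.01
        assert w[1] == pytest.approx(0.5)
        assert w[2] > 0.99
        assert np.all((w >= 0) & (w <= 1))


class TestSimulateAnimals:
    def test_hard_threshold_never_violated(self):
        lc = config(
            [FeatureSpec("well", "point", 25)],
            profile={"well": SuppressionFunction(500.0, form="hard")},
        )
        layers = generate_features(lc)
        animals = simulate_animal_locations(
            layers, lc.avoidance_profile, 300, EXTENT, seed=5
        )
        assert layers[0].distances(animals.x, animals.y).min() >= 500.0

    def test_null_profile_matches_random_distribution(self):
        # with no avoidance, animal and random nearest-distance distributions
        # are exchangeable: two-sample KS at alpha=0.01 passes in >=18/20 seeds
        lc = config([FeatureSpec("well", "point", 12)])
        layers = generate_features(lc)
        passes = 0
        for s in range(20):
            animals = simulate_animal_locations(layers, {}, 250, EXTENT, seed=100 + s)
            rand = generate_random_points(EXTENT, 2000, seed=200 + s)
            da = layers[0].distances(animals.x, animals.y)
            dr = layers[0].distances(rand.x, rand.y)
            passes += stats.ks_2samp(da, dr).pvalue > 0.01
        assert passes >= 18

    def test_logistic_suppression_thins_near_zone(self):
        lc = config(
            [FeatureSpec("well", "point", 25)],
            profile={"well": SuppressionFunction(500.0, softness_m=50.0, form="logistic")},
        )
        layers = generate_features(lc)
        thinner = 0
        for s in range(20):
            animals = simulate_animal_locations(
                layers, lc.avoidance_profile, 250, EXTENT, seed=300 + s
            )
            rand = generate_random_points(EXTENT, 250, seed=400 + s)
            fa = np.mean(layers[0].distances(animals.x, animals.y) < 400.0)
            fr = np.mean(layers[0].distances(rand.x, rand.y) < 400.0)
            thinner += fa < fr
        assert thinner >= 18

    def test_impossible_threshold_errors_after_bounded_attempts(self, monkeypatch):
        import featureshy.landscape as mod

        monkeypatch.setattr(mod, "REJECTION_CAP", 20_000)
        lc = config(
            [FeatureSpec("fence", "grid", spacing_m=1000.0)],
            profile={"fence": SuppressionFunction(600.0, form="hard")},  # covers extent
        )
        layers = generate_features(lc)
        with pytest.raises(RuntimeError, match="rejection"):
            simulate_animal_locations(layers, lc.avoidance_profile, 10, EXTENT, seed=6)

    def test_unknown_profile_name_rejected(self):
        lc = config([FeatureSpec("well", "point", 5)])
        layers = generate_features(lc)
        with pytest.raises(ValueError, match="unknown feature"):
            simulate_animal_locations(
                layers, {"road": SuppressionFunction(100.0)}, 5, EXTENT, seed=7
            )


class TestSimulateBearings:
    def test_noiseless_bearings_intersect_truth(self):
        stations = np.array([[0, 0], [1000, 0], [0, 1000]])
        bearings = simulate_bearings((400.0, 300.0), stations, 0.0, 0.0, seed=8)
        for b in bearings:
            az = np.degrees(np.arctan2(400.0 - b.station[0], 300.0 - b.station[1])) % 360
            assert b.azimuth_deg == pytest.approx(az, abs=1e-9)

    def test_full_outlier_rate_decouples_bearings(self):
        stations = np.array([[0, 0], [1000, 0]])
        bearings = simulate_bearings((400.0, 300.0), stations, 0.0, 1.0, seed=9)
        truth_az = [
            np.degrees(np.arctan2(400.0 - sx, 300.0 - sy)) % 360 for sx, sy in stations
        ]
        got = [b.azimuth_deg for b in bearings]
        assert not np.allclose(got, truth_az, atol=1.0)

    def test_no_stations_errors(self):
        with pytest.raises(ValueError):
            simulate_bearings((0.0, 0.0), np.empty((0, 2)), 0.0, 0.0, seed=10)
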