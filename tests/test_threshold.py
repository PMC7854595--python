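"""Difference posteriors, crossover location and threshold estimation."""

import numpy as np
import pytest

from featureshy import (
    AvoidanceThresholdModel,
    BinwiseDifferencePosterior,
    bin_cumulative,
    binomial_posterior,
    classify_hypotheses,
    difference_posterior,
    estimate_threshold,
    generate_features,
    generate_random_points,
    locate_crossover,
    simulate_animal_locations,
)
from featureshy.threshold import ThresholdEstimate

from conftest import recovery_landscape


def make_diff(means, sds, n_draws=4000, bin_width=10.0, seed=0):
    """Construct a difference posterior with prescribed per-bin normal draws."""
    rng = np.random.default_rng(seed)
    draws = rng.normal(means, sds, size=(n_draws, len(means)))
    edges = bin_width * np.arange(1, len(means) + 1)
    return BinwiseDifferencePosterior(bin_upper_edges=edges, bin_width_m=bin_width, draws=draws)


class TestDifferencePosterior:
    def test_p_identity_exact(self):
        # q fixed by construction: 750 positive of 1000 paired draws
        draws = np.concatenate([np.ones(750), -np.ones(250)])[:, None]
        diff = BinwiseDifferencePosterior(
            bin_upper_edges=np.array([10.0]), bin_width_m=10.0, draws=draws
        )
        assert diff.q[0] == 0.75
        assert diff.p[0] == 0.5
        assert np.all(diff.p == 1.0 - 2.0 * np.abs(diff.q - 0.5))

    def test_p_identity_extremes(self):
        for sign, expected_q in ((1.0, 1.0), (-1.0, 0.0)):
            draws = sign * np.ones((1000, 1))
            diff = BinwiseDifferencePosterior(
                bin_upper_edges=np.array([10.0]), bin_width_m=10.0, draws=draws
            )
            assert diff.q[0] == expected_q
            assert diff.p[0] == 0.0
        half = np.concatenate([np.ones(500), -np.ones(500)])[:, None]
        diff = BinwiseDifferencePosterior(
            bin_upper_edges=np.array([10.0]), bin_width_m=10.0, draws=half
        )
        assert diff.p[0] == 1.0

    def test_identical_curves_give_p_near_one(self, rng):
        d = rng.uniform(0, 500, 300)
        counts = bin_cumulative(d, 50, 500)
        c1 = binomial_posterior(counts, n_draws=8000, seed=1)
        c2 = binomial_posterior(counts, n_draws=8000, seed=2)
        diff = difference_posterior(c1, c2)
        assert np.all(np.abs(diff.q - 0.5) < 0.05)
        assert np.all(diff.p > 0.9)

    def test_separated_curves_give_p_zero(self, rng):
        near = bin_cumulative(rng.uniform(0, 100, 2000), 50, 500)
        far = bin_cumulative(rng.uniform(400, 500, 2000), 50, 500)
        cr = binomial_posterior(near, n_draws=5000, seed=3)
        cg = binomial_posterior(far, n_draws=5000, seed=4)
        diff = difference_posterior(cr, cg)
        assert diff.q[0] == 1.0 and diff.p[0] == 0.0

    def test_mismatched_edges_raise(self, rng):
        d = rng.uniform(0, 500, 100)
        c1 = binomial_posterior(bin_cumulative(d, 50, 500), n_draws=1000, seed=5)
        c2 = binomial_posterior(bin_cumulative(d, 100, 500), n_draws=1000, seed=6)
        with pytest.raises(ValueError):
            difference_posterior(c1, c2)


class TestLocateCrossover:
    def test_unambiguous_descending_crossover(self):
        diff = make_diff([0.3, 0.3, -0.3, -0.3], [0.01] * 4)
        assert locate_crossover(diff) == 2  # third bin, 0-based

    def test_conservative_rule_prefers_shorter_distance(self):
        # median crosses in the last bin, but HDIs overlap zero from bin 2
        diff = make_diff([0.3, 0.01, 0.01, -0.3], [0.02] * 4)
        assert locate_crossover(diff) == 1

    def test_all_positive_tight_means_no_crossover(self):
        diff = make_diff([0.3, 0.3, 0.3, 0.2], [0.01] * 4)
        assert locate_crossover(diff) is None

    def test_no_separation_means_no_crossover(self):
        diff = make_diff([0.005, -0.005, 0.004, -0.002], [0.05] * 4)
        assert locate_crossover(diff) is None

    def test_conservative_never_longer_than_unambiguous(self):
        # randomized separated-then-converging patterns
        rng = np.random.default_rng(11)
        for trial in range(30):
            k = rng.integers(5, 30)
            cross = rng.integers(2, k)
            means = np.where(np.arange(k) < cross, 0.3, -0.3).astype(float)
            widen = rng.integers(1, cross + 1)  # bins with HDIs overlapping 0
            sds = np.full(k, 0.01)
            sds[cross - widen : cross] = 0.5
            diff = make_diff(means, sds, seed=100 + trial)
            med = diff.median
            sep = diff.q >= 1.0
            if not sep.any():
                continue
            first_sep = np.argmax(sep)
            unambiguous = next(
                (
                    i
                    for i in range(first_sep + 1, k)
                    if med[i] <= 0 < med[i - 1]
                ),
                None,
            )
            got = locate_crossover(diff)
            if unambiguous is not None and got is not None:
                assert got <= unambiguous


class TestEstimateThreshold:
    def test_single_weighted_bin(self):
        # one straddling bin centred at 300 m among decisive bins
        means = [0.3] * 29 + [0.0] + [-0.3] * 10
        sds = [0.001] * 29 + [0.05] + [0.001] * 10
        diff = make_diff(means, sds)
        est = estimate_threshold(diff, seed=1)
        assert est.detected
        assert est.t_median == pytest.approx(295.0, abs=5.0)
        assert est.hdi_high - est.hdi_low <= 10.0

    def test_symmetric_weights_average_to_midpoint(self):
        # straddling bins centred at 395 and 595, decisive in between
        means = np.full(60, 0.3)
        sds = np.full(60, 0.001)
        means[39], sds[39] = 0.0, 0.05
        means[59], sds[59] = 0.0, 0.05
        diff = make_diff(list(means), list(sds))
        est = estimate_threshold(diff, window_m=500.0, seed=2)
        assert est.point_estimate == pytest.approx(495.0, abs=5.0)

    def test_no_crossover_returns_undetected(self):
        diff = make_diff([0.3, 0.3, 0.3], [0.01] * 3)
        est = estimate_threshold(diff, seed=3)
        assert not est.detected
        assert np.isnan(est.t_median)

    def test_recovery_of_hard_threshold(self):
        lc = recovery_landscape(seed=77)
        layers = generate_features(lc)
        fence = layers[0]
        animals = simulate_animal_locations(
            layers, lc.avoidance_profile, lc.n_animals, lc.extent, seed=78
        )
        rand = generate_random_points(lc.extent, lc.n_random, seed=79)
        res = AvoidanceThresholdModel(
            fence.distances(animals.x, animals.y),
            fence.distances(rand.x, rand.y),
            bin_width_m=10.0,
            feature="fence",
        ).fit(seed=80)
        assert res.detected
        assert abs(res.t_median - 500.0) <= 100.0
        assert res.estimate.minimum_observed_m >= 500.0

    def test_null_landscape_undetected(self):
        lc = recovery_landscape(seed=81)
        layers = generate_features(lc)
        fence = layers[0]
        animals = simulate_animal_locations(layers, {}, lc.n_animals, lc.extent, seed=82)
        rand = generate_random_points(lc.extent, lc.n_random, seed=83)
        res = AvoidanceThresholdModel(
            fence.distances(animals.x, animals.y),
            fence.distances(rand.x, rand.y),
            bin_width_m=10.0,
        ).fit(seed=84)
        assert not res.detected

    def test_summary_mentions_detection(self):
        lc = recovery_landscape(seed=85, n_animals=100, n_random=500)
        layers = generate_features(lc)
        fence = layers[0]
        animals = simulate_animal_locations(
            layers, lc.avoidance_profile, 100, lc.extent, seed=86
        )
        rand = generate_random_points(lc.extent, 500, seed=87)
        res = AvoidanceThresholdModel(
            fence.distances(animals.x, animals.y), fence.distances(rand.x, rand.y)
        ).fit(seed=88)
        text = res.summary()
        assert "threshold" in text.lower()
        assert "detected" in text.lower()


class TestClassifyHypotheses:
    @staticmethod
    def est(detected, lo=np.nan, hi=np.nan):
        return ThresholdEstimate(
            feature="f",
            detected=detected,
            t_median=(lo + hi) / 2 if detected else np.nan,
            hdi_low=lo,
            hdi_high=hi,
        )

    def test_none_detected_is_h1(self):
        report = classify_hypotheses({"a": self.est(False), "b": self.est(False)})
        assert report["supported"] == "H1"

    def test_all_overlapping_is_h2(self):
        report = classify_hypotheses(
            {"a": self.est(True, 400, 600), "b": self.est(True, 500, 700)}
        )
        assert report["supported"] == "H2"

    def test_disjoint_is_h3(self):
        report = classify_hypotheses(
            {"a": self.est(True, 100, 200), "b": self.est(True, 500, 700)}
        )
        assert report["supported"] == "H3"

    def test_mixed_detection_is_h3(self):
        report = classify_hypotheses(
            {"a": self.est(True, 400, 600), "b": self.est(False)}
        )
        assert report["supported"] == "H3"
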