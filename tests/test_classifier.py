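"""Tests for the shrunken-centroid classifier: feature mapping, training,
shrinkage limits, scoring against brute-force oracles, and cohort calls."""

import numpy as np
import pandas as pd
import pytest

import brcalike as bl
from brcalike import classifier as clf
from brcalike.study import profile_from_signal, reference_feature_grid


def toy_model(centroid_pos, centroid_neg, sd, s0=0.5, priors=(0.5, 0.5),
              threshold=0.63):
    p = len(centroid_pos)
    grid = pd.DataFrame({"chrom": ["1"] * p,
                         "start": np.arange(p) * 10,
                         "end": np.arange(p) * 10 + 10})
    return clf.CentroidModel(
        feature_grid=grid,
        overall_centroid=(np.asarray(centroid_pos) + np.asarray(centroid_neg)) / 2,
        class_centroids={bl.BRCA1_LIKE: np.asarray(centroid_pos, dtype=float),
                         bl.NON_BRCA1_LIKE: np.asarray(centroid_neg, dtype=float)},
        pooled_sd=np.asarray(sd, dtype=float),
        s0=s0, delta=0.0,
        priors={bl.BRCA1_LIKE: priors[0], bl.NON_BRCA1_LIKE: priors[1]},
        threshold=threshold,
    )


def planted_two_class_data(n_per_class, n_features, n_planted, shift, sd, seed):
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    X = rng.normal(0.0, sd, size=(n, n_features))
    X[:n_per_class, :n_planted] += shift
    y = np.array([bl.BRCA1_LIKE] * n_per_class + [bl.NON_BRCA1_LIKE] * n_per_class)
    return X, y


class TestFeatureMapping:
    def test_identity_grid_returns_profile_ratios(self, small_bins):
        signal = np.random.default_rng(0).normal(0, 0.3, len(small_bins))
        profile = profile_from_signal(small_bins, signal,
                                      included=np.ones(len(small_bins), dtype=bool))
        grid = small_bins[["chrom", "start", "end"]]
        values = clf.map_to_feature_grid(profile, grid)
        np.testing.assert_allclose(values, signal)

    def test_feature_spanning_two_bins_takes_mean(self, small_bins):
        signal = np.zeros(len(small_bins))
        signal[0], signal[1] = 0.2, 0.4
        profile = profile_from_signal(small_bins, signal,
                                      included=np.ones(len(small_bins), dtype=bool))
        grid = pd.DataFrame({"chrom": ["1"], "start": [0], "end": [40_000]})
        assert clf.map_to_feature_grid(profile, grid)[0] == pytest.approx(0.3)

    def test_mostly_missing_profile_rejected(self, small_bins):
        included = np.zeros(len(small_bins), dtype=bool)
        included[:200] = True  # only chromosome-1 head retains bins
        profile = profile_from_signal(small_bins, np.zeros(len(small_bins)),
                                      included=included)
        grid = reference_feature_grid(small_bins)
        with pytest.raises(ValueError, match="quality insufficient"):
            clf.map_to_feature_grid(profile, grid)

    def test_missing_features_imputed_with_overall_centroid(self, small_bins):
        included = np.ones(len(small_bins), dtype=bool)
        included[:5] = False
        profile = profile_from_signal(small_bins, np.full(len(small_bins), 0.7),
                                      included=included)
        grid = reference_feature_grid(small_bins)
        overall = np.full(len(grid), -0.25)
        values = clf.map_to_feature_grid(profile, grid, overall_centroid=overall)
        assert values[0] == pytest.approx(-0.25)  # fully-missing first feature
        assert values[-1] == pytest.approx(0.7)


class TestTraining:
    def test_delta_zero_gives_unshrunken_class_means(self):
        X, y = planted_two_class_data(10, 20, 5, 1.0, 0.3, seed=1)
        model = clf.train(X, y, delta_grid=[0.0], cv_folds=3, seed=0)
        for lab in (bl.BRCA1_LIKE, bl.NON_BRCA1_LIKE):
            np.testing.assert_allclose(model.class_centroids[lab],
                                       X[y == lab].mean(axis=0), atol=1e-12)

    def test_full_shrinkage_collapses_to_overall_centroid_and_prior(self):
        X, y = planted_two_class_data(10, 20, 5, 1.0, 0.3, seed=2)
        model = clf.train(X, y, delta_grid=[1e6], cv_folds=3, seed=0,
                          priors={bl.BRCA1_LIKE: 0.3, bl.NON_BRCA1_LIKE: 0.7})
        for lab in model.labels:
            np.testing.assert_allclose(model.class_centroids[lab],
                                       model.overall_centroid, atol=1e-12)
        result = clf.score(model, np.random.default_rng(0).normal(size=20))
        assert result.score == pytest.approx(0.3, abs=1e-9)

    def test_single_class_rejected(self):
        X = np.random.default_rng(3).normal(size=(12, 5))
        with pytest.raises(ValueError, match="single class"):
            clf.train(X, np.array([bl.BRCA1_LIKE] * 12))

    def test_small_class_rejected(self):
        X = np.random.default_rng(4).normal(size=(8, 5))
        y = np.array([bl.BRCA1_LIKE] * 4 + [bl.NON_BRCA1_LIKE] * 4)
        with pytest.raises(ValueError, match="fewer than 5"):
            clf.train(X, y)

    def test_well_separated_classes_have_high_cv_accuracy(self):
        """Separation chosen so nearest-mean classification is near-perfect."""
        X, y = planted_two_class_data(40, 200, 30, 1.0, 0.3, seed=5)
        model = clf.train(X, y, cv_folds=5, seed=0)
        # refit-free check: training-set accuracy of the returned model
        correct = sum(clf.score(model, x).label == lab for x, lab in zip(X, y))
        assert correct / len(y) >= 0.95

    def test_planted_features_recovered_with_high_precision(self):
        X, y = planted_two_class_data(40, 200, 30, 1.0, 0.3, seed=6)
        model = clf.train(X, y, cv_folds=5, seed=0)
        diff = np.abs(model.class_centroids[bl.BRCA1_LIKE] - model.overall_centroid)
        surviving = np.flatnonzero(diff > 0)
        assert len(surviving) > 0
        precision = np.mean(surviving < 30)
        assert precision >= 0.8


class TestScoring:
    def test_posteriors_sum_to_one(self):
        model = toy_model([1.0, 0.0, -1.0], [-1.0, 0.5, 1.0], [0.4, 0.4, 0.4])
        rng = np.random.default_rng(7)
        for _ in range(20):
            post = clf.posteriors(model, rng.normal(size=3))
            assert sum(post.values()) == pytest.approx(1.0, abs=1e-9)
            assert all(0.0 <= v <= 1.0 for v in post.values())

    def test_score_at_own_centroid_dominates(self):
        model = toy_model([1.0, 1.0, 1.0], [-1.0, -1.0, -1.0], [0.3, 0.3, 0.3])
        assert clf.score(model, np.array([1.0, 1.0, 1.0])).score > 0.5

    def test_brute_force_discriminant_oracle(self):
        """Score equals direct evaluation of both class discriminants."""
        model = toy_model([0.8, -0.2, 0.1], [-0.5, 0.4, 0.0], [0.3, 0.5, 0.2],
                          s0=0.25, priors=(0.6, 0.4))
        rng = np.random.default_rng(8)
        for _ in range(50):
            x = rng.normal(size=3)
            d = {}
            for lab in model.labels:
                c = model.class_centroids[lab]
                d[lab] = sum(
                    (x[k] - c[k]) ** 2 / (model.pooled_sd[k] + model.s0) ** 2
                    for k in range(3)
                ) - 2.0 * np.log(model.priors[lab])
            expected = np.exp(-d[bl.BRCA1_LIKE] / 2) / (
                np.exp(-d[bl.BRCA1_LIKE] / 2) + np.exp(-d[bl.NON_BRCA1_LIKE] / 2)
            )
            assert clf.score(model, x).score == pytest.approx(expected, abs=1e-12)

    def test_threshold_tie_goes_to_brca1_like(self):
        assert clf.label_for_score(0.63) == bl.BRCA1_LIKE
        assert clf.label_for_score(0.6299999) == bl.NON_BRCA1_LIKE
        assert clf.label_for_score(1.0) == bl.BRCA1_LIKE

    def test_misaligned_vector_rejected(self):
        model = toy_model([1.0, 0.0], [-1.0, 0.0], [0.3, 0.3])
        with pytest.raises(ValueError, match="align"):
            clf.score(model, np.zeros(5))

    def test_nearest_centroid_oracle_equivalence(self):
        """With delta=0 and equal priors, labels match a diagonal-Mahalanobis
        nearest-centroid rule (threshold at 0.5) on random toy instances."""
        rng = np.random.default_rng(9)
        model = toy_model(rng.normal(size=6), rng.normal(size=6),
                          rng.uniform(0.2, 0.8, size=6), threshold=0.5)
        for _ in range(200):
            x = rng.normal(scale=1.5, size=6)
            dists = {
                lab: np.sum((x - c) ** 2 / (model.pooled_sd + model.s0) ** 2)
                for lab, c in model.class_centroids.items()
            }
            oracle = min(dists, key=dists.get)
            assert clf.score(model, x).label == oracle

    def test_score_monotone_along_centroid_segment(self):
        rng = np.random.default_rng(10)
        model = toy_model(rng.normal(size=8), rng.normal(size=8),
                          rng.uniform(0.2, 0.6, size=8))
        c_neg = model.class_centroids[bl.NON_BRCA1_LIKE]
        c_pos = model.class_centroids[bl.BRCA1_LIKE]
        scores = [clf.score(model, c_neg + t * (c_pos - c_neg)).score
                  for t in np.linspace(0, 1, 21)]
        assert np.all(np.diff(scores) >= -1e-12)


class TestCohort:
    def test_empty_cohort(self):
        model = toy_model([1.0], [-1.0], [0.3])
        results, failures, summary = clf.classify_cohort(model, {})
        assert results == [] and failures == {} and summary.empty

    def test_identical_profiles_get_identical_labels(self, small_bins):
        grid = reference_feature_grid(small_bins)
        p = len(grid)
        rng = np.random.default_rng(11)
        model = clf.train(*planted_two_class_data(10, p, 20, 1.0, 0.3, seed=12),
                          feature_grid=grid, delta_grid=[0.0], cv_folds=3)
        signal = rng.normal(0, 0.3, len(small_bins))
        profile = profile_from_signal(small_bins, signal,
                                      included=np.ones(len(small_bins), dtype=bool))
        results, failures, summary = clf.classify_cohort(
            model, {"a": profile, "b": profile, "c": profile})
        assert len({r.label for r in results}) == 1
        assert not failures

    def test_failures_recorded_not_raised(self, small_bins):
        grid = reference_feature_grid(small_bins)
        model = clf.train(*planted_two_class_data(10, len(grid), 20, 1.0, 0.3, seed=13),
                          feature_grid=grid, delta_grid=[0.0], cv_folds=3)
        good = profile_from_signal(small_bins, np.zeros(len(small_bins)),
                                   included=np.ones(len(small_bins), dtype=bool))
        bad = profile_from_signal(small_bins, np.zeros(len(small_bins)),
                                  included=np.zeros(len(small_bins), dtype=bool))
        results, failures, summary = clf.classify_cohort(model, {"ok": good, "bad": bad})
        assert [r.sample_id for r in results] == ["ok"]
        assert "bad" in failures and "quality" in failures["bad"]
        assert summary["n"].sum() == 1
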