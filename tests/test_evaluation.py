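import itertools
import math

import numpy as np
import pandas as pd
import pytest

from hmboost.evaluation import (
    ConfusionCounts,
    compare_gene_sets,
    compare_to_control,
    cross_validate,
    evaluate_external_geneset,
    kfold,
    metrics,
    profile_correlation,
    replicate_experiment,
    selection_share,
    significance_band,
    truncate2,
)


class TestMetrics:
    def test_perfect_classifier(self):
        assert metrics(ConfusionCounts(10, 0, 5, 0)) == (1.0, 1.0, 1.0)

    def test_published_cluster_overlap_triple(self):
        """Overlap of 66 between a 392-gene cluster and a 454-gene truth set
        renders as 0.14 / 0.16 / 0.15 under two-decimal truncation."""
        sn, ppv, f = metrics(ConfusionCounts(TP=66, FP=326, TN=0, FN=388))
        assert sn == pytest.approx(0.1454, abs=1e-4)
        assert ppv == pytest.approx(0.1684, abs=1e-4)
        assert f == pytest.approx(0.1561, abs=1e-4)
        assert (truncate2(sn), truncate2(ppv), truncate2(f)) == (0.14, 0.16, 0.15)

    def test_all_wrong(self):
        assert metrics(ConfusionCounts(0, 5, 0, 5)) == (0.0, 0.0, 0.0)

    def test_undefined_denominators_are_nan_not_zero(self):
        sn, ppv, f = metrics(ConfusionCounts(0, 0, 10, 0))
        assert math.isnan(sn) and math.isnan(ppv) and math.isnan(f)

    def test_direct_formula_oracle_over_small_counts(self):
        """metrics equals the printed formulas on all counts <= 20."""
        for tp, fp, fn in itertools.product(range(0, 21, 4), repeat=3):
            sn, ppv, f = metrics(ConfusionCounts(tp, fp, 3, fn))
            if tp + fn > 0:
                assert sn == tp / (tp + fn)
            else:
                assert math.isnan(sn)
            if tp + fp > 0:
                assert ppv == tp / (tp + fp)
            else:
                assert math.isnan(ppv)
            if tp + fn > 0 and tp + fp > 0:
                expect = 0.0 if sn + ppv == 0 else 2 * sn * ppv / (sn + ppv)
                assert f == pytest.approx(expect)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)


def test_truncation_not_rounding():
    assert truncate2(0.1684) == 0.16
    assert truncate2(0.999) == 0.99
    assert truncate2(0.1561) == 0.15


def test_selection_share_renders_13_of_15_as_87_percent():
    assert selection_share(13, 15) == 87


class TestKFold:
    def test_sizes_and_coverage(self):
        y = np.array([1] * 5 + [-1] * 5)
        folds = kfold(y, k=5, seed=0)
        assert sorted(len(f) for f in folds) == [2] * 5
        assert sorted(np.concatenate(folds)) == list(range(10))

    def test_stratification(self):
        y = np.array([1] * 10 + [-1] * 10)
        for fold in kfold(y, k=5, seed=1):
            assert sorted(y[fold]) == [-1, -1, 1, 1]

    def test_seed_determinism(self):
        y = np.array([1, -1] * 10)
        a = kfold(y, seed=3)
        b = kfold(y, seed=3)
        assert all((x == z).all() for x, z in zip(a, b))

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            kfold(np.array([1, -1]), k=5)


def _planted(n=100, f=20.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.poisson(3.0, size=(n, 6)).astype(float)
    y = np.concatenate([np.ones(n // 2), -np.ones(n // 2)])
    X[: n // 2, 2] += rng.poisson(f, size=n // 2)
    cols = [f"m{i}:+1" for i in range(6)]
    return pd.DataFrame(X, columns=cols, index=[f"g{i}" for i in range(n)]), y


class TestCrossValidate:
    def test_separable_data_mean_f_near_one(self):
        X, y = _planted()
        res = cross_validate(X, y, k=5, seed=0, rounds=20)
        assert res["fscore"] >= 0.95

    def test_each_sample_tested_once(self):
        X, y = _planted(n=40)
        res = cross_validate(X, y, rounds=5)
        pooled = res["pooled"]
        assert pooled.TP + pooled.FP + pooled.TN + pooled.FN == 40

    def test_shuffled_labels_give_chance_level(self):
        X, y = _planted(n=400)
        rng = np.random.default_rng(9)
        res = cross_validate(X, rng.permutation(y), k=5, seed=0, rounds=10)
        assert 0.35 <= res["fscore"] <= 0.65


@pytest.fixture(scope="module")
def tables():
    X, y = _planted(n=120, seed=4)
    return X[y == 1], X[y == -1]


class TestReplicateExperiment:

    def test_report_means_within_replicate_range(self, tables):
        pos, neg = tables
        rep = replicate_experiment(pos, neg, replicates=6, rounds=10, seed=0)
        assert rep.fscore.min() <= rep.fscore.mean() <= rep.fscore.max()
        s = rep.summary()
        assert 0 <= s["fscore"]["mean"] <= 1

    def test_planted_mark_is_modal_top_feature(self, tables):
        pos, neg = tables
        rep = replicate_experiment(pos, neg, replicates=10, rounds=10, seed=1)
        top = rep.top_feature_counts.most_common(1)[0][0]
        assert top == "m2:+1"

    def test_fixed_seed_reproducible(self, tables):
        pos, neg = tables
        a = replicate_experiment(pos, neg, replicates=4, rounds=8, seed=7)
        b = replicate_experiment(pos, neg, replicates=4, rounds=8, seed=7)
        assert (a.fscore == b.fscore).all()
        assert a.top_feature_counts == b.top_feature_counts

    def test_more_negatives_than_positives_required(self, tables):
        pos, neg = tables
        with pytest.raises(ValueError):
            replicate_experiment(neg, pos.iloc[: len(pos) // 2], replicates=2)


class TestCompareToControl:
    def make_report(self, fs):
        from hmboost.evaluation import ReplicateReport

        fs = np.asarray(fs, dtype=float)
        return ReplicateReport(sensitivity=fs, ppv=fs, fscore=fs)

    def test_identical_scores_p_is_one(self):
        r = self.make_report([0.5] * 10)
        p, band = compare_to_control(r, r)
        assert p == 1.0 and band == "+"

    def test_disjoint_ranges_extreme_p(self):
        hi = self.make_report(np.linspace(0.8, 0.95, 100))
        lo = self.make_report(np.linspace(0.4, 0.55, 100))
        p, band = compare_to_control(hi, lo)
        assert p < 1e-5 and band == ""

    def test_mismatched_replicates_rejected(self):
        with pytest.raises(ValueError):
            compare_to_control(self.make_report([0.5] * 3),
                               self.make_report([0.5] * 4))

    def test_band_thresholds(self):
        assert significance_band(1e-6) == ""
        assert significance_band(1e-3) == "*"
        assert significance_band(0.5) == "+"


class TestProfileCorrelation:
    def make(self, arr):
        return pd.DataFrame(arr, index=[f"g{i}" for i in range(len(arr))])

    def test_identical_profiles(self):
        a = self.make(np.random.default_rng(0).poisson(5, size=(5, 26)).astype(float))
        r, med = profile_correlation(a, a)
        assert np.allclose(r.dropna(), 1.0)
        assert med == pytest.approx(1.0)

    def test_negated_profiles(self):
        a = self.make(np.random.default_rng(1).normal(5, 2, size=(5, 26)))
        r, med = profile_correlation(a, -a)
        assert np.allclose(r, -1.0)

    def test_independent_noise_median_near_zero(self):
        rng = np.random.default_rng(2)
        a = self.make(rng.normal(size=(200, 26)))
        b = self.make(rng.normal(size=(200, 26)))
        _, med = profile_correlation(a, b)
        assert abs(med) < 0.1

    def test_constant_profiles_excluded(self):
        a = self.make(np.vstack([np.ones(26), np.arange(26.0)]))
        b = self.make(np.vstack([np.arange(26.0), np.arange(26.0)]))
        r, _ = profile_correlation(a, b)
        assert math.isnan(r.iloc[0]) and r.iloc[1] == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            profile_correlation(self.make(np.ones((2, 26))),
                                self.make(np.ones((2, 15))))


class TestCompareGeneSets:
    def test_clearly_shifted_sets(self):
        rng = np.random.default_rng(0)
        a = rng.normal(1.0, 0.1, 200)
        b = rng.normal(0.2, 0.1, 200)
        p, stars = compare_gene_sets(a, b)
        assert p < 1e-4 and stars == "**"

    def test_same_distribution_not_significant(self):
        rng = np.random.default_rng(1)
        p, stars = compare_gene_sets(rng.normal(size=50), rng.normal(size=50))
        assert stars in ("", "*")  # typically '' at matched distributions
        assert p > 1e-4

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            compare_gene_sets(np.array([]), np.array([1.0]))


class TestEvaluateExternalGeneset:
    def test_published_overlap_example(self):
        uni = {f"g{i}" for i in range(2000)}
        predicted = {f"g{i}" for i in range(392)}
        truth = {f"g{i}" for i in range(326, 780)}  # 454 genes, overlap 66
        res = evaluate_external_geneset(predicted, truth, uni)
        assert res["confusion"].TP == 66
        assert res["truncated"] == (0.14, 0.16, 0.15)

    def test_perfect_prediction(self):
        uni = {"a", "b", "c"}
        res = evaluate_external_geneset({"a", "b"}, {"a", "b"}, uni)
        assert (res["sensitivity"], res["ppv"], res["fscore"]) == (1, 1, 1)

    def test_disjoint_sets(self):
        uni = {"a", "b", "c", "d"}
        res = evaluate_external_geneset({"a"}, {"b"}, uni)
        assert (res["sensitivity"], res["ppv"], res["fscore"]) == (0, 0, 0)

    def test_sets_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            evaluate_external_geneset({"x"}, {"a"}, {"a"})
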