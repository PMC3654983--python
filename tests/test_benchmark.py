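"""Confusion metrics, ROC/AUC, precision-recall, rank-sum, bootstrap, enrichment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import prionscan as ps


class TestConfusionAndMetrics:
    def test_direct_counts(self):
        c = ps.confusion_at_cutoff([60, 40], [30, 55], 50)
        assert (c.TP, c.FN, c.FP, c.TN) == (1, 1, 1, 1)

    def test_cutoff_below_everything(self):
        c = ps.confusion_at_cutoff([60, 40], [30, 55], -10)
        assert c.FN == 0 and c.TN == 0

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            ps.confusion_at_cutoff([], [1.0], 0.0)

    def test_threshold_sweep_matches_brute_force(self):
        rng = np.random.default_rng(73)
        pos = rng.normal(1, 1, 40)
        neg = rng.normal(0, 1, 60)
        for cutoff in np.unique(np.concatenate([pos, neg])):
            c = ps.confusion_at_cutoff(pos, neg, cutoff)
            assert c.TP == sum(1 for x in pos if x >= cutoff)
            assert c.FP == sum(1 for x in neg if x >= cutoff)
            assert c.P == 40 and c.N == 60

    def test_metric_formulas(self):
        m = ps.metrics(ps.ConfusionCounts(TP=8, FN=2, FP=1, TN=9))
        assert m.tpr == 0.8
        assert m.fpr == pytest.approx(0.1)
        assert m.accuracy == 0.85
        assert m.precision == pytest.approx(8 / 9)
        assert m.fdr == pytest.approx(1 / 9)

    def test_undefined_ratios_are_nan_not_errors(self):
        m = ps.metrics(ps.ConfusionCounts(TP=0, FP=0, TN=5, FN=5))
        assert np.isnan(m.precision) and np.isnan(m.fdr)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 500)] * 4))
    def test_precision_plus_fdr_is_one(self, tpfp):
        tp, fp, tn, fn = tpfp
        m = ps.metrics(ps.ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn))
        if tp + fp > 0:
            assert m.precision + m.fdr == pytest.approx(1.0, abs=1e-12)


class TestROC:
    def test_perfect_separation(self):
        assert ps.roc_curve([2, 3], [0, 1]).auc == 1.0

    def test_pair_counting_example(self):
        # 3 of the 4 (pos, neg) pairs are correctly ordered
        assert ps.roc_curve([2, 4], [1, 3]).auc == pytest.approx(0.75)

    def test_identical_scores_give_diagonal(self):
        curve = ps.roc_curve([5.0, 5.0], [5.0, 5.0, 5.0])
        assert curve.auc == pytest.approx(0.5)

    def test_staircase_monotone_between_corners(self):
        rng = np.random.default_rng(79)
        curve = ps.roc_curve(rng.normal(1, 1, 30), rng.normal(0, 1, 50))
        assert curve.fpr[0] == 0 and curve.tpr[0] == 0
        assert curve.fpr[-1] == 1 and curve.tpr[-1] == 1
        assert np.all(np.diff(curve.fpr) >= 0)
        assert np.all(np.diff(curve.tpr) >= 0)

    def test_shuffled_labels_give_half(self):
        rng = np.random.default_rng(83)
        scores = rng.normal(size=10_000)
        labels = rng.random(10_000) < 0.5
        auc = ps.roc_curve(scores[labels], scores[~labels]).auc
        assert auc == pytest.approx(0.5, abs=0.02)


class TestAucRankSumEquivalence:
    def test_random_and_tied_datasets(self):
        rng = np.random.default_rng(89)
        for _ in range(100):
            n, m = rng.integers(2, 40, 2)
            if rng.random() < 0.5:
                pos = rng.normal(0.5, 1, n)
                neg = rng.normal(0, 1, m)
            else:  # heavy ties: three distinct values only
                pos = rng.choice([0.0, 1.0, 2.0], n)
                neg = rng.choice([0.0, 1.0, 2.0], m)
            auc, u_nm = ps.auc_equals_rank_sum_check(pos, neg)
            assert abs(auc - u_nm) < 1e-12

    def test_single_pair(self):
        auc, u_nm = ps.auc_equals_rank_sum_check([2.0], [1.0])
        assert auc == 1.0 and u_nm == 1.0


class TestPrecisionRecall:
    def test_perfect_separation_has_unit_precision(self):
        recall, precision, _ = ps.precision_recall_curve([5, 6, 7], [1, 2, 3])
        assert np.all(precision == 1.0)

    def test_skewed_dataset_matches_threshold_sweep(self):
        rng = np.random.default_rng(97)
        neg = rng.normal(0, 1, 5300)
        pos = rng.normal(3, 1, 10)
        recall, precision, thresholds = ps.precision_recall_curve(pos, neg)
        assert len(recall) == len(precision) == len(thresholds)
        assert np.all(np.isfinite(precision))
        # brute-force check at every threshold, including recall >= 0.9
        for thr, r, pr in zip(thresholds, recall, precision):
            tp = np.sum(pos >= thr)
            fp = np.sum(neg >= thr)
            assert r == pytest.approx(tp / pos.size)
            assert pr == pytest.approx(tp / (tp + fp))
        assert np.any(recall >= 0.9)

    def test_more_negatives_lower_precision_at_fixed_recall(self):
        rng = np.random.default_rng(101)
        pos = rng.normal(2, 1, 50)
        neg_small = rng.normal(0, 1, 500)
        neg_big = np.concatenate([neg_small, rng.normal(0, 1, 4500)])

        def precision_at(recall_level, neg):
            r, p, _ = ps.precision_recall_curve(pos, neg)
            return p[np.argmax(r >= recall_level)]

        assert precision_at(0.8, neg_big) < precision_at(0.8, neg_small)


class TestAccuracyVsCutoff:
    def test_perfect_separation_reaches_one(self):
        tab, best = ps.accuracy_vs_cutoff([10, 11], [1, 2], np.arange(0, 15, 1.0))
        assert tab[:, 1].max() == 1.0
        assert 2 < best <= 10

    def test_ties_broken_toward_largest_cutoff(self):
        tab, best = ps.accuracy_vs_cutoff([10.0], [0.0], np.arange(1.0, 10.0))
        assert np.all(tab[:, 1] == 1.0)
        assert best == 9.0

    def test_single_point_grid(self):
        _, best = ps.accuracy_vs_cutoff([1.0], [0.0], np.array([42.0]))
        assert best == 42.0

    def test_calibration_regime_concentrates_near_fifty(self):
        rng = np.random.default_rng(103)
        grid = np.arange(0, 100.5, 0.5)
        hits = 0
        for _ in range(50):
            pos = rng.normal(55, 5, 18)
            neg = rng.normal(20, 10, 18)
            _, best = ps.accuracy_vs_cutoff(pos, neg, grid)
            hits += 40 <= best <= 60
        assert hits >= 47


class TestRankSumTest:
    def test_exact_complete_reversal(self):
        u, p, method = ps.rank_sum_test([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert method == "exact"
        assert p == pytest.approx(0.1)

    def test_identical_multisets_have_no_signal(self):
        u, p, method = ps.rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p > 0.85  # ties force the asymptotic path; p is near 1

    def test_large_samples_use_asymptotic(self):
        rng = np.random.default_rng(107)
        u, p, method = ps.rank_sum_test(rng.normal(1, 1, 100), rng.normal(0, 1, 100))
        assert method == "asymptotic"
        assert p < 1e-6

    def test_null_pvalues_are_uniform(self):
        rng = np.random.default_rng(109)
        pvals = []
        for _ in range(400):
            p = ps.rank_sum_test(rng.normal(size=250), rng.normal(size=250))[1]
            pvals.append(p)
        ks = stats.kstest(pvals, "uniform").statistic
        assert ks < 0.07


def identity_scorer(train_records):
    return lambda records: np.asarray(records, dtype=float)


class TestBootstrapRoc:
    def test_single_iteration_matches_hand_trace(self):
        positives = [10.0, 20.0, 30.0, 40.0]
        negatives = [1.0, 2.0]
        res = ps.bootstrap_roc(
            positives, negatives, identity_scorer, n_iterations=1, seed=0
        )
        perm = np.random.default_rng(0).permutation(4)
        test_half = [positives[i] for i in perm[2:]]
        expect = ps.roc_curve(np.array(test_half), np.array(negatives))
        assert res.auc_samples[0] == expect.auc == 1.0
        assert res.mean_auc == 1.0

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(113)
        positives = list(rng.normal(2, 1, 8))
        negatives = list(rng.normal(0, 1, 10))
        a = ps.bootstrap_roc(positives, negatives, identity_scorer, 50, seed=5)
        b = ps.bootstrap_roc(positives, negatives, identity_scorer, 50, seed=5)
        assert np.array_equal(a.auc_samples, b.auc_samples)
        assert np.array_equal(a.mean_tpr, b.mean_tpr)

    def test_mean_curve_dominates_diagonal_when_separated(self):
        rng = np.random.default_rng(127)
        positives = list(rng.normal(4, 1, 10))
        negatives = list(rng.normal(0, 1, 12))
        res = ps.bootstrap_roc(positives, negatives, identity_scorer, 200, seed=6)
        assert np.all(res.mean_tpr >= res.fpr_grid - 1e-9)
        assert res.mean_auc == pytest.approx(np.mean(res.auc_samples))

    def test_held_out_auc_not_better_than_full_training(self, proline_model):
        pos, neg, _ = ps.make_benchmark_sets(n_pos=8, n_neg=12, seed=131)
        cfg = ps.ScanConfig()

        def build_scorer(train_records):
            t = ps.train_table(train_records)
            return lambda records: np.array(
                [ps.best_score(r, t, proline_model, cfg) for r in records]
            )

        full_scores = build_scorer(pos)
        full_auc = ps.roc_curve(full_scores(pos), full_scores(neg)).auc
        res = ps.bootstrap_roc(pos, neg, build_scorer, n_iterations=30, seed=7)
        assert res.mean_auc <= full_auc + 0.02

    def test_odd_positive_count_rejected(self):
        with pytest.raises(ValueError, match="even"):
            ps.bootstrap_roc([1.0, 2.0, 3.0], [0.0], identity_scorer, 10, seed=1)


class TestEnrichment:
    def test_concentrated_selection_matches_hypergeometric(self):
        universe = {
            f"i{k}": (["hit"] if k < 100 else ["other"]) for k in range(1000)
        }
        selection = [f"i{k}" for k in range(50)]
        results = {
            r.category: r
            for r in ps.enrichment_zscores(universe, selection, 10_000, seed=8)
        }
        hit = results["hit"]
        assert hit.observed == 50
        # hypergeometric: mean 5, sd ~2.06 -> z ~21.8
        assert hit.null_mean == pytest.approx(5.0, rel=0.1)
        assert hit.z == pytest.approx(21.8, rel=0.1)

    def test_zero_spread_category_gets_nan(self):
        universe = {f"i{k}": ["all"] + (["half"] if k < 25 else []) for k in range(50)}
        selection = [f"i{k}" for k in range(49)]
        results = {r.category: r for r in ps.enrichment_zscores(universe, selection, 200, seed=9)}
        assert np.isnan(results["all"].z)  # every draw of 49 contains 49 members
        assert np.isfinite(results["half"].z)

    def test_random_selection_is_unenriched(self):
        rng = np.random.default_rng(137)
        cats = [f"c{j}" for j in range(20)]
        universe = {f"i{k}": [cats[k % 20]] for k in range(1000)}
        selection = [f"i{k}" for k in rng.choice(1000, 60, replace=False)]
        results = ps.enrichment_zscores(universe, selection, 2000, seed=10)
        z = np.array([r.z for r in results])
        assert np.sum(np.abs(z) < 3) >= 19

    def test_selection_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="not in universe"):
            ps.enrichment_zscores({"a": ["x"]}, ["b"], 100, seed=1)

    def test_too_few_randomizations_rejected(self):
        with pytest.raises(ValueError):
            ps.enrichment_zscores({"a": ["x"]}, ["a"], 10, seed=1)
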