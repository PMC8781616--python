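"""Confusion metrics, ROC/AUC, cross-validation and significance tests.

AUC oracle: the probability that a random positive outscores a random
negative (ties counted half), computed by brute-force pair enumeration.
"""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hhtecg as hg


def auc_by_pair_enumeration(scores, truth) -> float:
    pos = [s for s, t in zip(scores, truth) if t == 1]
    neg = [s for s, t in zip(scores, truth) if t == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in product(pos, neg))
    return wins / (len(pos) * len(neg))


class TestConfusionMetrics:
    def test_hand_counts(self):
        m = hg.confusion_metrics(hg.ConfusionCounts(tp=9, fn=1, fp=2, tn=8))
        assert (m.accuracy, m.sensitivity, m.specificity) == (0.85, 0.90, 0.80)

    def test_perfect_classifier(self):
        m = hg.confusion_metrics(hg.ConfusionCounts(tp=5, fn=0, fp=0, tn=5))
        assert (m.accuracy, m.sensitivity, m.specificity) == (1.0, 1.0, 1.0)

    def test_zero_denominator_flagged_not_nan(self):
        m = hg.confusion_metrics(hg.ConfusionCounts(tp=0, fn=0, fp=2, tn=8))
        assert m.sensitivity is None
        assert "sensitivity" in m.undefined
        assert m.accuracy == 0.8

    @given(
        tp=st.integers(0, 20), fn=st.integers(0, 20),
        fp=st.integers(0, 20), tn=st.integers(0, 20),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_accuracy_is_prevalence_weighted_mean(self, tp, fn, fp, tn):
        if tp + fn == 0 or fp + tn == 0:
            return
        m = hg.confusion_metrics(hg.ConfusionCounts(tp=tp, fn=fn, fp=fp, tn=tn))
        P, N = tp + fn, fp + tn
        assert m.accuracy == pytest.approx(
            (m.sensitivity * P + m.specificity * N) / (P + N)
        )


class TestROC:
    def test_perfect_separation(self):
        r = hg.roc_auc(np.array([0.9, 0.8, 0.3, 0.1]), np.array([1, 1, 0, 0]))
        assert r.auc == 1.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0

    def test_uninformative_scores_near_half(self):
        rng = np.random.default_rng(0)
        truth = rng.integers(0, 2, 2000)
        r = hg.roc_auc(rng.random(2000), truth)
        assert r.auc == pytest.approx(0.5, abs=0.05)

    def test_one_class_truth_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            hg.roc_auc(np.array([0.1, 0.9]), np.array([1, 1]))

    def test_curve_monotone_and_anchored(self):
        rng = np.random.default_rng(1)
        r = hg.roc_auc(rng.random(50), rng.integers(0, 2, 50) | np.arange(50) % 2)
        fpr = [p[0] for p in r.curve]
        tpr = [p[1] for p in r.curve]
        assert fpr == sorted(fpr) and tpr == sorted(tpr)
        assert r.curve[0] == (0.0, 0.0) and r.curve[-1] == (1.0, 1.0)

    @given(seed=st.integers(0, 5000), n=st.integers(4, 50))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_auc_equals_concordant_pair_probability(self, seed, n):
        rng = np.random.default_rng(seed)
        scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)  # induce ties
        truth = rng.integers(0, 2, n)
        if truth.min() == truth.max():
            return
        r = hg.roc_auc(scores, truth)
        assert r.auc == pytest.approx(auc_by_pair_enumeration(scores, truth),
                                      abs=1e-12)


class TestCrossValidate:
    def test_fold_sizes_and_stratification(self, reference_model):
        feats = hg.simulate_features(reference_model, 60, seed=5)  # 300 records
        folds = hg.cross_validate(feats, hg.ModelConfig(method="nb"), k=5, seed=0)
        assert len(folds) == 5
        for f in folds:
            assert f.n_train == 240 and f.n_test == 60

    def test_input_order_invariance(self, reference_model):
        feats = hg.simulate_features(reference_model, 30, seed=5)
        shuffled = list(feats)
        np.random.default_rng(3).shuffle(shuffled)
        t1 = hg.mean_auc(hg.cross_validate(feats, hg.ModelConfig(method="nb"), seed=1))
        t2 = hg.mean_auc(hg.cross_validate(shuffled, hg.ModelConfig(method="nb"), seed=1))
        assert t1.equals(t2)

    def test_k_below_two_rejected(self, reference_features):
        with pytest.raises(ValueError, match="k"):
            hg.cross_validate(reference_features, hg.ModelConfig(), k=1)

    def test_class_smaller_than_k_rejected(self, reference_model):
        feats = hg.simulate_features(reference_model, 3, seed=0)
        with pytest.raises(ValueError, match="at least k"):
            hg.cross_validate(feats, hg.ModelConfig(), k=5)


class TestEvaluatePatterns:
    def test_report_shape_ten_pairs_plus_five_ovr(self, reference_features):
        reports = hg.evaluate_patterns(
            reference_features, reference_features, hg.ModelConfig(method="nb")
        )
        pairs = [r for r in reports if r.pattern[0] == "pair"]
        ovr = [r for r in reports if r.pattern[0] == "ovr"]
        assert len(pairs) == 10 and len(ovr) == 5

    def test_separable_fixture_all_auc_high(self, separable_features):
        reports = hg.evaluate_patterns(
            separable_features, separable_features,
            [hg.ModelConfig(method="nb"), hg.ModelConfig(method="svm")],
        )
        for rep in reports:
            for r in rep.results.values():
                assert r.auc >= 0.99

    def test_table_export_shape(self, reference_features):
        reports = hg.evaluate_patterns(
            reference_features, reference_features, hg.ModelConfig(method="nb")
        )
        table = hg.reports_to_table(reports)
        assert list(table.columns) == [
            "pattern", "method", "sensitivity", "specificity",
            "accuracy", "auc", "n_test",
        ]
        assert len(table) == 15


class TestPairwiseFeatureTest:
    def test_identical_groups_p_one(self):
        feats = [hg.FeatureRecord(np.arange(6), lab) for lab in (1, 1, 2, 2)]
        assert hg.pairwise_feature_test(feats, "f1_freq", 1, 2) == 1.0

    def test_overwhelming_separation(self):
        rng = np.random.default_rng(0)
        feats = [hg.FeatureRecord(rng.normal(0, 1, 6), 1) for _ in range(100)]
        feats += [hg.FeatureRecord(rng.normal(10, 1, 6), 2) for _ in range(100)]
        assert hg.pairwise_feature_test(feats, "f1_freq", 1, 2) < 0.001
        assert hg.pairwise_feature_test(
            feats, "f1_freq", 1, 2, method="mannwhitney"
        ) < 0.001

    def test_welch_statistic_matches_textbook_formula(self):
        xa = np.array([4.1, 4.5, 3.9, 4.3, 4.2])
        xb = np.array([3.1, 3.6, 3.3, 3.2, 3.5])
        feats = [hg.FeatureRecord(np.full(6, v), 1) for v in xa]
        feats += [hg.FeatureRecord(np.full(6, v), 2) for v in xb]
        p = hg.pairwise_feature_test(feats, "f1_freq", 1, 2)
        # hand computation: t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2), then the
        # two-sided p from the t distribution with Welch-Satterthwaite df
        from scipy.stats import t as tdist

        m1, m2 = xa.mean(), xb.mean()
        v1, v2 = xa.var(ddof=1) / 5, xb.var(ddof=1) / 5
        tstat = (m1 - m2) / np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / 4 + v2**2 / 4)
        expected = 2 * tdist.sf(abs(tstat), df)
        assert p == pytest.approx(expected, rel=1e-12)

    def test_full_significance_table_shape(self, reference_features):
        table = hg.feature_significance_table(reference_features)
        assert table.shape == (10, 7)
        assert ((table.drop(columns="pattern") >= 0)
                & (table.drop(columns="pattern") <= 1)).all().all()
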