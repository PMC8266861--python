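"""ROC/AUC, Youden thresholding, confusion metrics, LOO and clinical fusion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dcepcr.evaluation import (ModelSpec, PcrSvmClassifier, append_clinical,
                               confusion_metrics, evaluate_loo,
                               independent_eval, loo_scores, roc_auc,
                               subtype_stratified_eval, youden_threshold)
from dcepcr.synthetic import SyntheticCohortConfig, gen_feature_cohort


def auc_pair_count(scores, labels):
    """Oracle: concordant-pair fraction with half credit for ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def youden_enumeration(scores, labels):
    """Oracle: best J over an exhaustive sweep of thresholds."""
    best_j = -np.inf
    pos, neg = scores[labels == 1], scores[labels == 0]
    for t in np.concatenate([scores - 1e-9, scores + 1e-9,
                             [scores.min() - 1, scores.max() + 1]]):
        j = (pos >= t).mean() + (neg < t).mean() - 1
        best_j = max(best_j, j)
    return best_j


class TestRocAuc:
    def test_worked_example(self):
        _, auc = roc_auc(np.array([0.9, 0.4, 0.6, 0.1]), np.array([1, 1, 0, 0]))
        assert auc == pytest.approx(0.75)

    def test_separation_and_ties(self):
        assert roc_auc(np.array([3, 4, 1, 2.]), np.array([1, 1, 0, 0]))[1] == 1.0
        assert roc_auc(np.array([1, 1, 1, 1.]), np.array([1, 1, 0, 0]))[1] == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([1.0, 2.0]), np.array([1, 1]))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.normal(size=30), 1)  # rounding forces ties
        labels = np.zeros(30, int)
        labels[rng.choice(30, 12, replace=False)] = 1
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(auc_pair_count(scores, labels))


class TestYouden:
    def test_separable_gap_midpoint(self):
        thr = youden_threshold(np.array([3.0, 4.0, 1.0, 2.0]),
                               np.array([1, 1, 0, 0]))
        assert thr == pytest.approx(2.5)

    def test_tie_break_toward_specificity(self):
        scores = np.array([0.9, 0.4, 0.6, 0.1])
        labels = np.array([1, 1, 0, 0])
        thr = youden_threshold(scores, labels)
        assert 0.6 < thr < 0.9  # two J=0.5 candidates; pick the specific one
        m = confusion_metrics(scores, labels, thr)
        assert m["specificity"] == 100.0 and m["sensitivity"] == 50.0

    def test_uninformative_scores(self):
        scores = np.full(6, 2.0)
        labels = np.array([1, 1, 1, 0, 0, 0])
        thr = youden_threshold(scores, labels)
        m = confusion_metrics(scores, labels, thr)
        assert m["sensitivity"] / 100 + m["specificity"] / 100 - 1 == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_maximizes_over_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        scores = np.round(rng.normal(size=25), 1)
        labels = np.zeros(25, int)
        labels[rng.choice(25, 10, replace=False)] = 1
        thr = youden_threshold(scores, labels)
        pos, neg = scores[labels == 1], scores[labels == 0]
        j = (pos >= thr).mean() + (neg < thr).mean() - 1
        assert j == pytest.approx(youden_enumeration(scores, labels))


class TestConfusionMetrics:
    def test_worked_arithmetic(self):
        # TP=2, FP=1, TN=3, FN=0
        scores = np.array([0.9, 0.8, 0.7, 0.2, 0.1, 0.05])
        labels = np.array([1, 1, 0, 0, 0, 0])
        m = confusion_metrics(scores, labels, 0.5)
        assert m == {"accuracy": 83.3, "sensitivity": 100.0, "specificity": 75.0}

    def test_extreme_thresholds(self):
        scores = np.array([0.2, 0.8, 0.5])
        labels = np.array([1, 0, 1])
        lo = confusion_metrics(scores, labels, -10)
        hi = confusion_metrics(scores, labels, 10)
        assert lo["sensitivity"] == 100.0 and lo["specificity"] == 0.0
        assert hi["sensitivity"] == 0.0 and hi["specificity"] == 100.0

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=-3, max_value=3))
    def test_threshold_monotonicity(self, threshold):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=40)
        labels = (rng.random(40) < 0.4).astype(int)
        labels[:2], labels[-2:] = 1, 0
        m1 = confusion_metrics(scores, labels, threshold)
        m2 = confusion_metrics(scores, labels, threshold + 0.5)
        assert m2["sensitivity"] <= m1["sensitivity"]
        assert m2["specificity"] >= m1["specificity"]


class TestLoo:
    def test_separable_cohort_perfect_auc(self, planted_small):
        X, y, info = planted_small
        rep = evaluate_loo(X[:, sorted(info)], y)
        assert rep.auc == 1.0 and rep.accuracy == 100.0

    def test_deterministic(self, planted_small):
        X, y, info = planted_small
        s1 = loo_scores(X[:, :6], y)
        s2 = loo_scores(X[:, :6], y)
        assert np.array_equal(s1, s2)

    def test_order_invariance_of_scores(self, planted_small):
        # invariant up to the SVM solver tolerance (libsvm tol = 1e-3)
        X, y, _ = planted_small
        perm = np.random.default_rng(0).permutation(len(y))
        s = loo_scores(X[:, :6], y)
        sp = loo_scores(X[perm][:, :6], y[perm])
        assert np.allclose(np.sort(s), np.sort(sp), atol=1e-3)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            loo_scores(np.zeros((4, 2)), np.array([1, 1, 1, 1]))


class TestIndependent:
    def test_resubstitution_on_separable(self, planted_small):
        X, y, info = planted_small
        Xs = X[:, sorted(info)]
        rep = independent_eval(Xs, y, Xs, y)
        assert rep.accuracy == 100.0 and rep.auc == 1.0

    def test_empty_feature_matrix_rejected(self, planted_small):
        X, y, _ = planted_small
        with pytest.raises(ValueError, match="empty OSF"):
            independent_eval(np.empty((len(y), 0)), y, np.empty((len(y), 0)), y)

    def test_both_threshold_sources_reported(self, planted_small):
        X, y, info = planted_small
        rep = independent_eval(X[:, :8], y, X[:, :8], y, threshold_from="train")
        assert "threshold_test_roc" in rep.extras
        assert rep.youden_threshold == rep.extras["threshold_train_roc"]


class TestSubtypeStratified:
    def test_missing_subtypes_excluded(self):
        scores = np.array([1.0, 1.0, -1.0, -1.0, 0.5, -0.5])
        labels = np.array([1, 1, 0, 0, 1, 0])
        subtype = np.array(["Luminal", "HER2+", "Luminal", "HER2+", None, None],
                           dtype=object)
        out = subtype_stratified_eval(scores, labels, subtype, 0.0)
        assert out["n_excluded_missing_subtype"] == 2
        assert sum(s["n"] for s in out["strata"].values()) == 4
        assert out["strata"]["Luminal"]["accuracy"] == 100.0

    def test_single_class_stratum_reports_none(self):
        scores = np.array([1.0, 0.5, -1.0])
        labels = np.array([1, 1, 0])
        subtype = np.array(["Luminal", "Luminal", "Triple Negative"], dtype=object)
        out = subtype_stratified_eval(scores, labels, subtype, 0.0)
        assert out["strata"]["Luminal"]["specificity"] is None
        assert out["strata"]["Triple Negative"]["sensitivity"] is None


class TestAppendClinical:
    @staticmethod
    def _table(n=10):
        rng = np.random.default_rng(0)
        return pd.DataFrame({
            "er": rng.integers(0, 2, n),
            "pgr": rng.integers(0, 2, n),
            "her2": rng.integers(0, 2, n),
            "subtype": rng.choice(["Luminal", "HER2+", "Triple Negative"], n),
        })

    def test_width_twenty_plus_four(self):
        X = np.zeros((10, 20))
        aug, info = append_clinical(X, self._table())
        assert aug.shape == (10, 24) and info["n_clinical"] == 4

    def test_clinical_only_width_four(self):
        aug, _ = append_clinical(np.empty((10, 0)), self._table())
        assert aug.shape == (10, 4)

    def test_missing_values_imputed_and_flagged(self):
        tab = self._table()
        tab.loc[3, "her2"] = np.nan
        aug, info = append_clinical(np.zeros((10, 1)), tab,
                                    train_idx=np.arange(10) != 3)
        assert (3, "her2") in info["imputed"]
        assert np.isfinite(aug).all()

    def test_unknown_category_rejected(self):
        tab = self._table()
        tab.loc[0, "subtype"] = "Basal"
        with pytest.raises(ValueError, match="Basal"):
            append_clinical(np.zeros((10, 1)), tab)


def test_pcr_svm_classifier_sklearn_api(planted_small):
    from sklearn.base import clone

    X, y, info = planted_small
    clf = PcrSvmClassifier()
    clf2 = clone(clf).fit(X[:, sorted(info)], y)
    assert set(clf2.classes_) == {0, 1}
    scores = clf2.decision_function(X[:, sorted(info)])
    # larger score = more pCR-like
    assert scores[y == 1].mean() > scores[y == 0].mean()
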