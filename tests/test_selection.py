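"""Stability selection: rank-sum filter, set algebra, determinism, nulls."""

import itertools

import numpy as np
import pytest

from dcepcr.selection import (SelectionConfig, StabilityFeatureSelector,
                              compute_osf, filter_features, iteration_select,
                              loo_dynamic_select, rank_sum_pvalues)
from dcepcr.synthetic import SyntheticCohortConfig, gen_feature_cohort
from dcepcr._utils import substream


def exact_rank_sum_p(a, b):
    """Enumeration oracle: two-sided rank-sum p by listing all assignments.

    Every C(n1+n2, n1) split of the pooled (midranked) values is equally
    likely under the null; the p-value is the fraction of splits whose
    |rank sum - mean| is at least as large as observed.
    """
    pooled = np.concatenate([a, b])
    n1 = len(a)
    # midranks
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled))
    sorted_v = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_v[j + 1] == sorted_v[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    mean = n1 * (len(pooled) + 1) / 2
    obs = abs(ranks[:n1].sum() - mean)
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(ranks[list(comb)].sum() - mean) >= obs - 1e-12:
            count += 1
    return count / total


class TestRankSum:
    def test_exact_three_vs_three(self):
        p = rank_sum_pvalues(np.array([[1.], [2.], [3.], [4.], [5.], [6.]]),
                             np.array([1, 1, 1, 0, 0, 0]))
        assert p[0] == pytest.approx(0.1)
        assert exact_rank_sum_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_path_matches_enumeration(self, seed):
        # tie-free small samples use the exact null: enumeration must agree
        rng = np.random.default_rng(seed)
        vals = rng.permutation(np.arange(11.0))
        a, b = vals[:5], vals[5:]
        X = np.concatenate([a, b])[:, None]
        y = np.r_[np.ones(5), np.zeros(6)].astype(int)
        assert rank_sum_pvalues(X, y)[0] == pytest.approx(
            exact_rank_sum_p(a, b), abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_tied_small_samples_use_midrank_approximation(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 6, size=5).astype(float)
        b = rng.integers(0, 6, size=6).astype(float)
        if len(np.unique(np.concatenate([a, b]))) == 11:
            pytest.skip("no ties drawn")
        from scipy import stats
        X = np.concatenate([a, b])[:, None]
        y = np.r_[np.ones(5), np.zeros(6)].astype(int)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic").pvalue
        assert rank_sum_pvalues(X, y)[0] == pytest.approx(ref, abs=1e-12)

    def test_identical_columns_give_p_one(self):
        X = np.ones((30, 3))
        y = np.r_[np.ones(12), np.zeros(18)].astype(int)
        assert np.all(rank_sum_pvalues(X, y) == 1.0)

    def test_negation_symmetry(self):
        rng = np.random.default_rng(3)
        col = rng.normal(size=40)
        X = np.column_stack([col, -col])
        y = (rng.random(40) < 0.4).astype(int)
        y[:2], y[-2:] = 1, 0
        p = rank_sum_pvalues(X, y)
        assert p[0] == pytest.approx(p[1])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            rank_sum_pvalues(np.zeros((4, 2)), np.ones(4))


class TestFilter:
    def test_strict_cutoff_small_samples(self):
        # the minimum achievable exact two-sided p with 3 vs 3 is 0.1, so
        # alpha=0.001 can never select anything at this size
        X = np.arange(6.0)[:, None]
        y = np.array([1, 1, 1, 0, 0, 0])
        assert len(filter_features(X, y, 0.001)) == 0
        assert filter_features(X, y, 1.0).tolist() == [0]

    def test_planted_recall(self):
        X, y, info = gen_feature_cohort(SyntheticCohortConfig(
            n_pcr=40, n_nonpcr=40, n_features=200,
            informative_idx=frozenset(range(10)), effect_size=3.0, seed=8))
        sel = set(filter_features(X, y, 0.001).tolist())
        assert len(sel & set(info.tolist())) / 10 >= 0.8


class TestIteration:
    def test_degenerate_resampling_equals_plain_filter(self):
        X, y, _ = gen_feature_cohort(SyntheticCohortConfig(
            n_pcr=20, n_nonpcr=20, n_features=60, effect_size=2.5, seed=1))
        cfg = SelectionConfig(n_subsets=1, subset_fraction=1.0, alpha=0.01, seed=0)
        res = iteration_select(X, y, cfg, substream(0, 17, 0, 0))
        assert res.features == frozenset(filter_features(X, y, 0.01).tolist())

    def test_union_of_subset_filters(self):
        X, y, _ = gen_feature_cohort(SyntheticCohortConfig(
            n_pcr=20, n_nonpcr=20, n_features=60, effect_size=2.0, seed=2))
        cfg = SelectionConfig(n_subsets=5, alpha=0.05, seed=0)
        res = iteration_select(X, y, cfg, substream(0, 17, 0, 0))
        # replay the logged draws: the result must be exactly the union
        union = set()
        for idx in res.draws:
            union.update(filter_features(X[idx], y[idx], 0.05).tolist())
        assert res.features == frozenset(union)

    def test_deterministic_draws(self):
        X, y, _ = gen_feature_cohort(SyntheticCohortConfig(
            n_pcr=10, n_nonpcr=10, n_features=30, seed=3))
        cfg = SelectionConfig(n_subsets=4, seed=5)
        r1 = iteration_select(X, y, cfg, substream(5, 17, 2, 3))
        r2 = iteration_select(X, y, cfg, substream(5, 17, 2, 3))
        assert r1.features == r2.features
        assert all(np.array_equal(a, b) for a, b in zip(r1.draws, r2.draws))


@pytest.fixture(scope="module")
def small():
    cfg = SyntheticCohortConfig(n_pcr=6, n_nonpcr=8, n_features=40,
                                informative_idx=frozenset(range(4)),
                                effect_size=2.5, seed=4)
    return gen_feature_cohort(cfg)


class TestLooSelect:
    def test_matches_unrestricted_reference(self, small):
        # oracle: re-run each LOO step without the candidate-column
        # restriction, intersecting full iteration results
        X, y, _ = small
        cfg = SelectionConfig(n_iterations=3, n_subsets=3, alpha=0.05, seed=9)
        res = loo_dynamic_select(X, y, cfg)
        for i in range(len(y)):
            tr = np.delete(np.arange(len(y)), i)
            ref = None
            for t in range(cfg.n_iterations):
                it = iteration_select(X[tr], y[tr], cfg, substream(9, 17, i, t))
                ref = it.features if ref is None else ref & it.features
            assert res.per_patient_sets[i] == ref

    def test_monotone_nesting_in_alpha(self, small):
        X, y, _ = small
        lo = loo_dynamic_select(X, y, SelectionConfig(n_iterations=3, n_subsets=3,
                                                      alpha=0.01, seed=9))
        hi = loo_dynamic_select(X, y, SelectionConfig(n_iterations=3, n_subsets=3,
                                                      alpha=0.2, seed=9))
        assert lo.osf <= hi.osf
        for i in lo.per_patient_sets:
            assert lo.per_patient_sets[i] <= hi.per_patient_sets[i]

    def test_full_determinism_and_digest(self, small):
        X, y, _ = small
        cfg = SelectionConfig(n_iterations=2, n_subsets=3, alpha=0.05, seed=1)
        r1 = loo_dynamic_select(X, y, cfg)
        r2 = loo_dynamic_select(X, y, cfg)
        assert r1.per_patient_sets == r2.per_patient_sets
        assert r1.osf == r2.osf and r1.draw_digest == r2.draw_digest

    def test_single_iteration_equals_iteration_select(self, small):
        X, y, _ = small
        cfg = SelectionConfig(n_iterations=1, n_subsets=3, alpha=0.05, seed=2)
        res = loo_dynamic_select(X, y, cfg)
        tr = np.arange(1, len(y))
        ref = iteration_select(X[tr], y[tr], cfg, substream(2, 17, 0, 0))
        assert res.per_patient_sets[0] == ref.features

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            loo_dynamic_select(np.zeros((2, 3)), np.array([0, 1]))


class TestOsf:
    def test_intersection_examples(self):
        sets = {0: {1, 2, 3}, 1: {2, 3}, 2: {2, 3, 4}}
        assert compute_osf(sets) == frozenset({2, 3})
        assert compute_osf({0: set(), 1: {1}}) == frozenset()
        assert compute_osf({0: {5, 7}}) == frozenset({5, 7})

    def test_empty_mapping_rejected(self):
        with pytest.raises(ValueError):
            compute_osf({})


class TestSelectorEstimator:
    def test_sklearn_selector_api(self):
        X, y, info = gen_feature_cohort(SyntheticCohortConfig(
            n_pcr=15, n_nonpcr=20, n_features=50,
            informative_idx=frozenset(range(3)), effect_size=3.0, seed=6))
        sel = StabilityFeatureSelector(n_iterations=4, n_subsets=4, alpha=0.01,
                                       random_state=0)
        assert sel.get_params()["alpha"] == 0.01
        Xt = sel.fit(X, y).transform(X)
        assert Xt.shape == (35, len(sel.osf_))
        assert sel.support_.sum() == len(sel.osf_)
        assert sel.osf_ <= frozenset(range(50))
        # OSF contained in every per-patient set
        for s in sel.per_patient_sets_.values():
            assert sel.osf_ <= s
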