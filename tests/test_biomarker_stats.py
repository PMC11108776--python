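import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from tmetrial.biomarker_stats import (
    TmeLogisticModel,
    TwoByTwo,
    bottom_tertile_cutoff,
    chi_square,
    correlation_cluster,
    diagnostics,
    dichotomize,
    fisher_exact,
    logistic_fit,
    mann_whitney,
    pairwise_pearson,
    roc_auc,
)


class TestMannWhitney:
    def test_disjoint_triplets_exact_enumeration(self):
        """x={1,2,3}, y={4,5,6}: 2 of the 20 rank assignments are as
        extreme, so the exact two-sided p is 0.1."""
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.method == "exact"
        assert res.pvalue == pytest.approx(0.1)

    def test_identical_multisets_give_p_one(self):
        res = mann_whitney([1, 2, 2, 3], [1, 2, 2, 3])
        assert res.pvalue == pytest.approx(1.0)

    def test_group_swap_symmetry(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(0.8, 1, size=15)
        a, b = mann_whitney(x, y), mann_whitney(y, x)
        assert a.pvalue == pytest.approx(b.pvalue)
        assert a.u == pytest.approx(len(x) * len(y) - b.u)

    def test_exact_distribution_matches_combination_enumeration(self):
        """The q-Pascal U null distribution equals direct enumeration of
        rank subsets for several group sizes."""
        from tmetrial.biomarker_stats import _u_null_counts

        for m, n in [(2, 3), (3, 5), (4, 4)]:
            counts = _u_null_counts(m, n)
            brute = np.zeros(m * n + 1)
            for comb in itertools.combinations(range(m + n), m):
                u = sum(comb) + m - m * (m + 1) / 2
                brute[int(u)] += 1
            np.testing.assert_array_equal(counts, brute)

    def test_normal_path_matches_scipy(self, rng):
        for _ in range(10):
            x = rng.normal(size=int(rng.integers(9, 30)))
            y = rng.normal(0.5, 1, size=int(rng.integers(9, 30)))
            ours = mann_whitney(x, y)
            ref = sps.mannwhitneyu(x, y, method="asymptotic")
            assert ours.pvalue == pytest.approx(ref.pvalue, abs=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestFisherExact:
    def test_reconstructed_megf8_table(self):
        """6/19 vs 0/14 mutated: two-sided p = 0.027."""
        assert fisher_exact(TwoByTwo(6, 0, 13, 14)) == pytest.approx(0.027, abs=5e-4)

    def test_zero_margin_gives_p_one(self):
        assert fisher_exact(TwoByTwo(0, 0, 5, 7)) == 1.0

    def test_matches_full_enumeration_oracle(self, rng):
        """Minimum-likelihood sum over all tables with fixed margins."""
        for _ in range(30):
            a, b, c, d = (int(v) for v in rng.integers(0, 10, 4))
            if a + b + c + d == 0:
                continue
            t = TwoByTwo(a, b, c, d)
            row1, col1, n = a + b, a + c, a + b + c + d
            p_obs = sps.hypergeom.pmf(a, n, row1, col1)
            total = sum(
                p
                for k in range(max(0, col1 - (n - row1)), min(col1, row1) + 1)
                if (p := sps.hypergeom.pmf(k, n, row1, col1)) <= p_obs * (1 + 1e-7)
            )
            assert fisher_exact(t) == pytest.approx(min(total, 1.0), abs=1e-10)

    def test_matches_scipy(self, rng):
        for _ in range(30):
            a, b, c, d = (int(v) for v in rng.integers(0, 12, 4))
            if a + b + c + d == 0:
                continue
            ref = sps.fisher_exact([[a, b], [c, d]])[1]
            assert fisher_exact(TwoByTwo(a, b, c, d)) == pytest.approx(ref, abs=1e-9)


class TestChiSquare:
    def test_balanced_table_is_null(self):
        stat, p = chi_square(TwoByTwo(5, 5, 5, 5))
        assert stat == 0.0 and p == 1.0

    def test_fully_concordant_statistic_equals_n(self):
        stat, _ = chi_square(TwoByTwo(10, 0, 0, 10))
        assert stat == pytest.approx(20.0)

    def test_degenerate_margin_warns_and_returns_null(self):
        stat, p = chi_square(TwoByTwo(3, 0, 4, 0))
        assert (stat, p) == (0.0, 1.0)

    @pytest.mark.parametrize("yates", [False, True])
    def test_matches_direct_formula_and_scipy(self, rng, yates):
        for _ in range(50):
            a, b, c, d = (int(v) for v in rng.integers(1, 15, 4))
            stat, p = chi_square(TwoByTwo(a, b, c, d), yates=yates)
            ref = sps.chi2_contingency([[a, b], [c, d]], correction=yates)
            assert stat == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)


class TestDiagnostics:
    def test_perfect_table(self):
        d = diagnostics(TwoByTwo(10, 0, 0, 10))
        assert all(v == 100.0 for v in d.values())

    def test_inverted_table_has_zero_sensitivity(self):
        d = diagnostics(TwoByTwo(0, 10, 10, 0))
        assert d["sensitivity"] == 0.0 and d["specificity"] == 0.0

    def test_matches_direct_count_definitions(self, rng):
        for _ in range(20):
            a, b, c, d = (int(v) for v in rng.integers(1, 20, 4))
            m = diagnostics(TwoByTwo(a, b, c, d))
            assert m["sensitivity"] == pytest.approx(100 * a / (a + c))
            assert m["specificity"] == pytest.approx(100 * d / (b + d))
            assert m["ppv"] == pytest.approx(100 * a / (a + b))
            assert m["npv"] == pytest.approx(100 * d / (c + d))


class TestTertileCutoff:
    def test_interpolated_quantile_of_one_to_nine(self):
        cutoff = bottom_tertile_cutoff(range(1, 10))
        assert cutoff == pytest.approx(11 / 3)
        assert sum(v <= cutoff for v in range(1, 10)) == 3

    def test_constant_values_degenerate_split(self):
        cutoff = bottom_tertile_cutoff([4.0] * 6)
        high = dichotomize([4.0] * 6, cutoff)
        assert not high.any()

    def test_permutation_invariance(self, rng):
        vals = rng.normal(size=20)
        shuffled = rng.permutation(vals)
        assert bottom_tertile_cutoff(vals) == bottom_tertile_cutoff(shuffled)

    def test_too_few_values_error(self):
        with pytest.raises(ValueError):
            bottom_tertile_cutoff([1.0, 2.0])


class TestCorrelationCluster:
    def test_duplicated_column_unit_correlation_and_adjacent_leaves(self, rng):
        base = rng.normal(size=30)
        m = pd.DataFrame({"a": base, "b": base.copy(), "c": rng.normal(size=30)})
        corr, order = correlation_cluster(m)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert abs(order.index("a") - order.index("b")) == 1

    def test_negated_column_perfect_anticorrelation(self, rng):
        x = rng.normal(size=25)
        corr = pairwise_pearson(pd.DataFrame({"x": x, "neg": -x}))
        assert corr.loc["x", "neg"] == pytest.approx(-1.0)

    def test_matches_covariance_formula_on_random_data(self, rng):
        data = pd.DataFrame(rng.normal(size=(40, 5)), columns=list("abcde"))
        corr = pairwise_pearson(data)
        ref = np.corrcoef(data.to_numpy().T)
        np.testing.assert_allclose(corr.to_numpy(), ref, atol=1e-12)

    def test_pairwise_complete_matches_pandas(self, rng):
        data = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        data.iloc[rng.integers(0, 30, 10), 1] = np.nan
        corr = pairwise_pearson(data)
        ref = data.corr(method="pearson", min_periods=3)
        np.testing.assert_allclose(corr.to_numpy(), ref.to_numpy(), atol=1e-12)

    def test_constant_column_excluded_with_nan(self, rng):
        m = pd.DataFrame({"a": rng.normal(size=20), "b": np.ones(20),
                          "c": rng.normal(size=20)})
        corr, order = correlation_cluster(m)
        assert math.isnan(corr.loc["a", "b"])
        assert order[-1] == "b"  # appended after the clustered leaves

    def test_average_linkage_merge_heights_match_scipy(self, rng):
        from scipy.cluster import hierarchy

        data = pd.DataFrame(rng.normal(size=(50, 6)), columns=list("abcdef"))
        corr, order = correlation_cluster(data)
        dist = 1 - corr.to_numpy()
        condensed = dist[np.triu_indices(6, k=1)]
        link = hierarchy.linkage(condensed, method="average")
        ref_order = [data.columns[i] for i in hierarchy.leaves_list(link)]
        # orientation of dendrogram branches is arbitrary; compare the sets of
        # adjacent sibling pairs produced by the first merge and overall leaves
        assert set(order) == set(ref_order)
        first_pair = {data.columns[int(link[0, 0])], data.columns[int(link[0, 1])]}
        i, j = sorted(order.index(c) for c in first_pair)
        assert j == i + 1


class TestLogisticFit:
    def test_intercept_only_closed_form(self, rng):
        y = np.r_[np.ones(5), np.zeros(15)]
        X = np.zeros((20, 1))
        fit = logistic_fit(X, y)
        assert fit.fitted == pytest.approx(np.full(20, 0.25), abs=1e-8)
        assert fit.params[0] == pytest.approx(math.log(0.25 / 0.75), abs=1e-6)

    def test_parameter_recovery_within_ten_percent(self, rng):
        n = 2000
        X = rng.normal(size=(n, 2))
        beta = np.array([-1.0, 1.5, -2.0])
        p = 1 / (1 + np.exp(-(beta[0] + X @ beta[1:])))
        y = (rng.random(n) < p).astype(float)
        fit = logistic_fit(X, y)
        assert fit.converged and not fit.separated
        np.testing.assert_allclose(fit.params, beta, rtol=0.10)

    def test_null_slopes_within_confidence_band(self, rng):
        n = 1500
        X = rng.normal(size=(n, 2))
        y = (rng.random(n) < 0.4).astype(float)  # independent of X
        fit = logistic_fit(X, y)
        assert np.all(np.abs(fit.params[1:]) < 3 * fit.se[1:])

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        X = rng.normal(size=(200, 2))
        y = (rng.random(200) < 1 / (1 + np.exp(-(0.3 + X[:, 0])))).astype(float)
        fit = logistic_fit(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(fit.params, ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.se, ref.bse, atol=1e-5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            logistic_fit(np.zeros((10, 1)), np.ones(10))

    def test_complete_separation_flagged(self):
        X = np.linspace(-1, 1, 20)[:, None]
        y = (X[:, 0] > 0).astype(float)
        fit = logistic_fit(X, y)
        assert fit.separated


class TestTmeLogisticModel:
    def test_sklearn_estimator_contract(self, rng):
        from sklearn.base import clone

        model = TmeLogisticModel(max_iter=50)
        assert clone(model).get_params() == {"tol": 1e-8, "max_iter": 50}
        X = rng.normal(size=(100, 2))
        y = (X[:, 0] + rng.normal(0, 0.5, 100) > 0).astype(int)
        model.fit(X, y)
        proba = model.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        assert model.score(X, y) > 0.7
        assert model.coef_.shape == (1, 2)


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([0.1, 0.2, 0.8, 0.9], [False, False, True, True])
        assert res.auc == 1.0

    def test_null_limit_near_half(self, rng):
        scores = rng.normal(size=4000)
        labels = rng.random(4000) < 0.5
        assert roc_auc(scores, labels).auc == pytest.approx(0.5, abs=0.03)

    def test_trapezoid_equals_rank_formula(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 60))
            scores = rng.choice(np.linspace(0, 1, 12), size=n)  # force ties
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            res = roc_auc(scores, labels)
            assert np.trapezoid(res.tpr, res.fpr) == pytest.approx(res.auc, abs=1e-12)

    def test_score_negation_antisymmetry_without_ties(self, rng):
        scores = rng.normal(size=50)
        labels = rng.random(50) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        assert roc_auc(scores, labels).auc + roc_auc(-scores, labels).auc == pytest.approx(1.0)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=80)
        labels = rng.random(80) < 0.4
        assert roc_auc(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [True, True])
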