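"""Ranking criteria, AHP comparison matrices, and aggregate selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mriens import (
    FeatureMatrix,
    ValidationError,
    aggregate_select,
    build_comparison_matrix,
    consistency_ratio,
    fisher_score,
    sbmlr_score,
    ttest_score,
)
from mriens.feature_reduction import (
    positivize_scores,
    random_index,
    ranking_eigenvector,
)


def toy_matrix(seed=0, n=6, d=8):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    y = np.array([0, 1] * (n // 2))
    return FeatureMatrix(X=X, y=y, feature_ids=np.arange(d))


def loop_fisher(X, y):
    n, d = X.shape
    out = np.zeros(d)
    for j in range(d):
        mu = X[:, j].mean()
        num = den = 0.0
        for c in (0, 1):
            xc = X[y == c, j]
            num += len(xc) * (xc.mean() - mu) ** 2
            den += len(xc) * xc.var()
        out[j] = num / den if den > 0 else 0.0
    return out


def loop_welch_t(X, y):
    out = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        a, b = X[y == 1, j], X[y == 0, j]
        se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        out[j] = abs((a.mean() - b.mean()) / se)
    return out


class TestFisherScore:
    def test_matches_formula_oracle(self):
        fm = toy_matrix(seed=1)
        np.testing.assert_allclose(
            fisher_score(fm), loop_fisher(fm.X, fm.y), atol=1e-12
        )

    def test_constant_feature_scores_zero(self):
        fm = toy_matrix(seed=2)
        fm.X[:, 0] = 3.14
        assert fisher_score(fm)[0] == 0.0

    def test_perfect_separator_gets_sentinel_max(self):
        fm = toy_matrix(seed=3)
        fm.X[:, 0] = fm.y.astype(float)  # zero within-class variance
        scores = fisher_score(fm)
        assert scores[0] > scores[1:].max()

    def test_single_class_rejected(self):
        fm = toy_matrix()
        fm.y[:] = 0
        with pytest.raises(ValidationError):
            fisher_score(fm)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(scale=st.floats(0.01, 100), seed=st.integers(0, 10))
    def test_invariant_to_positive_feature_rescaling(self, scale, seed):
        fm = toy_matrix(seed=seed)
        base = fisher_score(fm)
        fm2 = FeatureMatrix(
            X=fm.X * scale, y=fm.y, feature_ids=fm.feature_ids
        )
        np.testing.assert_allclose(fisher_score(fm2), base, rtol=1e-9)


class TestTTestScore:
    def test_zero_when_classes_identical(self):
        fm = toy_matrix(seed=4)
        fm.X[fm.y == 1] = fm.X[fm.y == 0]
        np.testing.assert_allclose(ttest_score(fm), 0.0, atol=1e-12)

    def test_matches_textbook_welch_formula(self):
        fm = toy_matrix(seed=5, n=10)
        np.testing.assert_allclose(
            ttest_score(fm), loop_welch_t(fm.X, fm.y), atol=1e-10
        )

    def test_scale_invariance(self):
        fm = toy_matrix(seed=6)
        base = ttest_score(fm)
        fm2 = FeatureMatrix(X=fm.X * 7.5, y=fm.y, feature_ids=fm.feature_ids)
        np.testing.assert_allclose(ttest_score(fm2), base, rtol=1e-9)


class TestSbmlrScore:
    def test_pure_noise_strong_regularization_all_zero(self):
        rng = np.random.default_rng(0)
        fm = FeatureMatrix(
            X=rng.normal(size=(12, 30)),
            y=np.array([0, 1] * 6),
            feature_ids=np.arange(30),
        )
        scores = sbmlr_score(fm, reg=1e-3)
        assert np.all(scores == 0.0)

    def test_separating_feature_dominates(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 20))
        y = np.array([0, 1] * 10)
        X[:, 0] = y + rng.normal(0, 0.05, 20)
        fm = FeatureMatrix(X=X, y=y, feature_ids=np.arange(20))
        scores = sbmlr_score(fm, reg=0.5, seed=1)
        assert scores[0] > scores[1:].max()

    def test_weak_penalty_approaches_unregularized_fit(self):
        from sklearn.linear_model import LogisticRegression
        from sklearn.preprocessing import StandardScaler

        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 2))
        y = (X[:, 0] + 2 * rng.normal(size=40) > 0).astype(int)  # not separable
        fm = FeatureMatrix(X=X, y=y, feature_ids=np.arange(2))
        ours = sbmlr_score(fm, reg=1e6)
        ref = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000)
        ref.fit(StandardScaler().fit_transform(X), y)
        np.testing.assert_allclose(ours, np.abs(ref.coef_.ravel()), rtol=1e-2)


class TestComparisonMatrix:
    def test_ratio_matrices_are_perfectly_consistent(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = rng.integers(3, 12)
            cm = build_comparison_matrix(rng.uniform(0.05, 10, n))
            assert abs(cm.CR) < 1e-8
            assert abs(cm.lambda_max - n) < 1e-8
            # reciprocal within tolerance
            np.testing.assert_allclose(cm.M * cm.M.T, 1.0, atol=1e-10)

    def test_uniform_scores_give_all_ones_matrix(self):
        cm = build_comparison_matrix(np.array([1.0, 1.0, 1.0]))
        np.testing.assert_allclose(cm.M, 1.0)
        np.testing.assert_allclose(cm.eigvec, 1 / 3)

    def test_eigvec_equals_normalized_scores(self):
        s = np.array([0.2, 1.4, 3.3, 0.9])
        cm = build_comparison_matrix(s)
        np.testing.assert_allclose(
            cm.eigvec, ranking_eigenvector(s), atol=1e-10
        )

    def test_power_iteration_oracle_on_perturbed_matrix(self):
        rng = np.random.default_rng(4)
        s = rng.uniform(0.5, 3.0, 4)
        M = s[:, None] / s[None, :]
        M *= np.exp(rng.normal(0, 0.1, (4, 4)))  # break consistency
        upper = np.triu(M, 1)
        with np.errstate(divide="ignore"):
            recip = np.where(upper.T > 0, 1.0 / np.where(upper.T > 0, upper.T, 1.0), 0.0)
        M = upper + np.tril(recip, -1) + np.eye(4)
        x = np.ones(4)
        for _ in range(2000):
            x = M @ x
            x /= np.linalg.norm(x)
        lam_power = float(x @ M @ x)
        lam_dense = max(np.linalg.eigvals(M).real)
        assert abs(lam_power - lam_dense) < 1e-8
        assert consistency_ratio(M, lambda_max=lam_dense) > 0

    def test_all_zero_scores_rejected(self):
        with pytest.raises(ValidationError):
            build_comparison_matrix(np.zeros(4))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        st.lists(st.floats(0.01, 100), min_size=2, max_size=25),
    )
    def test_consistency_property_over_random_score_vectors(self, scores):
        cm = build_comparison_matrix(np.array(scores))
        assert abs(cm.CR) < 1e-8


class TestConsistencyRatio:
    def test_consistent_ratio_matrix_has_zero_ci(self):
        s = np.array([1.0, 2.0, 4.0])
        M = s[:, None] / s[None, :]
        lam = max(np.linalg.eigvals(M).real)
        assert abs(lam - 3) < 1e-10
        assert consistency_ratio(M) == 0.0

    def test_all_ones_order_five(self):
        assert consistency_ratio(np.ones((5, 5))) == 0.0

    def test_perturbed_judgment_matches_hand_computation(self):
        # one inconsistent judgment: M[0,2] = 4 while transitivity implies 6
        M = np.array([[1, 2, 4], [0.5, 1, 3], [0.25, 1 / 3, 1.0]])
        lam = max(np.linalg.eigvals(M).real)
        expected = ((lam - 3) / 2) / random_index(3)
        assert consistency_ratio(M) == pytest.approx(expected, abs=1e-12)
        assert 0 < consistency_ratio(M) < 0.1  # still acceptable judgments

    def test_order_below_two_rejected(self):
        with pytest.raises(ValidationError):
            consistency_ratio(np.ones((1, 1)))

    def test_random_index_table_and_asymptote(self):
        assert random_index(3) == 0.58
        assert random_index(15) == 1.59
        assert random_index(20) == pytest.approx(1.98 * 18 / 20)


class TestAggregateSelect:
    def test_identical_rankings_are_preserved(self):
        fm = toy_matrix(seed=7, n=10, d=6)
        sel = aggregate_select(fm, k=3, criteria=("fisher", "fisher", "fisher"))
        fisher_only = np.argsort(-fisher_score(fm), kind="stable")[:3]
        assert set(sel.selected_indices) == set(fisher_only)

    def test_degenerate_weights_reduce_to_single_criterion(self):
        fm = toy_matrix(seed=8, n=10, d=6)
        sel = aggregate_select(fm, k=6, weights=(1.0, 0.0, 0.0))
        np.testing.assert_allclose(
            sel.final_scores, ranking_eigenvector(fisher_score(fm)), atol=1e-12
        )

    def test_final_scores_match_chained_matrix_product_oracle(self):
        fm = toy_matrix(seed=9, n=12, d=50)
        sel = aggregate_select(fm, k=10, seed=3)
        # independent step-by-step chain: per criterion build the full ratio
        # matrix, take its principal eigenvector, stack, multiply by weights
        cols = []
        for scores in sel.criterion_scores.values():
            s = positivize_scores(scores)
            M = s[:, None] / s[None, :]
            vals, vecs = np.linalg.eig(M)
            v = np.abs(vecs[:, np.argmax(vals.real)].real)
            cols.append(v / v.sum())
        S = np.column_stack(cols)
        expected = S @ np.full(3, 1 / 3)
        np.testing.assert_allclose(sel.final_scores, expected, atol=1e-8)

    def test_invariant_to_feature_permutation(self):
        fm = toy_matrix(seed=10, n=10, d=12)
        perm = np.random.default_rng(0).permutation(12)
        fm_p = FeatureMatrix(
            X=fm.X[:, perm], y=fm.y, feature_ids=fm.feature_ids[perm]
        )
        sel = aggregate_select(fm, k=5, seed=1)
        sel_p = aggregate_select(fm_p, k=5, seed=1)
        assert set(sel.selected_ids) == set(sel_p.selected_ids)

    def test_deterministic_under_fixed_seed(self):
        fm = toy_matrix(seed=11, n=10, d=15)
        s1 = aggregate_select(fm, k=5, seed=9)
        s2 = aggregate_select(fm, k=5, seed=9)
        np.testing.assert_array_equal(s1.final_scores, s2.final_scores)
        np.testing.assert_array_equal(s1.selected_ids, s2.selected_ids)

    def test_criterion_failure_names_the_criterion(self):
        fm = toy_matrix(seed=12)
        fm.y[:] = 0
        with pytest.raises(RuntimeError, match="fisher"):
            aggregate_select(fm, k=2, criteria=("fisher",), weights=(1.0,))

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_select(toy_matrix(), k=100)
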