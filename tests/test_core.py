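"""Unit and property tests for the score-statistic core."""

import numpy as np
import pytest
import scipy.linalg
from hypothesis import given, settings
from hypothesis import strategies as st

from towcm.core import (
    DegenerateTraitError,
    RankDeficiencyError,
    analytic_weight_single_variant,
    center_columns,
    drop_collinear_variants,
    optimal_weights,
    score_components,
    score_statistic,
    tow_cm_statistic,
)


def _direct_S(w, Y, X):
    """Independent evaluation of the score statistic from its definition,
    materializing the centering projector explicitly."""
    w = np.asarray(w, float)
    n = Y.shape[0]
    P = np.eye(n) - np.ones((n, n)) / n
    U = (P @ X).T @ (P @ Y @ w)
    V = ((P @ Y @ w) @ (P @ Y @ w) / n) * ((P @ X).T @ (P @ X))
    return float(U @ np.linalg.solve(V, U))


class TestCentering:
    def test_mean_subtraction(self):
        out = center_columns(np.array([[1.0], [2.0], [3.0]]))
        assert np.allclose(out.ravel(), [-1.0, 0.0, 1.0])

    def test_constant_column_annihilated(self):
        out = center_columns(np.full((5, 2), 7.0))
        assert np.allclose(out, 0.0)

    def test_idempotent(self, rng):
        A = rng.standard_normal((10, 3))
        once = center_columns(A)
        assert np.allclose(center_columns(once), once)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            center_columns(np.array([[1.0, 2.0]]))


class TestScoreStatistic:
    def test_perfect_correlation_gives_n(self):
        y = np.array([1.0, 2.0, 3.0])
        x = np.array([1.0, 2.0, 3.0])
        assert np.isclose(score_components([1.0], y, x).S, 3.0)

    def test_hand_computed_value(self):
        # r^2 = 0.75 between (1,2,3) and (1,0,0); S = n r^2 = 2.25
        y = np.array([1.0, 2.0, 3.0])
        x = np.array([1.0, 0.0, 0.0])
        sc = score_components([1.0], y, x)
        assert np.isclose(sc.S, 2.25)
        assert np.isclose(sc.S, _direct_S([1.0], y[:, None], x[:, None]))

    def test_scale_invariance_in_w(self, rng):
        Y = rng.standard_normal((20, 3))
        X = rng.binomial(2, 0.4, (20, 4)).astype(float)
        w = rng.standard_normal(3)
        assert np.isclose(score_statistic(w, Y, X), score_statistic(5.7 * w, Y, X))

    def test_two_formulations_agree_on_random_instances(self):
        # the U'V^-1 U and ratio-of-quadratic-forms expressions are
        # algebraically identical; check both against the direct evaluation
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = rng.integers(8, 30)
            K = rng.integers(1, 5)
            M = rng.integers(1, 7)
            Y = rng.standard_normal((n, K))
            X = rng.binomial(2, 0.4, (n, M)).astype(float)
            if np.any(X.std(axis=0) == 0) or np.linalg.matrix_rank(center_columns(X)) < M:
                continue
            w = rng.standard_normal(K)
            s2 = score_components(w, Y, X).S
            s3 = score_statistic(w, Y, X)
            assert np.isclose(s2, s3, rtol=1e-8)
            assert np.isclose(s2, _direct_S(w, Y, X), rtol=1e-8)
            assert -1e-9 <= s3 <= n + 1e-9

    def test_duplicated_trait_cancellation_is_degenerate(self, rng):
        y = rng.standard_normal(15)
        Y = np.column_stack([y, y])
        X = rng.binomial(2, 0.3, (15, 2)).astype(float)
        with pytest.raises(DegenerateTraitError):
            score_statistic([1.0, -1.0], Y, X)

    def test_row_relabeling_invariance(self, rng, small_null):
        Y, X, _ = small_null
        w = rng.standard_normal(Y.shape[1])
        perm = rng.permutation(Y.shape[0])
        assert np.isclose(score_statistic(w, Y, X), score_statistic(w, Y[perm], X[perm]))

    def test_collinear_variants_named(self, rng):
        X = rng.binomial(2, 0.3, (30, 3)).astype(float)
        X = np.column_stack([X, 2.0 * X[:, 0]])
        Y = rng.standard_normal((30, 2))
        with pytest.raises(RankDeficiencyError) as exc:
            score_statistic([1.0, 0.5], Y, X)
        assert exc.value.variant_ids  # offending variants are reported


class TestOptimalWeights:
    def test_single_trait_is_vacuous(self, rng):
        y = rng.standard_normal(30)
        X = rng.binomial(2, 0.3, (30, 3)).astype(float)
        sol = optimal_weights(y, X, ridge_policy="never")
        assert sol.w_opt[0] > 0
        assert np.isclose(sol.T, score_statistic([1.0], y, X) / 30)

    def test_random_search_never_beats_T(self):
        rng = np.random.default_rng(11)
        Y = rng.standard_normal((40, 3))
        X = rng.binomial(2, 0.35, (40, 5)).astype(float)
        sol = optimal_weights(Y, X, ridge_policy="never")
        # vectorized S(w)/n over 10,000 random unit directions
        Yc, Xc = center_columns(Y), center_columns(X)
        A = Yc.T @ Xc @ np.linalg.solve(Xc.T @ Xc, Xc.T @ Yc)
        D = Yc.T @ Yc
        W = rng.standard_normal((10_000, 3))
        ratios = np.einsum("ij,jk,ik->i", W, A, W) / np.einsum("ij,jk,ik->i", W, D, W)
        assert ratios.max() <= sol.T + 1e-10
        # and the claimed optimum is attained at w_opt
        assert np.isclose(score_statistic(sol.w_opt, Y, X) / 40, sol.T, rtol=1e-8)

    def test_generalized_eigenvalue_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            Y = rng.standard_normal((35, 4))
            X = rng.binomial(2, 0.4, (35, 6)).astype(float)
            if np.linalg.matrix_rank(center_columns(X)) < 6:
                continue
            sol = optimal_weights(Y, X, ridge_policy="never")
            Yc, Xc = center_columns(Y), center_columns(X)
            A = Yc.T @ Xc @ np.linalg.solve(Xc.T @ Xc, Xc.T @ Yc)
            D = Yc.T @ Yc
            top = scipy.linalg.eigh(A, D, eigvals_only=True)[-1]
            assert np.isclose(sol.T, top, rtol=1e-8)

    def test_solution_internal_identities(self, small_null):
        Y, X, _ = small_null
        sol = optimal_weights(Y, X)
        assert np.allclose(sol.L @ sol.L.T, sol.D, rtol=1e-8)
        assert np.isclose(np.linalg.norm(sol.c), 1.0)
        assert np.allclose(sol.C, sol.C.T)
        assert 0.0 <= sol.T <= 1.0
        assert np.isclose(np.linalg.eigvalsh(sol.C)[-1], sol.T)

    def test_ridge_policies(self, rng):
        y = rng.standard_normal(25)
        Y = np.column_stack([y, y])  # exactly collinear traits
        X = rng.binomial(2, 0.3, (25, 2)).astype(float)
        sol = optimal_weights(Y, X, ridge_policy="auto")
        assert sol.ridge_applied and np.isclose(sol.lambda0, 1 / 25)
        with pytest.raises(DegenerateTraitError):
            optimal_weights(Y, X, ridge_policy="never")
        full = optimal_weights(rng.standard_normal((25, 2)), X, ridge_policy="always")
        assert full.ridge_applied

    def test_all_constant_traits_rejected(self, rng):
        X = rng.binomial(2, 0.3, (20, 2)).astype(float)
        with pytest.raises(DegenerateTraitError):
            optimal_weights(np.ones((20, 2)), X)


class TestTowCmStatistic:
    def test_ratio_equals_eigenvalue(self, small_null):
        Y, X, _ = small_null
        T, sol = tow_cm_statistic(Y, X)
        assert np.isclose(T, sol.T, rtol=1e-8)
        assert 0.0 <= T <= 1.0

    def test_invariant_under_trait_recombination(self, rng, small_null):
        Y, X, _ = small_null
        T0, _ = tow_cm_statistic(Y, X, ridge_policy="never")
        B = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        T1, _ = tow_cm_statistic(Y @ B, X, ridge_policy="never")
        assert np.isclose(T0, T1, atol=1e-8)

    def test_invariant_under_variant_rescaling_and_shifts(self, rng, small_null):
        Y, X, _ = small_null
        T0, _ = tow_cm_statistic(Y, X)
        scales = rng.uniform(0.5, 3.0, X.shape[1])
        T1, _ = tow_cm_statistic(Y + 5.0, X * scales + 1.0)
        assert np.isclose(T0, T1, atol=1e-8)

    def test_invariant_under_joint_row_permutation(self, rng, small_null):
        Y, X, _ = small_null
        perm = rng.permutation(Y.shape[0])
        T0, _ = tow_cm_statistic(Y, X)
        T1, _ = tow_cm_statistic(Y[perm], X[perm])
        assert np.isclose(T0, T1, atol=1e-10)

    def test_null_permutation_matches_sampling_distribution(self):
        # under H0 the permutation distribution of T is the right reference:
        # compare it to T's sampling distribution over independent null draws
        from scipy.stats import ks_2samp

        rng = np.random.default_rng(99)
        n, K, M = 500, 3, 8
        X = rng.binomial(2, 0.3, (n, M)).astype(float)
        sampled = []
        for _ in range(200):
            T, _ = tow_cm_statistic(rng.standard_normal((n, K)), X)
            sampled.append(T)
        from towcm.inference import PermutationEngine, residualize

        engine = PermutationEngine(residualize(rng.standard_normal((n, K))), residualize(X))
        permuted = np.concatenate(
            [t for t, _ in engine.permuted(200, np.random.default_rng(1))]
        )
        assert ks_2samp(sampled, permuted).pvalue > 0.01


class TestAnalyticWeight:
    def test_hand_computed(self):
        assert np.isclose(
            analytic_weight_single_variant([0.0, 1.0, 2.0], [0.0, 1.0, 2.0]), 1.0
        )

    def test_antisymmetry_in_x(self, rng):
        y = rng.standard_normal(30)
        x = rng.binomial(2, 0.4, 30).astype(float)
        w = analytic_weight_single_variant(y, x)
        assert np.isclose(analytic_weight_single_variant(y, -x), -w)

    def test_sign_follows_covariance(self, rng):
        x = rng.binomial(2, 0.4, 100).astype(float)
        y = 0.5 * x + rng.standard_normal(100)
        assert analytic_weight_single_variant(y, x) > 0

    def test_constant_trait_rejected(self):
        with pytest.raises(DegenerateTraitError):
            analytic_weight_single_variant(np.ones(10), np.arange(10.0))

    def test_matches_optimal_weights_for_independent_traits(self):
        # with independent traits and M = 1 the closed form is the optimal
        # direction up to finite-sample trait correlation
        rng = np.random.default_rng(3)
        n, K = 2000, 4
        x = rng.binomial(2, 0.3, n).astype(float)
        Y = rng.standard_normal((n, K)) * np.array([1.0, 2.0, 0.5, 1.5])
        Y[:, 0] += 0.15 * x
        Y[:, 2] += 0.10 * x
        analytic = np.array(
            [analytic_weight_single_variant(Y[:, k], x) for k in range(K)]
        )
        sol = optimal_weights(Y, x, ridge_policy="never")
        cos = abs(analytic @ sol.w_opt) / (
            np.linalg.norm(analytic) * np.linalg.norm(sol.w_opt)
        )
        assert cos > 0.95


class TestCollinearityPruning:
    def test_duplicate_column_dropped(self, rng):
        X = rng.binomial(2, 0.3, (30, 3)).astype(float)
        Xd = np.column_stack([X, X[:, 1]])
        kept_mat, kept, dropped = drop_collinear_variants(Xd, ["a", "b", "c", "b_dup"])
        assert len(kept) == 3
        assert dropped == ["b_dup"] or "b" in dropped  # either copy may be pruned
        assert np.linalg.matrix_rank(center_columns(kept_mat)) == 3


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    n=st.integers(6, 25),
    K=st.integers(1, 4),
    M=st.integers(1, 5),
    seed=st.integers(0, 10_000),
)
def test_statistic_bounds_property(n, K, M, seed):
    """0 <= T <= 1 and 0 <= S(w) <= n whenever the inputs are non-degenerate."""
    rng = np.random.default_rng(seed)
    Y = rng.standard_normal((n, K))
    X = rng.binomial(2, 0.4, (n, M)).astype(float)
    if np.linalg.matrix_rank(center_columns(X)) < M:
        return
    T, _ = tow_cm_statistic(Y, X)
    assert -1e-9 <= T <= 1 + 1e-9
    w = rng.standard_normal(K)
    s = score_statistic(w, Y, X)
    assert -1e-9 <= s <= n + 1e-9
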