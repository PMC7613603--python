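"""Stacking, weight-matrix averaging, sandwich variances, Rubin pooling,
and joint Wald tests."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pairjm import pseudolik as pl
from pairjm.glmm import FitResult, ModelSpec, fit_bivariate

from conftest import SMALL_TERMS, simulate_clustered


def fake_fit(pair, k, beta=None, D=None, cluster_ids=None, scores=None,
             hessians=None, X=None):
    """Minimal FitResult carrying only what the combiner needs."""
    p_dim = 2
    beta = np.zeros((p_dim, k)) if beta is None else np.asarray(beta, float)
    D = np.eye(p_dim) * 0.5 if D is None else D
    n_par = p_dim * k + 3
    cluster_ids = np.arange(3) if cluster_ids is None else cluster_ids
    J = len(cluster_ids)
    scores = np.zeros((J, n_par)) if scores is None else scores
    hessians = (np.tile(-np.eye(n_par), (J, 1, 1)) if hessians is None
                else hessians)
    return FitResult(
        outcomes=pair, labels=[f"c{i}" for i in range(k)], beta=beta, D=D,
        theta=np.zeros(n_par), loglik=0.0, converged=True, grad_norm=0.0,
        n_iter=1, flags=[], cluster_ids=cluster_ids,
        per_cluster_loglik=np.zeros(J), per_cluster_scores=scores,
        per_cluster_hessians=hessians, info=None, X=X)


class TestPairIndex:
    def test_nine_outcomes_give_36_pairs(self):
        idx = pl.enumerate_pairs(9)
        assert idx.Q == 36
        assert idx.pairs[0] == (1, 2) and idx.pairs[-1] == (8, 9)

    def test_two_outcomes(self):
        assert pl.enumerate_pairs(2).pairs == ((1, 2),)

    def test_each_outcome_in_p_minus_1_pairs(self):
        # brute-force enumeration oracle
        for p in (3, 4, 6):
            idx = pl.enumerate_pairs(p)
            brute = [(r, s) for r in range(1, p + 1)
                     for s in range(1, p + 1) if r < s]
            assert list(idx.pairs) == brute
            for o in range(1, p + 1):
                assert sum(o in pr for pr in idx.pairs) == p - 1

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            pl.enumerate_pairs(1)


class TestStack:
    def test_nine_outcome_stack_length(self):
        idx = pl.enumerate_pairs(9)
        fits = [fake_fit(pr, 13) for pr in idx.pairs]
        st_ = pl.stack(fits, idx)
        assert st_.beta_stacked.shape == (936,)

    def test_small_dimensions_and_order_invariance(self):
        idx = pl.enumerate_pairs(2)
        rng = np.random.default_rng(0)
        f = fake_fit((1, 2), 3, beta=rng.normal(size=(2, 3)))
        st_ = pl.stack([f], idx)
        assert st_.beta_stacked.shape == (6,)
        assert np.array_equal(st_.beta_stacked, f.beta.ravel())

        idx3 = pl.enumerate_pairs(3)
        fits = [fake_fit(pr, 2, beta=rng.normal(size=(2, 2)))
                for pr in idx3.pairs]
        a = pl.stack(fits, idx3).beta_stacked
        b = pl.stack(fits[::-1], idx3).beta_stacked
        assert np.array_equal(a, b)

    def test_missing_and_duplicate_pairs_rejected(self):
        idx = pl.enumerate_pairs(3)
        fits = [fake_fit(pr, 2) for pr in idx.pairs]
        with pytest.raises(ValueError, match="missing"):
            pl.stack(fits[:-1], idx)
        with pytest.raises(ValueError, match="duplicate"):
            pl.stack(fits + [fits[0]], idx)


class TestWeightMatrix:
    def test_nine_outcome_shape(self):
        A = pl.build_weight_matrix(9, 13)
        assert A.shape == (117, 936)
        assert np.allclose(A.sum(axis=1), 1.0)

    def test_hand_enumeration_p3_k2(self):
        # pairs (1,2), (1,3), (2,3); every coefficient occurs twice
        A = pl.build_weight_matrix(3, 2)
        assert A.shape == (6, 12)
        assert np.all(np.isin(A, (0.0, 0.5)))
        assert np.all((A != 0).sum(axis=1) == 2)
        # coefficient 0 of outcome 1 sits at stacked slots 0 and 4
        assert A[0, 0] == 0.5 and A[0, 4] == 0.5
        # coefficient 1 of outcome 3: slot 2k+k+1=7 in (1,3), 8+3 in (2,3)
        assert A[5, 7] == 0.5 and A[5, 11] == 0.5

    @settings(deadline=None, max_examples=25)
    @given(p=st.integers(2, 9), k=st.integers(1, 6))
    def test_row_sums_exactly_one(self, p, k):
        A = pl.build_weight_matrix(p, k)
        assert np.allclose(A.sum(axis=1), 1.0, atol=1e-12)

    @settings(deadline=None, max_examples=10)
    @given(p=st.integers(2, 6), k=st.integers(1, 4), seed=st.integers(0, 99))
    def test_averaging_consistent_stack_is_exact(self, p, k, seed):
        # a stack whose duplicates agree is reproduced without drift
        rng = np.random.default_rng(seed)
        target = rng.normal(size=(p, k))
        idx = pl.enumerate_pairs(p)
        stacked = np.concatenate([
            np.concatenate([target[r - 1], target[s - 1]])
            for (r, s) in idx.pairs])
        A = pl.build_weight_matrix(p, k)
        assert np.max(np.abs(A @ stacked - target.ravel())) < 1e-12


class TestSandwich:
    def test_single_pair_equals_direct_cluster_robust(self, bivariate_data):
        data, _, _ = bivariate_data
        fit = fit_bivariate(data, ModelSpec((1, 2), terms=SMALL_TERMS,
                                            n_quad=9))
        st_ = pl.sandwich_empirical(pl.stack([fit], pl.enumerate_pairs(2)))
        info = -fit.per_cluster_hessians.sum(axis=0)
        binv = np.linalg.inv(info)
        direct = binv @ (fit.per_cluster_scores.T
                         @ fit.per_cluster_scores) @ binv
        nb = 2 * fit.k
        assert np.allclose(st_.omega, direct[:nb, :nb], atol=1e-10)

    def test_disjoint_clusters_zero_cross_blocks(self):
        idx = pl.enumerate_pairs(3)
        rng = np.random.default_rng(1)
        k = 2
        clusters = {(1, 2): np.arange(0, 5), (1, 3): np.arange(0, 5),
                    (2, 3): np.arange(10, 15)}  # third pair disjoint
        fits = [fake_fit(pr, k, cluster_ids=clusters[pr],
                         scores=rng.normal(size=(5, 2 * k + 3)))
                for pr in idx.pairs]
        st_ = pl.sandwich_empirical(pl.stack(fits, idx))
        G = st_.G
        n_par = 2 * k + 3
        cross_13_23 = G[n_par:2 * n_par, 2 * n_par:]
        assert np.allclose(cross_13_23, 0.0)
        cross_12_13 = G[:n_par, n_par:2 * n_par]
        assert np.abs(cross_12_13).max() > 0  # shared clusters do correlate

    def test_literal_recipe_matches_matrix_oracle(self):
        # well-conditioned toy fixture: 2 pairs, 3 clusters, tiny design
        rng = np.random.default_rng(4)
        k = 2
        X = np.column_stack([np.ones(6), rng.normal(size=6)])
        idx = pl.enumerate_pairs(3)
        Ds = {pr: np.array([[0.6, 0.2], [0.2, 0.9]]) for pr in idx.pairs}
        fits = [fake_fit(pr, k, D=Ds[pr], X=X) for pr in idx.pairs]
        st_ = pl.stack(fits, idx)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            st_ = pl.sandwich_literal_recipe(st_)
        # independent step-by-step loop computation
        N = 6
        nb = 2 * k
        J = np.zeros((nb * 3, nb * 3))
        K = np.zeros((nb * 3, 2 * N))
        for qi, pr in enumerate(idx.pairs):
            D = Ds[pr]
            for i in range(N):
                Xi = np.zeros((2, nb))
                Xi[0, :k] = X[i]
                Xi[1, k:] = X[i]
                J[qi * nb:(qi + 1) * nb, qi * nb:(qi + 1) * nb] += Xi.T @ D @ Xi
                K[qi * nb:(qi + 1) * nb, 2 * i:2 * i + 2] = Xi.T @ D
        H, G = J / N, K @ K.T / N
        omega = np.linalg.inv(H) @ G @ np.linalg.inv(H)
        assert np.allclose(st_.omega, omega, atol=1e-8)
        assert st_.H.shape == (nb * 3, nb * 3)

    def test_literal_recipe_zero_random_effects_is_singular(self):
        # the literal formula with Z = 0 gives T = 0, hence singular J
        X = np.column_stack([np.ones(4), np.arange(4.0)])
        fits = [fake_fit((1, 2), 2, D=np.zeros((2, 2)), X=X)]
        st_ = pl.stack(fits, pl.enumerate_pairs(2))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with pytest.raises(ValueError, match="singular"):
                pl.sandwich_literal_recipe(st_)

    def test_literal_recipe_warns(self):
        X = np.column_stack([np.ones(4), np.arange(4.0)])
        fits = [fake_fit((1, 2), 2, X=X)]
        st_ = pl.stack(fits, pl.enumerate_pairs(2))
        with pytest.warns(UserWarning, match="inverse"):
            pl.sandwich_literal_recipe(st_)


class TestCombine:
    def test_identity_omega_variance_halves(self):
        # p=3, k=1: each row of A has two entries of 1/2 -> 2 (1/2)^2 = 0.5
        idx = pl.enumerate_pairs(3)
        fits = [fake_fit(pr, 1, beta=np.ones((2, 1))) for pr in idx.pairs]
        st_ = pl.stack(fits, idx)
        st_.omega = np.eye(6)
        ce = pl.combine(pl.build_weight_matrix(3, 1), st_)
        assert np.allclose(np.diag(ce.sigma_star), 0.5)
        assert np.allclose(ce.beta_star, 1.0)  # duplicate-consistent stack

    def test_nine_outcome_dimension(self):
        idx = pl.enumerate_pairs(9)
        fits = [fake_fit(pr, 13) for pr in idx.pairs]
        st_ = pl.stack(fits, idx)
        st_.omega = np.eye(936)
        ce = pl.combine(pl.build_weight_matrix(9, 13), st_)
        assert ce.sigma_star.shape == (117, 117)
        assert ce.beta_star.shape == (117,)

    def test_shape_mismatch_rejected(self):
        idx = pl.enumerate_pairs(3)
        fits = [fake_fit(pr, 2) for pr in idx.pairs]
        st_ = pl.stack(fits, idx)
        st_.omega = np.eye(12)
        with pytest.raises(ValueError, match="columns"):
            pl.combine(pl.build_weight_matrix(3, 3), st_)


class TestRubinPooling:
    def test_hand_fixture(self):
        c1 = pl.CombinedEstimates(np.array([1.0]), np.array([[0.5]]), 1, 1, 1)
        c2 = pl.CombinedEstimates(np.array([3.0]), np.array([[0.5]]), 1, 1, 2)
        po = pl.rubin_pool([c1, c2])
        assert po.beta_bar[0] == pytest.approx(2.0, abs=1e-12)
        assert po.W[0, 0] == pytest.approx(0.5, abs=1e-12)
        assert po.B[0, 0] == pytest.approx(2.0, abs=1e-12)
        assert po.V[0, 0] == pytest.approx(0.5 + 1.5 * 2.0, abs=1e-12)

    def test_identical_imputations_give_zero_between(self):
        c = pl.CombinedEstimates(np.array([1.0, -1.0]), np.eye(2), 2, 1)
        po = pl.rubin_pool([c, c, c])
        assert np.allclose(po.B, 0.0)
        assert np.allclose(po.V, po.W)

    def test_single_imputation_rejected(self):
        c = pl.CombinedEstimates(np.array([1.0]), np.eye(1), 1, 1)
        with pytest.raises(ValueError, match="M >= 2"):
            pl.rubin_pool([c])


class TestWald:
    def test_selector_positions_for_interaction(self):
        spec = pl.build_L("time_x_arm", 9, 13)
        assert spec.L.shape == (9, 117)
        # coefficient 13 of each outcome block (0-based 12, 25, ..., 116)
        for r in range(9):
            row = np.where(spec.L[r] == 1)[0]
            assert row.tolist() == [r * 13 + 12]
            assert (spec.L[r] != 0).sum() == 1
        assert spec.df == 9

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            pl.build_L("nope", 9, 13)

    def test_null_beta_gives_zero_statistic(self):
        spec = pl.build_L("arm", 3, 13)
        res = pl.wald_joint_test(spec, np.zeros(39), np.eye(39))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_one_df_equals_squared_z(self):
        from scipy import stats
        L = pl.WaldSpec(np.array([[1.0, 0.0]]), "c")
        V = np.diag([0.04, 1.0])
        beta = np.array([0.5, 2.0])
        res = pl.wald_joint_test(L, beta, V)
        z = 0.5 / 0.2
        assert res.statistic == pytest.approx(z ** 2, rel=1e-12)
        assert res.p_value == pytest.approx(2 * stats.norm.sf(z), rel=1e-9)

    def test_singular_contrast_covariance_rejected(self):
        L = pl.WaldSpec(np.eye(2), "c")
        V = np.ones((2, 2))
        with pytest.raises(ValueError, match="condition"):
            pl.wald_joint_test(L, np.ones(2), V)
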