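"""Connectivity estimators, similarity graph and Laplacian construction."""

import numpy as np
import pytest

from sgrnet import (
    BoldTimeSeries,
    ConnectivityMatrix,
    SimilarityGraph,
    SolverConfig,
    build_laplacian,
    build_similarity,
    estimate,
    graph_penalty,
    normalize_weights,
    pearson_fcn,
    sgr_objective,
    standardize,
    symmetrize,
    threshold_by_sparsity,
)
from sgrnet.solver import smooth_objective
from sgrnet.types import InvariantError


def oracle_pearson(x: np.ndarray) -> np.ndarray:
    """Entrywise covariance/variance ratio, coded independently."""
    n = x.shape[1]
    w = np.eye(n)
    for i in range(n):
        for j in range(n):
            xi = x[:, i] - x[:, i].mean()
            xj = x[:, j] - x[:, j].mean()
            w[i, j] = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
    return w


class TestStandardize:
    def test_single_column_moments(self):
        ts = BoldTimeSeries(np.array([[1.0, 0.0], [2.0, 1.0], [3.0, -1.0]]))
        z = standardize(ts)
        assert np.allclose(z.data.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(z.data.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_idempotent(self, std_ts):
        again = standardize(std_ts)
        assert np.max(np.abs(again.data - std_ts.data)) < 1e-12

    def test_random_matrix_moments(self):
        rng = np.random.default_rng(0)
        z = standardize(BoldTimeSeries(rng.standard_normal((20, 5))))
        assert np.all(np.abs(z.data.mean(axis=0)) < 1e-10)
        assert np.all(np.abs(z.data.std(axis=0, ddof=1) - 1) < 1e-10)

    def test_constant_column_names_roi(self):
        ts = BoldTimeSeries(np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]))
        with pytest.raises(InvariantError, match="1"):
            standardize(ts)


class TestPearson:
    def test_identical_columns_give_one(self, toy_ts):
        w = pearson_fcn(toy_ts).weights
        assert w[0, 1] == pytest.approx(1.0)

    def test_sign_flip_gives_minus_one(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(10)
        ts = BoldTimeSeries(np.column_stack([x, -x]))
        assert pearson_fcn(ts).weights[0, 1] == pytest.approx(-1.0)

    def test_toy_matrix_matches_bruteforce(self, toy_ts):
        w = pearson_fcn(toy_ts).weights
        assert np.allclose(w, oracle_pearson(toy_ts.data), atol=1e-12)

    def test_bounds_and_affine_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((25, 4))
        w1 = pearson_fcn(BoldTimeSeries(x)).weights
        assert np.all(np.abs(w1) <= 1.0)
        scaled = x * np.array([2.0, 0.5, 3.0, 10.0]) + np.array([1.0, -4.0, 0.0, 7.0])
        w2 = pearson_fcn(BoldTimeSeries(scaled)).weights
        assert np.allclose(w1, w2, atol=1e-12)


class TestThresholdBySparsity:
    def test_keep_all_is_noop(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal((5, 5))
        w = ConnectivityMatrix((a + a.T) / 2)
        out = threshold_by_sparsity(w, 1.0)
        assert np.array_equal(out.weights, w.weights)

    def test_forced_ordering_three_nodes(self):
        w = np.array([[1.0, 0.9, 0.5], [0.9, 1.0, -0.1], [0.5, -0.1, 1.0]])
        out = threshold_by_sparsity(ConnectivityMatrix(w), 1 / 3).weights
        assert out[0, 1] == 0.9 and out[0, 2] == 0.0 and out[1, 2] == 0.0
        assert np.allclose(np.diag(out), 1.0)

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal((10, 10))
        w = ConnectivityMatrix((a + a.T) / 2)
        out = threshold_by_sparsity(w, 0.4).weights
        iu, ju = np.triu_indices(10, 1)
        kept = np.count_nonzero(out[iu, ju])
        assert kept == round(0.4 * 45)
        # oracle: sort all |w| and keep the top round(0.4*45)
        mags = np.sort(np.abs(w.weights[iu, ju]))[::-1]
        cut = mags[kept - 1]
        surviving = set(map(tuple, np.argwhere(np.abs(np.triu(out, 1)) > 0)))
        expected = {
            (i, j) for i, j in zip(iu, ju) if abs(w.weights[i, j]) >= cut
        }
        assert surviving == expected

    @pytest.mark.parametrize("bad", [0.0, -0.5, 1.5])
    def test_invalid_fraction(self, bad):
        w = ConnectivityMatrix(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            threshold_by_sparsity(w, bad)

    def test_symmetry_preserved(self):
        rng = np.random.default_rng(6)
        a = rng.standard_normal((8, 8))
        out = threshold_by_sparsity(ConnectivityMatrix((a + a.T) / 2), 0.5)
        assert out.is_symmetric()


class TestSimilarityAndLaplacian:
    def test_anticorrelated_clipped_to_zero(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(12)
        s = build_similarity(BoldTimeSeries(np.column_stack([x, -x])))
        assert s.s[0, 1] == 0.0

    def test_identical_gives_one(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(12)
        s = build_similarity(BoldTimeSeries(np.column_stack([x, x])))
        assert s.s[0, 1] == pytest.approx(1.0)

    def test_toy_matrix_is_clipped_oracle_pc(self, toy_ts):
        s = build_similarity(toy_ts).s
        expected = np.maximum(oracle_pearson(toy_ts.data), 0.0)
        np.fill_diagonal(expected, 0.0)
        assert np.allclose(s, expected, atol=1e-12)

    def test_two_node_normalized(self):
        s = SimilarityGraph(np.array([[0.0, 1.0], [1.0, 0.0]]))
        lap = build_laplacian(s, normalized=True)
        assert np.allclose(lap.l, [[1, -1], [-1, 1]])
        assert np.allclose(np.sort(np.linalg.eigvalsh(lap.l)), [0.0, 2.0])

    def test_isolated_node_identity_row(self):
        s = SimilarityGraph(
            np.array([[0.0, 0.5, 0.0], [0.5, 0.0, 0.0], [0.0, 0.0, 0.0]])
        )
        lap = build_laplacian(s, normalized=True).l
        assert np.allclose(lap[2], [0, 0, 1])
        assert np.allclose(lap[:, 2], [0, 0, 1])

    def test_eigenvalue_bounds_and_row_sums(self):
        rng = np.random.default_rng(1)
        a = np.abs(rng.standard_normal((7, 7)))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        s = SimilarityGraph(a)
        ev = np.linalg.eigvalsh(build_laplacian(s, normalized=True).l)
        assert ev.min() >= -1e-8 and ev.max() <= 2 + 1e-8
        unnorm = build_laplacian(s, normalized=False).l
        assert np.allclose(unnorm.sum(axis=1), 0.0, atol=1e-10)
        assert np.linalg.eigvalsh(unnorm).min() >= -1e-8

    def test_invalid_similarity_rejected(self):
        with pytest.raises(InvariantError):
            SimilarityGraph(np.array([[0.0, -0.2], [-0.2, 0.0]]))
        with pytest.raises(InvariantError):
            SimilarityGraph(np.array([[0.0, 1.0], [0.5, 0.0]]))


class TestGraphPenalty:
    def test_zero_matrix(self):
        s = SimilarityGraph(np.array([[0.0, 1.0], [1.0, 0.0]]))
        lap = build_laplacian(s, normalized=False)
        assert graph_penalty(np.zeros((2, 2)), lap) == 0.0

    def test_identical_rows_vanish_unnormalized(self):
        rng = np.random.default_rng(2)
        a = np.abs(rng.standard_normal((5, 5)))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        lap = build_laplacian(SimilarityGraph(a), normalized=False)
        w = np.tile(rng.standard_normal(5), (5, 1))  # identical rows
        assert abs(graph_penalty(w, lap)) < 1e-10

    def test_pairwise_identity(self):
        rng = np.random.default_rng(3)
        n = 6
        a = np.abs(rng.standard_normal((n, n)))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        lap = build_laplacian(SimilarityGraph(a), normalized=False)
        w = rng.standard_normal((n, n))
        brute = 0.5 * sum(
            a[i, j] * np.sum((w[i] - w[j]) ** 2) for i in range(n) for j in range(n)
        )
        assert graph_penalty(w, lap) == pytest.approx(brute, abs=1e-10)


class TestObjective:
    def test_zero_w_regression(self, std_ts):
        lap = build_laplacian(build_similarity(std_ts))
        val = sgr_objective(std_ts, np.zeros((6, 6)), 1.0, 1.0, lap, "regression")
        assert val == pytest.approx(np.sum(std_ts.data**2))

    def test_covariance_at_gram_with_zero_diag(self, std_ts):
        x = std_ts.data
        gram = x.T @ x
        w = gram.copy()
        np.fill_diagonal(w, 0.0)
        lap = build_laplacian(build_similarity(std_ts))
        val = sgr_objective(std_ts, w, 0.0, 0.0, lap, "covariance")
        assert val == pytest.approx(0.5 * np.sum(np.diag(gram) ** 2))

    def test_matches_naive_termwise_sum(self, std_ts):
        rng = np.random.default_rng(9)
        w = rng.standard_normal((6, 6))
        np.fill_diagonal(w, 0.0)
        lam, beta = 0.7, 1.3
        lap = build_laplacian(build_similarity(std_ts), normalized=True)
        x = std_ts.data
        naive = (
            sum(np.sum((x[:, i] - x @ w[:, i]) ** 2) for i in range(6))
            + lam * sum(abs(w[i, j]) for i in range(6) for j in range(6) if i != j)
            + beta * sum(w[:, c] @ lap.l @ w[:, c] for c in range(6))
        )
        val = sgr_objective(std_ts, w, lam, beta, lap, "regression")
        assert val == pytest.approx(naive, rel=1e-10)

    def test_negative_hyperparameters_rejected(self, std_ts):
        lap = build_laplacian(build_similarity(std_ts))
        with pytest.raises(ValueError):
            sgr_objective(std_ts, np.zeros((6, 6)), -1.0, 0.0, lap)


class TestEstimateDispatch:
    def test_huge_lambda_gives_zero(self, std_ts):
        x = std_ts.data
        lam = 2.0 * np.max(np.abs(x.T @ x - np.diag(np.diag(x.T @ x))))
        res = estimate(std_ts, SolverConfig(lam=lam, beta=0.0))
        assert np.all(res.w.weights == 0.0)
        # 0 satisfies the lasso optimality condition ||grad(0)||_inf <= lam
        grad0 = -2.0 * x.T @ x
        off = ~np.eye(6, dtype=bool)
        assert np.max(np.abs(grad0[off])) <= lam

    def test_matches_lasso_oracle(self, std_ts):
        from sklearn.linear_model import Lasso

        lam = 0.5
        res = estimate(std_ts, SolverConfig(lam=lam, tol=1e-12, max_iter=20000))
        x = std_ts.data
        t, n = x.shape
        oracle = np.zeros((n, n))
        for i in range(n):
            idx = [j for j in range(n) if j != i]
            model = Lasso(alpha=lam / (2 * t), fit_intercept=False, tol=1e-12,
                          max_iter=100000)
            model.fit(x[:, idx], x[:, i])
            oracle[idx, i] = model.coef_
        assert np.max(np.abs(oracle - res.w.weights)) < 1e-4

    def test_unpenalized_matches_least_squares(self):
        rng = np.random.default_rng(10)
        ts = standardize(BoldTimeSeries(rng.standard_normal((50, 5))))
        res = estimate(ts, SolverConfig(lam=0.0, beta=0.0, tol=1e-14, max_iter=50000))
        x = ts.data
        for i in range(5):
            idx = [j for j in range(5) if j != i]
            coef = np.linalg.lstsq(x[:, idx], x[:, i], rcond=None)[0]
            assert np.max(np.abs(res.w.weights[idx, i] - coef)) < 1e-6

    def test_estimator_tags(self, std_ts):
        assert estimate(std_ts, SolverConfig(lam=0.5, beta=0.0)).w.estimator_tag == "SR"
        assert estimate(std_ts, SolverConfig(lam=0.0, beta=0.5)).w.estimator_tag == "GR"
        assert estimate(std_ts, SolverConfig(lam=0.5, beta=0.5)).w.estimator_tag == "SGR"

    def test_beta_penalizes_sr_solution(self, std_ts):
        """Convexity sanity: the SGR minimizer beats the SR solution on the
        SGR objective when beta > 0."""
        lam, beta = 0.3, 2.0
        sr = estimate(std_ts, SolverConfig(lam=lam, beta=0.0, tol=1e-10))
        sgr = estimate(std_ts, SolverConfig(lam=lam, beta=beta, tol=1e-10))
        lap = sgr.laplacian
        obj_sr = sgr_objective(std_ts, sr.w.weights, lam, beta, lap)
        obj_sgr = sgr_objective(std_ts, sgr.w.weights, lam, beta, lap)
        assert obj_sgr <= obj_sr + 1e-8

    def test_similarity_override_is_used(self, std_ts):
        s = np.zeros((6, 6))
        s[0, 1] = s[1, 0] = 1.0
        cfg = SolverConfig(lam=0.2, beta=1.0, similarity_override=SimilarityGraph(s))
        res = estimate(std_ts, cfg)
        expected = build_laplacian(SimilarityGraph(s), normalized=True).l
        assert np.allclose(res.laplacian.l, expected)


class TestSymmetrizeNormalize:
    def test_symmetrize_examples(self):
        w = ConnectivityMatrix(np.array([[0.0, 1.0], [0.0, 0.0]]))
        out = symmetrize(w)
        assert np.allclose(out.weights, [[0.0, 0.5], [0.5, 0.0]])
        assert np.array_equal(symmetrize(out).weights, out.weights)

    def test_symmetrize_is_frobenius_projection(self):
        rng = np.random.default_rng(11)
        w = rng.standard_normal((5, 5))
        proj = symmetrize(ConnectivityMatrix(w)).weights
        # any symmetric perturbation moves farther from w
        for _ in range(10):
            p = rng.standard_normal((5, 5)) * 0.1
            p = (p + p.T) / 2
            assert np.linalg.norm(proj - w) <= np.linalg.norm(proj + p - w) + 1e-12

    def test_normalize_scales_and_preserves_ratios(self):
        rng = np.random.default_rng(12)
        w = rng.standard_normal((4, 4)) * 2.0
        out = normalize_weights(ConnectivityMatrix(w)).weights
        assert np.max(np.abs(out)) == pytest.approx(1.0)
        nz = w != 0
        ratio = out[nz] / w[nz]
        assert np.max(np.abs(ratio - ratio.flat[0])) < 1e-12

    def test_normalize_zero_matrix_unchanged(self):
        out = normalize_weights(ConnectivityMatrix(np.zeros((3, 3))))
        assert np.array_equal(out.weights, np.zeros((3, 3)))
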