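import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from nrlmf import AssociationMatrix, EntityIndex, NRLMF, SimilarityMatrix
from nrlmf.model import (
    Hyperparameters,
    association_probability,
    gradients,
    knn_adjacency,
    laplacian,
    objective,
    smooth_latent,
)


def _random_similarity(k, rng):
    vals = rng.random((k, k))
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 1.0)
    return vals


def _problem(m=7, n=5, r=3, seed=0, density=0.3):
    rng = np.random.default_rng(seed)
    Y = (rng.random((m, n)) < density).astype(float)
    SR = _random_similarity(m, rng)
    SD = _random_similarity(n, rng)
    L_r = laplacian(knn_adjacency(SR, 3))
    L_d = laplacian(knn_adjacency(SD, 3))
    U = rng.standard_normal((m, r))
    V = rng.standard_normal((n, r))
    return Y, SR, SD, L_r, L_d, U, V


class TestKnnAdjacency:
    def test_keeps_only_top_neighbor(self):
        S = np.array([[1.0, 0.9, 0.2], [0.9, 1.0, 0.6], [0.2, 0.6, 1.0]])
        A = knn_adjacency(S, 1)
        np.testing.assert_array_equal(A[0], [0.0, 0.9, 0.0])
        np.testing.assert_array_equal(A[2], [0.0, 0.6, 0.0])

    def test_large_k_equals_zero_diagonal_similarity(self):
        rng = np.random.default_rng(0)
        S = _random_similarity(5, rng)
        A = knn_adjacency(S, 10)
        expected = S.copy()
        np.fill_diagonal(expected, 0.0)
        np.testing.assert_array_equal(A, expected)

    def test_ties_resolve_to_lowest_index(self):
        S = np.full((4, 4), 0.5)
        np.fill_diagonal(S, 1.0)
        A = knn_adjacency(S, 1)
        assert A[0, 1] == 0.5 and A[0, 2] == 0.0
        assert A[1, 0] == 0.5 and A[1, 2] == 0.0

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError):
            knn_adjacency(np.eye(3), 0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 6))
    def test_row_support_bounded_and_off_diagonal(self, seed, k):
        S = _random_similarity(7, np.random.default_rng(seed))
        A = knn_adjacency(S, k)
        assert (np.count_nonzero(A, axis=1) <= k).all()
        assert (np.diag(A) == 0).all()


class TestLaplacian:
    def test_two_node_hand_value(self):
        A = np.array([[0.0, 1.0], [0.0, 0.0]])
        np.testing.assert_array_equal(laplacian(A), [[1.0, -1.0], [-1.0, 1.0]])

    def test_zero_adjacency_gives_zero(self):
        np.testing.assert_array_equal(laplacian(np.zeros((3, 3))), np.zeros((3, 3)))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_quadratic_identity_and_nullspace(self, seed):
        rng = np.random.default_rng(seed)
        A = knn_adjacency(_random_similarity(6, rng), 2)
        L = laplacian(A)
        U = rng.standard_normal((6, 3))
        brute = 0.5 * sum(
            A[i, mu] * np.sum((U[i] - U[mu]) ** 2)
            for i in range(6) for mu in range(6)
        )
        assert 0.5 * np.trace(U.T @ L @ U) == pytest.approx(brute, abs=1e-10)
        np.testing.assert_allclose(L @ np.ones(6), 0.0, atol=1e-12)
        assert np.linalg.eigvalsh(L).min() > -1e-10  # positive semidefinite


class TestAssociationProbability:
    def test_zero_inner_product_is_half(self):
        U = np.zeros((2, 3))
        V = np.zeros((2, 3))
        np.testing.assert_array_equal(association_probability(U, V), 0.5)

    def test_log_three_gives_three_quarters(self):
        U = np.array([[np.log(3.0)]])
        V = np.array([[1.0]])
        assert association_probability(U, V)[0, 0] == pytest.approx(0.75, rel=1e-12)

    def test_huge_inner_product_stays_finite(self):
        U = np.array([[1000.0]])
        V = np.array([[1.0]])
        p = association_probability(U, V)[0, 0]
        assert np.isfinite(p) and p < 1.0


class TestObjectiveAndGradients:
    def test_value_at_origin(self):
        m, n, c, k = 4, 3, 5.0, 2
        Y = np.zeros((m, n))
        Y[0, 0] = Y[1, 2] = 1.0
        U = np.zeros((m, 2))
        V = np.zeros((n, 2))
        L0_r, L0_d = np.zeros((m, m)), np.zeros((n, n))
        f = objective(U, V, Y, c, 1e-300, 1e-300, 0.0, 0.0, L0_r, L0_d)
        assert f == pytest.approx((m * n + (c - 1) * k) * np.log(2.0), rel=1e-12)

    def test_regularizers_vanish_at_origin(self):
        Y, SR, SD, L_r, L_d, U, V = _problem()
        f = objective(np.zeros_like(U), np.zeros_like(V), Y, 5.0,
                      3.0, 7.0, 2.0, 4.0, L_r, L_d)
        f0 = objective(np.zeros_like(U), np.zeros_like(V), Y, 5.0,
                       1e-9, 1e-9, 0.0, 0.0, L_r, L_d)
        assert f == pytest.approx(f0, rel=1e-12)

    def test_reduces_to_plain_logistic_mf_loss(self):
        """With c = 1 and no graph terms the objective is the plain
        weighted-free logistic loss plus Frobenius penalties."""
        Y, SR, SD, L_r, L_d, U, V = _problem(seed=3)
        lam = 0.7
        f = objective(U, V, Y, 1.0, lam, lam, 0.0, 0.0, L_r, L_d)
        X = U @ V.T
        plain = np.sum(np.log1p(np.exp(-np.abs(X))) + np.maximum(X, 0.0) - Y * X)
        plain += 0.5 * lam * (np.sum(U**2) + np.sum(V**2))
        assert f == pytest.approx(plain, rel=1e-10)

    def test_gradients_match_finite_differences(self):
        Y, SR, SD, L_r, L_d, U, V = _problem(seed=9)
        args = (Y, 5.0, 0.3, 0.6, 0.2, 0.4, L_r, L_d)

        def f(U, V):
            return objective(U, V, *args)

        P = association_probability(U, V)
        dU, dV = gradients(U, V, Y, P, *args[1:-2], L_r, L_d)
        eps = 1e-6
        for M, dM, which in ((U, dU, "U"), (V, dV, "V")):
            for _ in range(5):
                rng = np.random.default_rng(hash(which) % 2**31)
                i, j = rng.integers(M.shape[0]), rng.integers(M.shape[1])
                Mp, Mm = M.copy(), M.copy()
                Mp[i, j] += eps
                Mm[i, j] -= eps
                if which == "U":
                    num = (f(Mp, V) - f(Mm, V)) / (2 * eps)
                else:
                    num = (f(U, Mp) - f(U, Mm)) / (2 * eps)
                assert dM[i, j] == pytest.approx(num, rel=1e-5, abs=1e-8)

    def test_zero_v_and_regularizers_zero_gradient(self):
        Y, SR, SD, L_r, L_d, U, V = _problem()
        V0 = np.zeros_like(V)
        P = association_probability(U, V0)
        dU, _ = gradients(U, V0, Y, P, 5.0, 1e-300, 1.0, 0.0, 1.0, L_r, L_d)
        np.testing.assert_allclose(dU, 0.0, atol=1e-290)

    def test_importance_weight_inactive_without_positives(self):
        Y0 = np.zeros((7, 5))
        _, SR, SD, L_r, L_d, U, V = _problem()
        P = association_probability(U, V)
        dU1, _ = gradients(U, V, Y0, P, 1.0, 0.3, 0.3, 0.1, 0.1, L_r, L_d)
        dU9, _ = gradients(U, V, Y0, P, 9.0, 0.3, 0.3, 0.1, 0.1, L_r, L_d)
        np.testing.assert_array_equal(dU1, dU9)


def _model(Y_vals, seed=0, **hyper_kw):
    m, n = Y_vals.shape
    rng = np.random.default_rng(seed + 100)
    Y = AssociationMatrix(Y_vals, EntityIndex([f"r{i}" for i in range(m)]),
                          EntityIndex([f"d{j}" for j in range(n)]))
    SR = SimilarityMatrix(_random_similarity(m, rng), Y.mirna_index, "SR")
    SD = SimilarityMatrix(_random_similarity(n, rng), Y.disease_index, "SD")
    kw = dict(r=4, max_iter=60, K1=3, K2=2)
    kw.update(hyper_kw)
    return NRLMF(Y, SR, SD, Hyperparameters(**kw))


class TestFit:
    def test_objective_decreases_on_planted_world(self, tiny_world):
        from nrlmf.evaluation import _Pipeline
        h = Hyperparameters(r=5)
        pipe = _Pipeline(tiny_world.Y, tiny_world.MS, tiny_world.ontology, h)
        sr, sd = pipe._similarities(tiny_world.Y)
        res = NRLMF(tiny_world.Y, sr, sd, h).fit(seed=0)
        assert res.objective_trace[-1] < res.objective_trace[0]
        assert len(res.objective_trace) == h.max_iter + 1

    def test_zero_iterations_returns_initialization(self):
        rng = np.random.default_rng(2)
        model = _model((rng.random((6, 4)) < 0.4).astype(float), max_iter=0)
        res = model.fit(seed=5)
        U0, V0 = model.initialize(5)
        np.testing.assert_array_equal(res.U, U0)
        np.testing.assert_array_equal(res.V, V0)

    def test_same_seed_is_bitwise_identical(self):
        rng = np.random.default_rng(3)
        Yv = (rng.random((8, 6)) < 0.4).astype(float)
        res1 = _model(Yv).fit(seed=11)
        res2 = _model(Yv).fit(seed=11)
        np.testing.assert_array_equal(res1.U, res2.U)
        np.testing.assert_array_equal(res1.V, res2.V)
        np.testing.assert_array_equal(res1.objective_trace, res2.objective_trace)

    def test_gradient_accumulators_nonnegative(self):
        rng = np.random.default_rng(4)
        res = _model((rng.random((6, 4)) < 0.4).astype(float)).fit(seed=0)
        assert (res.factors.grad_accum_U >= 0).all()
        assert (res.factors.grad_accum_V >= 0).all()

    def test_index_mismatch_rejected(self):
        rng = np.random.default_rng(5)
        Y = AssociationMatrix(np.ones((2, 2)), EntityIndex(["r1", "r2"]),
                              EntityIndex(["d1", "d2"]))
        bad = SimilarityMatrix(np.eye(2), EntityIndex(["x", "y"]), "SR")
        good = SimilarityMatrix(np.eye(2), Y.disease_index, "SD")
        with pytest.raises(ValueError, match="miRNA similarity"):
            NRLMF(Y, bad, good)

    def test_summary_reports_dimensions(self):
        rng = np.random.default_rng(6)
        res = _model((rng.random((6, 4)) < 0.4).astype(float)).fit(seed=0)
        text = res.summary()
        assert "miRNAs (m)" in text and "final objective" in text


class TestSmoothing:
    def test_single_neighbor_copies_vector(self):
        U = np.array([[1.0, 2.0], [9.0, 9.0]])
        Y = np.array([[1.0], [0.0]])
        SR = np.array([[1.0, 0.8], [0.8, 1.0]])
        SD = np.array([[1.0]])
        U_s, _ = smooth_latent(U, np.zeros((1, 2)), Y, SR, SD, k2=1)
        np.testing.assert_array_equal(U_s[1], U[0])

    def test_warm_entities_unchanged(self):
        U = np.array([[1.0, 2.0], [3.0, 4.0]])
        Y = np.array([[1.0], [1.0]])
        U_s, _ = smooth_latent(U, np.zeros((1, 2)), Y,
                               np.eye(2), np.array([[1.0]]), k2=1)
        np.testing.assert_array_equal(U_s, U)

    def test_weighted_average_hand_value(self):
        U = np.array([[1.0, 0.0], [0.0, 1.0], [5.0, 5.0]])
        Y = np.array([[1.0], [1.0], [0.0]])
        SR = np.array([[1.0, 0.0, 0.6], [0.0, 1.0, 0.2], [0.6, 0.2, 1.0]])
        U_s, _ = smooth_latent(U, np.zeros((1, 2)), Y, SR, np.array([[1.0]]), k2=2)
        np.testing.assert_allclose(U_s[2], [0.75, 0.25], atol=1e-12)

    def test_zero_similarities_fall_back_to_plain_mean(self):
        U = np.array([[1.0, 0.0], [0.0, 1.0], [9.0, 9.0]])
        Y = np.array([[1.0], [1.0], [0.0]])
        SR = np.eye(3)
        U_s, _ = smooth_latent(U, np.zeros((1, 2)), Y, SR, np.array([[1.0]]), k2=2)
        np.testing.assert_allclose(U_s[2], [0.5, 0.5], atol=1e-12)

    def test_no_positive_pool_rejected(self):
        with pytest.raises(ValueError, match="training association"):
            smooth_latent(np.zeros((2, 2)), np.zeros((1, 2)),
                          np.zeros((2, 1)), np.eye(2), np.eye(1), k2=1)


class TestPredict:
    def test_without_cold_entities_equals_raw_probability(self):
        rng = np.random.default_rng(7)
        Yv = np.ones((4, 3))  # every entity warm
        res = _model(Yv).fit(seed=0)
        np.testing.assert_array_equal(res.predict(smooth=True),
                                      association_probability(res.U, res.V))

    def test_duplicated_mirna_inherits_score_row(self):
        # a cold miRNA with similarity 1 to exactly one warm miRNA and 0 to
        # the rest copies that miRNA's latent vector, hence its score row
        rng = np.random.default_rng(8)
        Yv = (rng.random((5, 4)) < 0.5).astype(float)
        Yv[1] = 1.0  # warm template row
        Yv[4] = 0.0  # cold row
        m = 5
        SRv = np.eye(m)
        SRv[4, 1] = SRv[1, 4] = 1.0
        Y = AssociationMatrix(Yv, EntityIndex([f"r{i}" for i in range(m)]),
                              EntityIndex([f"d{j}" for j in range(4)]))
        SR = SimilarityMatrix(SRv, Y.mirna_index, "SR")
        SD = SimilarityMatrix(_random_similarity(4, rng), Y.disease_index, "SD")
        res = NRLMF(Y, SR, SD, Hyperparameters(r=3, max_iter=30, K1=2, K2=1)).fit(seed=0)
        scores = res.predict()
        np.testing.assert_allclose(scores[4], scores[1], atol=1e-12)


class TestHyperparameters:
    @pytest.mark.parametrize(
        "kw",
        [dict(r=0), dict(lambda_r=0.0), dict(c=0.5), dict(gamma=0.0),
         dict(K1=0), dict(alpha=-1.0), dict(max_iter=-1)],
    )
    def test_invalid_values_rejected(self, kw):
        with pytest.raises(ValueError):
            Hyperparameters(**kw)
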