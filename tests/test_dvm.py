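"""The discriminative vector machine: neighbours, weights, solver, HQ loop."""

import numpy as np
import pytest
from scipy.optimize import minimize

from ppidvm import (
    DVMModel,
    DVMParams,
    find_neighbors,
    predict,
    predict_one,
    residual_margin,
    solve_beta,
    welsch_weights,
)


def fixed_p_objective(y, Xk, beta, p, L, delta, gamma_reg):
    """Independent evaluation of the fixed-weight objective."""
    r = y - Xk.T @ beta
    return r @ (p * r) + delta * beta @ beta + gamma_reg * beta @ L @ beta


class TestNeighbors:
    def test_self_neighbor_k1(self, rng):
        X = rng.normal(size=(6, 4))
        model = DVMModel(X, np.ones(6, dtype=int))
        nb = find_neighbors(model, X[2], k=1)
        assert nb.indices[0] == 2
        np.testing.assert_allclose(nb.W, [[1.0]])
        np.testing.assert_allclose(nb.L, [[0.0]])

    def test_matches_brute_force_sort(self, rng):
        X = rng.normal(size=(10, 5))
        y = rng.normal(size=5)
        model = DVMModel(X, np.ones(10, dtype=int))
        nb = find_neighbors(model, y, k=5)
        brute = sorted(range(10), key=lambda i: (np.linalg.norm(X[i] - y), i))[:5]
        np.testing.assert_array_equal(nb.indices, brute)

    @pytest.mark.parametrize("seed", range(4))
    def test_laplacian_identities(self, seed):
        g = np.random.default_rng(seed)
        X = g.normal(size=(12, 6))
        model = DVMModel(X, np.ones(12, dtype=int))
        nb = find_neighbors(model, g.normal(size=6), k=7)
        np.testing.assert_allclose(nb.L, nb.D - nb.W)
        np.testing.assert_allclose(nb.L.sum(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(nb.L, nb.L.T)
        assert np.linalg.eigvalsh(nb.L).min() >= -1e-10
        assert nb.W.min() >= 0.0 and nb.W.max() <= 1.0

    def test_k_larger_than_n_rejected(self, rng):
        model = DVMModel(rng.normal(size=(4, 3)), np.ones(4, dtype=int))
        with pytest.raises(ValueError, match="exceeds"):
            find_neighbors(model, np.zeros(3), k=5)

    def test_zero_norm_row_gets_zero_similarity(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        model = DVMModel(X, np.ones(3, dtype=int))
        nb = find_neighbors(model, np.array([0.0, 0.0]), k=3)
        zero_row = int(np.where(nb.indices == 0)[0][0])
        off_diag = np.delete(nb.W[zero_row], zero_row)
        np.testing.assert_allclose(off_diag, 0.0)

    def test_laplacian_quadratic_form_equals_double_sum(self, rng):
        # ties the matrix form b'Lb to the pairwise smoothness penalty
        for _ in range(5):
            k = 6
            W = rng.uniform(0, 1, size=(k, k))
            W = (W + W.T) / 2
            np.fill_diagonal(W, 1.0)
            L = np.diag(W.sum(axis=1)) - W
            b = rng.normal(size=k)
            double_sum = sum(
                W[p, q] * (b[p] - b[q]) ** 2
                for p in range(k) for q in range(p + 1, k)
            )
            assert b @ L @ b == pytest.approx(double_sum, abs=1e-10)


class TestWelschWeights:
    def test_perfect_fit_gives_unit_weights(self):
        y = np.array([1.0, 2.0, 3.0])
        Xk = y.reshape(1, 3)
        p, sigma = welsch_weights(y, Xk, np.array([1.0]))
        np.testing.assert_array_equal(p, 1.0)
        assert sigma == 0.0

    def test_equal_magnitude_residuals(self):
        # |r_i| all equal with theta=1: sigma^2 = r^2, every weight e^-1
        y = np.array([1.0, -1.0, 1.0, -1.0]) * 0.3
        Xk = np.zeros((2, 4))
        p, sigma = welsch_weights(y, Xk, np.zeros(2), theta=1.0)
        np.testing.assert_allclose(p, np.exp(-1.0))
        assert sigma == pytest.approx(0.3)

    def test_largest_residual_gets_smallest_weight(self, rng):
        y = rng.normal(size=8)
        Xk = rng.normal(size=(3, 8))
        beta = rng.normal(size=3)
        p, _ = welsch_weights(y, Xk, beta)
        r = np.abs(y - Xk.T @ beta)
        assert np.argmin(p) == np.argmax(r)
        assert np.all(p > 0) and np.all(p <= 1)

    def test_welsch_loss_shape(self):
        # phi(x) = (1 - exp(-x^2))/2: even, increasing in |x|, in [0, 1/2)
        x = np.linspace(-5, 5, 201)
        phi = 0.5 * (1 - np.exp(-x ** 2))
        assert np.all(phi >= 0) and np.all(phi < 0.5)
        np.testing.assert_allclose(phi, phi[::-1])
        half = phi[x >= 0]
        assert np.all(np.diff(half) >= 0)


class TestSolveBeta:
    def test_scalar_closed_form(self):
        y = np.array([1.0, 2.0, 2.0])
        Xk = y.reshape(1, 3)
        for delta in (1e-1, 1e-3, 1e-6):
            beta = solve_beta(y, Xk, np.ones(3), np.zeros((1, 1)), delta, 0.0)
            expected = (y @ y) / (y @ y + delta)
            assert beta[0] == pytest.approx(expected, rel=1e-12)
        assert solve_beta(y, Xk, np.ones(3), np.zeros((1, 1)), 1e-9, 0.0)[0] == \
            pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_numerical_minimizer(self, seed):
        g = np.random.default_rng(seed)
        k, d = int(g.integers(2, 7)), int(g.integers(3, 9))
        y = g.normal(size=d)
        Xk = g.normal(size=(k, d))
        p = g.uniform(0.1, 1.0, size=d)
        W = g.uniform(0, 1, size=(k, k))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 1.0)
        L = np.diag(W.sum(axis=1)) - W
        delta, gamma_reg = 1e-3, 1e-4

        beta = solve_beta(y, Xk, p, L, delta, gamma_reg)
        res = minimize(
            lambda b: fixed_p_objective(y, Xk, b, p, L, delta, gamma_reg),
            x0=np.zeros(k),
            jac=lambda b: -2 * Xk @ (p * (y - Xk.T @ b))
            + 2 * delta * b + 2 * gamma_reg * (L @ b),
            method="BFGS",
            options={"gtol": 1e-12, "maxiter": 2000},
        )
        np.testing.assert_allclose(beta, res.x, rtol=0, atol=1e-5)

    def test_gradient_stationarity(self, rng):
        k, d = 5, 3
        y = rng.normal(size=d)
        Xk = rng.normal(size=(k, d))
        p = rng.uniform(0.2, 1.0, size=d)
        L = np.eye(k) - np.full((k, k), 1 / k)
        beta = solve_beta(y, Xk, p, L, 1e-3, 1e-4)
        A = Xk.T
        grad = -2 * A.T @ (p * (y - A @ beta)) + 2e-3 * beta + 2e-4 * (L @ beta)
        np.testing.assert_allclose(grad, 0.0, atol=1e-10)

    def test_large_ridge_shrinks_to_zero(self, rng):
        y = rng.normal(size=6)
        Xk = rng.normal(size=(4, 6))
        beta = solve_beta(y, Xk, np.ones(6), np.zeros((4, 4)), 1e9, 0.0)
        np.testing.assert_allclose(beta, 0.0, atol=1e-7)


class TestHalfQuadratic:
    @pytest.mark.parametrize("seed", range(20))
    def test_objective_nonincreasing_across_iterations(self, seed):
        # every solve, for the weights it was given, cannot increase the
        # fixed-P objective (it is that objective's exact minimiser)
        g = np.random.default_rng(seed)
        k, d = 6, 8
        y = g.normal(size=d)
        Xk = g.normal(size=(k, d))
        W = g.uniform(0, 1, size=(k, k))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 1.0)
        L = np.diag(W.sum(axis=1)) - W
        delta, gamma_reg = 1e-3, 1e-4

        p = np.ones(d)
        beta = solve_beta(y, Xk, p, L, delta, gamma_reg)
        for _ in range(10):
            p, _ = welsch_weights(y, Xk, beta)
            before = fixed_p_objective(y, Xk, beta, p, L, delta, gamma_reg)
            beta = solve_beta(y, Xk, p, L, delta, gamma_reg)
            after = fixed_p_objective(y, Xk, beta, p, L, delta, gamma_reg)
            assert after <= before + 1e-9


class TestPrediction:
    def test_memorized_sample_recovered(self, rng):
        X = np.vstack([rng.normal(0, 1, (10, 4)), rng.normal(10, 1, (10, 4))])
        labels = np.array([1] * 10 + [2] * 10)
        model = DVMModel(X, labels, DVMParams(k=8))
        sol = predict_one(model, X[15])
        assert sol.predicted == 2
        assert sol.residuals[2] < 0.2
        assert sol.residuals[2] < sol.residuals[1]

    def test_separable_gaussians_high_accuracy(self, gaussian_task):
        Xtr, ytr, Xte, yte = gaussian_task
        model = DVMModel(Xtr, ytr)
        labels, _ = predict(model, Xte)
        assert np.mean(labels == yte) >= 0.98

    def test_invariant_to_training_order(self, rng):
        X = rng.normal(size=(30, 5))
        labels = np.array([1, 2] * 15)
        y = rng.normal(size=5)
        baseline = predict_one(DVMModel(X, labels, DVMParams(k=10)), y)
        for _ in range(10):
            perm = rng.permutation(30)
            sol = predict_one(DVMModel(X[perm], labels[perm], DVMParams(k=10)), y)
            assert sol.predicted == baseline.predicted
            for c in (1, 2):
                assert sol.residuals[c] == pytest.approx(baseline.residuals[c], abs=1e-9)

    def test_empty_batch(self, rng):
        model = DVMModel(rng.normal(size=(6, 3)), np.array([1, 1, 1, 2, 2, 2]))
        labels, residuals = predict(model, np.empty((0, 3)))
        assert labels.size == 0 and residuals.shape == (0, 2)

    def test_batch_equals_looped_single(self, rng):
        X = rng.normal(size=(20, 4))
        labels = np.array([1, 2] * 10)
        model = DVMModel(X, labels, DVMParams(k=8))
        Y = rng.normal(size=(7, 4))
        batch_labels, batch_res = predict(model, Y)
        for i, row in enumerate(Y):
            sol = predict_one(model, row)
            assert batch_labels[i] == sol.predicted
            np.testing.assert_allclose(
                batch_res[i], [sol.residuals[1], sol.residuals[2]], atol=1e-12
            )

    def test_margin_sign_agrees_with_prediction(self, rng):
        X = np.vstack([rng.normal(0, 1, (15, 3)), rng.normal(4, 1, (15, 3))])
        labels = np.array([1] * 15 + [2] * 15)
        model = DVMModel(X, labels, DVMParams(k=12))
        Y = rng.normal(2, 2, size=(20, 3))
        pred, res = predict(model, Y)
        margin = residual_margin(res)
        assert np.all((margin > 0) == (pred == 2))

    def test_absent_class_gets_query_norm_residual(self):
        X = np.array([[1.0, 0.0], [0.9, 0.1], [1.1, -0.1]])
        model = DVMModel(X, np.array([1, 1, 2]), DVMParams(k=2))
        y = np.array([1.0, 0.05])
        sol = predict_one(model, y)
        present = set(int(c) for c in sol.neighbors.labels)
        for c in (1, 2):
            if c not in present:
                assert sol.residuals[c] == pytest.approx(np.linalg.norm(y))

    def test_robust_to_corrupted_feature_column(self):
        # gross noise on one feature: Welsch weighting should lose less
        # accuracy than an unweighted ridge fit on the same neighbours
        g = np.random.default_rng(3)
        d = 6
        Xtr = np.vstack([g.normal(0, 1, (60, d)), g.normal(4, 1, (60, d))])
        ytr = np.array([1] * 60 + [2] * 60)
        Xte = np.vstack([g.normal(0, 1, (40, d)), g.normal(4, 1, (40, d))])
        yte = np.array([1] * 40 + [2] * 40)
        Xte_bad = Xte.copy()
        Xte_bad[:, 0] += g.normal(0, 60, size=Xte.shape[0])  # corrupted channel

        model = DVMModel(Xtr, ytr, DVMParams(k=20))
        dvm_labels, _ = predict(model, Xte_bad)
        dvm_acc = np.mean(dvm_labels == yte)

        ridge_correct = 0
        for row, truth in zip(Xte_bad, yte):
            nb = find_neighbors(model, row)
            beta = solve_beta(row, nb.Xk, np.ones(d), np.zeros_like(nb.L), 1e-3, 0.0)
            A = nb.Xk.T
            res = {}
            for c in (1, 2):
                mask = nb.labels == c
                res[c] = (np.linalg.norm(row - A[:, mask] @ beta[mask])
                          if mask.any() else np.linalg.norm(row))
            ridge_correct += (min(res, key=res.get) == truth)
        ridge_acc = ridge_correct / len(yte)
        assert dvm_acc >= ridge_acc
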