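import numpy as np
import pytest

from twinnet import (GlassoConvergenceError, ebic, estimate_network,
                     glasso_fit, kkt_residual, precision_to_partial)
from tests.conftest import chain_data
from tests.oracles import glasso_admm


def random_correlation(rng, p, n=80):
    A = rng.standard_normal((n, p))
    return np.corrcoef(A, rowvar=False)


class TestGlassoFit:
    def test_full_shrinkage_gives_diagonal_precision(self, rng):
        C = random_correlation(rng, 5)
        lam = np.abs(C - np.eye(5)).max() + 0.01
        theta = glasso_fit(C, lam)
        assert np.allclose(theta, np.diag(np.diag(theta)))
        assert np.allclose(np.diag(theta), 1.0 / np.diag(C))

    def test_unpenalized_recovers_inverse(self, rng):
        C = random_correlation(rng, 4, n=200)
        theta = glasso_fit(C, 0.0)
        assert np.allclose(theta, np.linalg.inv(C), atol=1e-6)

    def test_matches_admm_reference_solver(self, rng):
        C = random_correlation(rng, 4)
        theta = glasso_fit(C, 0.1)
        reference = glasso_admm(C, 0.1)
        assert np.abs(theta - reference).max() < 1e-4

    def test_kkt_conditions_hold(self, rng):
        for lam in (0.02, 0.1, 0.3):
            C = random_correlation(rng, 6)
            theta = glasso_fit(C, lam)
            assert kkt_residual(C, theta, lam) <= 1e-4

    def test_asymmetric_input_rejected(self, rng):
        S = rng.standard_normal((4, 4))
        with pytest.raises(ValueError, match="symmetric"):
            glasso_fit(S, 0.1)

    def test_negative_penalty_rejected(self, rng):
        with pytest.raises(ValueError, match=">= 0"):
            glasso_fit(np.eye(3), -0.1)

    def test_nonconvergence_raises_with_diagnostics(self, rng):
        C = random_correlation(rng, 6)
        with pytest.raises(GlassoConvergenceError, match="sweeps"):
            glasso_fit(C, 0.05, max_iter=1, tol=1e-14)


class TestPrecisionToPartial:
    def test_two_by_two_example(self):
        W = precision_to_partial(np.array([[2.0, -1.0], [-1.0, 2.0]]))
        assert W[0, 1] == pytest.approx(0.5)
        assert W[0, 0] == 0.0

    def test_diagonal_precision_gives_empty_network(self):
        assert np.array_equal(precision_to_partial(np.diag([1.0, 2.0, 3.0])),
                              np.zeros((3, 3)))

    def test_matches_elementwise_formula(self, rng):
        A = rng.standard_normal((5, 5))
        theta = A @ A.T + 5 * np.eye(5)
        W = precision_to_partial(theta)
        for i in range(5):
            for j in range(5):
                expected = (0.0 if i == j else
                            -theta[i, j] / np.sqrt(theta[i, i] * theta[j, j]))
                assert W[i, j] == pytest.approx(expected, abs=1e-12)

    def test_invalid_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            precision_to_partial(np.array([[1.0, 0.0], [0.0, -1.0]]))


class TestEbic:
    def test_gamma_zero_is_bic(self):
        assert ebic(-50.0, 4, 100, 10, 0.0) == pytest.approx(
            100.0 + 4 * np.log(100))

    def test_zero_edges(self):
        assert ebic(-50.0, 0, 100, 10, 0.5) == pytest.approx(100.0)

    def test_arithmetic_example(self):
        value = ebic(-100.0, 3, 500, 10, 0.5)
        expected = 200.0 + 3 * np.log(500) + 6 * np.log(10)
        assert value == pytest.approx(expected, abs=1e-12)


class TestEstimateNetwork:
    def test_selected_model_minimizes_ebic(self, rng):
        X, _ = chain_data(rng, 8, 500, 0.3)
        model, path = estimate_network(X)
        assert path.ebics[path.selected_index] == path.ebics.min()
        assert model.lambda_selected == path.lambdas[path.selected_index]

    def test_path_has_100_models_and_monotone_edges(self, rng):
        X, _ = chain_data(rng, 8, 500, 0.3)
        _, path = estimate_network(X)
        assert len(path.lambdas) == 100
        assert (np.diff(path.lambdas) < 0).all()
        # edge count non-increasing in lambda (lambdas stored decreasing,
        # so counts are non-decreasing along the stored path); tolerate a
        # single +-1 numerical flip
        increments = np.diff(path.edge_counts.astype(int))
        assert (increments >= -1).all()

    def test_scale_invariance(self, rng):
        X, _ = chain_data(rng, 6, 400, 0.3)
        model_a, _ = estimate_network(X)
        scales = np.array([1.0, 10.0, 0.2, 5.0, 100.0, 0.01])
        model_b, _ = estimate_network(X * scales)
        assert np.allclose(model_a.W, model_b.W, atol=1e-10)

    def test_weight_matrix_invariants(self, rng):
        X, _ = chain_data(rng, 8, 500, 0.3)
        model, _ = estimate_network(X)
        assert np.allclose(model.W, model.W.T)
        assert np.all(np.diag(model.W) == 0)
        assert np.all(np.abs(model.W) < 1)
        # edges vanish exactly together in W and Theta
        off = ~np.eye(8, dtype=bool)
        assert np.array_equal(model.W[off] == 0, model.Theta[off] == 0)
        assert np.linalg.eigvalsh(model.Theta)[0] > 0

    def test_kkt_certified_along_path(self, rng):
        X, _ = chain_data(rng, 6, 400, 0.3)
        n = X.shape[0]
        C = np.corrcoef(X, rowvar=False)
        _, path = estimate_network(X, store_path_models=True)
        for i in range(0, 100, 10):
            assert kkt_residual(C, path.thetas[i], path.lambdas[i]) <= 1e-4

    def test_independent_data_selects_near_empty_graph(self, rng):
        X = rng.standard_normal((2000, 10))
        model, _ = estimate_network(X)
        assert model.n_edges <= 1

    def test_chain_recovery_at_large_n(self, rng):
        X, theta_true = chain_data(rng, 10, 2000, 0.3)
        model, _ = estimate_network(X)
        true_edges = np.abs(np.triu(theta_true, 1)) > 0
        found = np.abs(np.triu(model.W, 1)) > 0
        sensitivity = (found & true_edges).sum() / true_edges.sum()
        false_edges = (found & ~true_edges).sum()
        assert sensitivity >= 8 / 9
        assert false_edges <= 1

    def test_nan_rejected_unless_pairwise(self, rng):
        X, _ = chain_data(rng, 6, 600, 0.35)
        X[:40, 2] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            estimate_network(X)
        model, _ = estimate_network(X, missing="pairwise")
        X_complete = X[40:]
        model_c, _ = estimate_network(X_complete)
        # pairwise estimate close to the complete-case one
        assert np.abs(model.W - model_c.W).max() < 0.15

    def test_degenerate_column_rejected(self, rng):
        X = rng.standard_normal((100, 4))
        X[:, 1] = 7.0
        with pytest.raises(ValueError, match="constant"):
            estimate_network(X)

    def test_edge_list_export(self, rng):
        X, _ = chain_data(rng, 6, 400, 0.3)
        model, _ = estimate_network(X, node_labels=list("abcdef"))
        edges = model.edge_list()
        assert set(edges.columns) == {"node_i", "node_j", "weight"}
        assert len(edges) == model.n_edges
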