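"""Lasso solver and network estimation against closed-form/brute-force oracles."""

import numpy as np
import pytest

from clpnet import (
    EstimationOptions,
    InputError,
    estimate_network,
    fit_node,
    lambda_max,
    lasso_objective,
    simulate_panel,
    standardize,
)

from conftest import make_config, sparse_B


def _design(n, p, seed, beta=None, noise=1.0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    X -= X.mean(axis=0)
    X /= X.std(axis=0, ddof=1)
    if beta is None:
        beta = np.zeros(p)
    y = X @ beta + noise * rng.standard_normal(n)
    y -= y.mean()
    return X, y


class TestObjective:
    def test_zero_beta_value(self):
        X, y = _design(50, 3, 0)
        assert lasso_objective(np.zeros(3), y, X, 0.2) == pytest.approx(
            float(y @ y) / (2 * 50)
        )

    def test_ols_minimizes_unpenalized_objective(self):
        X, y = _design(80, 4, 1, beta=np.array([0.5, 0, -0.3, 0.1]))
        b_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        f_ols = lasso_objective(b_ols, y, X, 0.0)
        rng = np.random.default_rng(2)
        for _ in range(20):
            assert f_ols <= lasso_objective(b_ols + rng.normal(0, 0.3, 4), y, X, 0.0)

    def test_negative_lambda_rejected(self):
        X, y = _design(10, 2, 0)
        with pytest.raises(InputError):
            lasso_objective(np.zeros(2), y, X, -0.1)


def brute_force_lasso(X, y, lam, lim=2.0, step=0.001):
    """Exhaustive 2-D grid minimization of the lasso objective."""
    n = len(y)
    G = X.T @ X / n
    c = X.T @ y / n
    b = np.arange(-lim, lim + step / 2, step)
    b1, b2 = np.meshgrid(b, b, indexing="ij")
    obj = (
        0.5 * (G[0, 0] * b1**2 + G[1, 1] * b2**2)
        + G[0, 1] * b1 * b2
        - c[0] * b1
        - c[1] * b2
        + lam * (np.abs(b1) + np.abs(b2))
    )
    i, j = np.unravel_index(np.argmin(obj), obj.shape)
    return np.array([b[i], b[j]])


class TestFitNode:
    def test_unpenalized_limit_equals_ols(self):
        X, y = _design(500, 3, 3, beta=np.array([0.4, -0.2, 0.0]))
        coef, lam = fit_node(y, X, None, EstimationOptions(lambda_grid=[0.0]))
        b_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert lam == 0.0
        np.testing.assert_allclose(coef, b_ols, atol=1e-6)

    def test_full_shrinkage_above_lambda_max(self):
        X, y = _design(200, 4, 4, beta=np.array([0.3, 0.1, 0, 0]))
        rng = np.random.default_rng(0)
        C = rng.standard_normal((200, 1))
        C -= C.mean()
        mask = np.array([1.0, 1, 1, 1, 0])
        lmax = lambda_max(np.hstack([X, C]), y, mask)
        coef, _ = fit_node(y, X, C, EstimationOptions(lambda_grid=[lmax * 1.1]))
        np.testing.assert_array_equal(coef[:4], 0.0)
        assert coef[4] != 0.0  # covariate unpenalized, still fitted

    def test_matches_brute_force_grid(self):
        X, y = _design(20, 2, 5, beta=np.array([0.6, -0.4]), noise=0.5)
        for lam in (0.05, 0.1, 0.5):
            coef, _ = fit_node(y, X, None, EstimationOptions(lambda_grid=[lam]))
            oracle = brute_force_lasso(X, y, lam, step=0.005)
            np.testing.assert_allclose(coef, oracle, atol=0.006)

    def test_cv_recovers_single_signal(self):
        X, y = _design(1000, 5, 6, beta=np.array([0.5, 0, 0, 0, 0]), noise=0.1)
        coef, _ = fit_node(y, X, None, EstimationOptions(seed=1))
        assert 0.35 <= coef[0] <= 0.55
        np.testing.assert_array_equal(coef[1:], 0.0)

    def test_unpenalized_underdetermined_rejected(self):
        X, y = _design(4, 6, 0)
        with pytest.raises(InputError, match="n="):
            fit_node(y, X, None, EstimationOptions(lambda_grid=[0.0], n_folds=2))

    def test_monotone_shrinkage_in_lambda(self):
        X, y = _design(150, 5, 7, beta=np.array([0.5, -0.3, 0.2, 0, 0]))
        grid = np.geomspace(0.5, 1e-3, 25)
        norms = []
        for lam in grid:
            coef, _ = fit_node(y, X, None, EstimationOptions(lambda_grid=[lam]))
            norms.append(np.abs(coef).max())
        assert (np.diff(norms) >= -1e-10).all()  # sup-norm grows as lambda falls


class TestEstimateNetwork:
    def test_edge_bookkeeping_6_nodes(self):
        data, _ = simulate_panel(make_config(n=120, B=sparse_B(), seed=2))
        std, _ = standardize(data)
        net = estimate_network(std, ["age"], EstimationOptions(seed=0))
        assert net.B.shape == (6, 6)
        assert net.autoregressive().shape == (6,)
        off = ~np.eye(6, dtype=bool)
        assert off.sum() == 30
        types = net.edge_frame()["type"].value_counts()
        assert types["autoregressive"] == 6 and types["cross-lagged"] == 30

    def test_full_network_ols_oracle(self):
        data, _ = simulate_panel(make_config(n=500, p=3, B=np.eye(3) * 0.3, seed=3))
        std, _ = standardize(data)
        net = estimate_network(std, ["age"], EstimationOptions(lambda_grid=[0.0]))
        X = np.hstack(
            [std.frame[std.node_columns("t1")].to_numpy(), std.frame[["age"]].to_numpy()]
        )
        for j, node in enumerate(std.node_names):
            y = std.frame[f"{node}_t2"].to_numpy()
            b_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
            np.testing.assert_allclose(net.B[:, j], b_ols[:3], atol=1e-6)

    def test_sign_recovery_of_strong_group_edge(self):
        """Low-noise simulation recovers the depression->family negative path."""
        B = sparse_B()
        data, _ = simulate_panel(make_config(n=5000, B=B, residual=0.5, seed=4))
        std, _ = standardize(data)
        net = estimate_network(std, ["age"], EstimationOptions(seed=0))
        assert net.B[0, 2] < 0  # generated as -0.19
        assert net.B[0, 3] > 0  # generated as +0.15

    def test_row_order_invariance(self):
        data, _ = simulate_panel(make_config(n=200, B=sparse_B(), seed=8))
        std, _ = standardize(data)
        shuffled = std.subset(np.random.default_rng(9).permutation(200))
        net_a = estimate_network(std, ["age"], EstimationOptions(seed=3))
        net_b = estimate_network(shuffled, ["age"], EstimationOptions(seed=3))
        np.testing.assert_array_equal(net_a.B, net_b.B)

    def test_missing_values_rejected(self):
        data, _ = simulate_panel(make_config(n=50, seed=1, missing_rate=0.1))
        with pytest.raises(InputError):
            estimate_network(data, ["age"], EstimationOptions(seed=0))

    def test_invalid_options_rejected(self):
        with pytest.raises(InputError):
            EstimationOptions(lambda_grid=[0.1, 0.2])  # increasing
        with pytest.raises(InputError):
            EstimationOptions(n_folds=1)
        with pytest.raises(InputError):
            EstimationOptions(lambda_rule="aic")
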