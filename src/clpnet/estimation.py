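"""Directed cross-lagged network estimation via node-wise lasso regression.

Each T2 variable is regressed on all T1 variables plus covariates with an L1
penalty on the T1 coefficients only (covariates are adjustment variables and
stay unpenalized by default). The standardized coefficients form the edge
matrix B with the repo-wide orientation convention

    B[i, j] = effect of node i at T1 on node j at T2,

so the diagonal holds autoregressive paths and off-diagonal entries are
cross-lagged paths. The penalty level is selected per outcome node by K-fold
cross-validated mean squared error, either at the CV minimum (default) or by
the one-standard-error rule.

The solver is cyclic coordinate descent on the Gram form of the objective

    (1 / 2n) * sum((y - X beta)^2) + lambda * sum(mask * |beta|)

computed along a decreasing lambda path with warm starts; per-sweep cost is
independent of n, which keeps bootstrap re-estimation cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .panel import InputError, PanelDataset, node_column

# Convergence of coordinate descent: stop when no coefficient moves more
# than CD_TOL in a full sweep. Kept two orders below the tightest accuracy
# the package asserts against closed-form solutions.
CD_TOL = 1e-8
CD_MAX_ITER = 100_000

DEFAULT_N_LAMBDA = 30
DEFAULT_LAMBDA_MIN_RATIO = 1e-3


@dataclass
class EstimationOptions:
    """Options for node-wise lasso fitting.

    lambda_grid:
        Optional decreasing sequence of penalty values. When omitted, a
        30-point log-spaced grid from the node's lambda_max (smallest penalty
        that zeroes every penalized coefficient) down to lambda_max/1000 is
        built per outcome node.
    n_folds:
        Folds for cross-validated penalty selection (ignored when the grid
        has a single value).
    lambda_rule:
        "min" picks the CV-MSE minimizer; "1se" the largest penalty within
        one standard error of it.
    penalize_covariates:
        Apply the L1 penalty to covariate coefficients too (off by default).
    seed:
        Fold-assignment seed.
    """

    lambda_grid: Optional[Sequence[float]] = None
    n_folds: int = 10
    lambda_rule: str = "min"
    penalize_covariates: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_grid is not None:
            grid = np.asarray(self.lambda_grid, dtype=float)
            if grid.ndim != 1 or grid.size == 0:
                raise InputError("lambda_grid must be a non-empty 1-D sequence")
            if (grid < 0).any():
                raise InputError("lambda values must be >= 0")
            if grid.size > 1 and not (np.diff(grid) < 0).all():
                raise InputError("lambda_grid must be strictly decreasing")
            self.lambda_grid = grid
        if self.n_folds < 2:
            raise InputError("n_folds must be >= 2")
        if self.lambda_rule not in ("min", "1se"):
            raise InputError("lambda_rule must be 'min' or '1se'")


@dataclass
class CLPNetwork:
    """Directed weighted cross-lagged network.

    ``B[i, j]`` is the standardized coefficient of ``node_names[i]`` at T1
    predicting ``node_names[j]`` at T2. Covariate coefficients (one column
    per outcome node) and the selected penalty per node are retained as
    estimation metadata.
    """

    node_names: list[str]
    B: np.ndarray
    n: int
    covariate_names: list[str] = field(default_factory=list)
    covariate_coefs: Optional[np.ndarray] = None  # shape (n_cov, p)
    lambdas: Optional[np.ndarray] = None  # selected lambda per outcome node
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=float)
        p = len(self.node_names)
        if self.B.shape != (p, p):
            raise InputError(f"edge matrix must be {p}x{p}, got {self.B.shape}")
        if not np.isfinite(self.B).all():
            raise InputError("edge matrix contains non-finite entries")

    @property
    def p(self) -> int:
        return len(self.node_names)

    def autoregressive(self) -> np.ndarray:
        return np.diag(self.B).copy()

    def edge_frame(self) -> pd.DataFrame:
        """Long-format edge list: from, to, weight, type."""
        rows = []
        for i, src in enumerate(self.node_names):
            for j, dst in enumerate(self.node_names):
                rows.append(
                    {
                        "from": src,
                        "to": dst,
                        "weight": self.B[i, j],
                        "type": "autoregressive" if i == j else "cross-lagged",
                    }
                )
        return pd.DataFrame(rows, columns=["from", "to", "weight", "type"])


# ---------------------------------------------------------------------------
# Objective and solver
# ---------------------------------------------------------------------------


def lasso_objective(
    beta: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    lam: float,
    penalty_mask: Optional[np.ndarray] = None,
) -> float:
    """Penalized least-squares objective the solver minimizes.

    (1 / 2n) * sum((y - X beta)^2) + lambda * sum(penalty_mask * |beta|)
    """
    if lam < 0:
        raise InputError(f"lambda must be >= 0, got {lam}")
    beta = np.asarray(beta, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if penalty_mask is None:
        penalty_mask = np.ones(X.shape[1])
    penalty_mask = np.asarray(penalty_mask, dtype=float)
    resid = y - X @ beta
    n = y.shape[0]
    return float(resid @ resid / (2.0 * n) + lam * np.sum(penalty_mask * np.abs(beta)))


@njit(cache=True)
def _cd_path(G, c, penalty_mask, lambdas, tol, max_iter):  # pragma: no cover
    """Coordinate-descent lasso path on the Gram form (warm-started)."""
    p = G.shape[0]
    n_lam = lambdas.shape[0]
    betas = np.zeros((n_lam, p))
    beta = np.zeros(p)
    for li in range(n_lam):
        lam = lambdas[li]
        for _ in range(max_iter):
            max_change = 0.0
            for j in range(p):
                gjj = G[j, j]
                if gjj <= 0.0:
                    beta[j] = 0.0
                    continue
                rho = c[j] - np.dot(G[j], beta) + gjj * beta[j]
                thr = lam * penalty_mask[j]
                if rho > thr:
                    new = (rho - thr) / gjj
                elif rho < -thr:
                    new = (rho + thr) / gjj
                else:
                    new = 0.0
                change = abs(new - beta[j])
                if change > max_change:
                    max_change = change
                beta[j] = new
            if max_change < tol:
                break
        betas[li] = beta
    return betas


def _solve_path(X: np.ndarray, y: np.ndarray, penalty_mask: np.ndarray, lambdas: np.ndarray):
    n = X.shape[0]
    G = (X.T @ X) / n
    c = (X.T @ y) / n
    return _cd_path(
        np.ascontiguousarray(G),
        np.ascontiguousarray(c),
        np.ascontiguousarray(penalty_mask, dtype=np.float64),
        np.ascontiguousarray(lambdas, dtype=np.float64),
        CD_TOL,
        CD_MAX_ITER,
    )


def lambda_max(X: np.ndarray, y: np.ndarray, penalty_mask: np.ndarray) -> float:
    """Smallest penalty that shrinks every penalized coefficient to zero
    (ignoring the effect of unpenalized covariates on the active threshold)."""
    c = np.abs(X.T @ y) / X.shape[0]
    pen = penalty_mask.astype(bool)
    if not pen.any():
        return 0.0
    return float(c[pen].max())


def _default_grid(X, y, penalty_mask) -> np.ndarray:
    lmax = lambda_max(X, y, penalty_mask)
    if lmax <= 0:
        lmax = 1e-3
    return np.geomspace(lmax, lmax * DEFAULT_LAMBDA_MIN_RATIO, DEFAULT_N_LAMBDA)


def fit_node(
    y_t2: np.ndarray,
    X_t1: np.ndarray,
    covariates: Optional[np.ndarray],
    options: EstimationOptions,
) -> tuple[np.ndarray, float]:
    """Lasso fit of one T2 outcome on all T1 nodes plus covariates.

    Returns the coefficient vector ordered [T1 nodes..., covariates...] and
    the selected penalty. Inputs are assumed centered/standardized; no
    intercept is fitted.
    """
    y = np.asarray(y_t2, dtype=float)
    X_nodes = np.asarray(X_t1, dtype=float)
    if X_nodes.ndim != 2 or y.shape[0] != X_nodes.shape[0]:
        raise InputError("y and X_t1 are not conformable")
    if covariates is not None and np.size(covariates):
        C = np.asarray(covariates, dtype=float).reshape(X_nodes.shape[0], -1)
        X = np.hstack([X_nodes, C])
        n_cov = C.shape[1]
    else:
        X = X_nodes
        n_cov = 0
    if np.isnan(X).any() or np.isnan(y).any():
        raise InputError("missing values in regression inputs; impute first")
    # canonical row order: makes fold assignment (hence the whole fit) exactly
    # invariant to how participants happen to be ordered in the input
    order = np.lexsort(tuple(X[:, k] for k in range(X.shape[1] - 1, -1, -1)) + (y,))
    X, y = X[order], y[order]
    n, P = X.shape
    penalty_mask = np.ones(P)
    if not options.penalize_covariates and n_cov:
        penalty_mask[P - n_cov :] = 0.0

    grid = options.lambda_grid
    if grid is None:
        grid = _default_grid(X, y, penalty_mask)
    grid = np.asarray(grid, dtype=float)
    if grid.min() == 0.0 and n <= P:
        raise InputError(f"unpenalized fit requested with n={n} <= {P} predictors")
    if options.n_folds > n:
        raise InputError(f"n_folds={options.n_folds} exceeds n={n}")

    if grid.size == 1:
        sel = 0
    else:
        sel = _cv_select(X, y, penalty_mask, grid, options)
    betas = _solve_path(X, y, penalty_mask, grid[: sel + 1])
    return betas[-1], float(grid[sel])


def _cv_select(X, y, penalty_mask, grid, options: EstimationOptions) -> int:
    n = X.shape[0]
    rng = np.random.default_rng(options.seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, options.n_folds)
    fold_mse = np.empty((options.n_folds, grid.size))
    for k, val_idx in enumerate(folds):
        train = np.setdiff1d(perm, val_idx, assume_unique=True)
        betas = _solve_path(X[train], y[train], penalty_mask, grid)
        preds = X[val_idx] @ betas.T
        fold_mse[k] = np.mean((y[val_idx, None] - preds) ** 2, axis=0)
    mean_mse = fold_mse.mean(axis=0)
    best = int(np.argmin(mean_mse))  # ties -> first index = largest lambda
    if options.lambda_rule == "1se":
        se = fold_mse[:, best].std(ddof=1) / np.sqrt(options.n_folds)
        within = np.nonzero(mean_mse <= mean_mse[best] + se)[0]
        best = int(within.min())  # grid decreasing: smallest index = largest lambda
    return best


# ---------------------------------------------------------------------------
# Network assembly
# ---------------------------------------------------------------------------


def estimate_network(
    data: PanelDataset,
    covariate_names: Sequence[str],
    options: Optional[EstimationOptions] = None,
) -> CLPNetwork:
    """Node-wise lasso CLPN over a standardized, complete panel.

    For each node j, regresses its T2 score on all p T1 scores plus the named
    covariates; row i of the edge matrix collects the coefficient of node i.
    """
    if options is None:
        options = EstimationOptions()
    covariate_names = list(covariate_names)
    for c in covariate_names:
        if c not in data.frame.columns:
            raise InputError(f"covariate {c!r} not in panel")
    t1_cols = data.node_columns("t1")
    X_t1 = data.frame[t1_cols].to_numpy(dtype=float)
    C = (
        data.frame[covariate_names].to_numpy(dtype=float)
        if covariate_names
        else None
    )
    if np.isnan(X_t1).any() or (C is not None and np.isnan(C).any()):
        raise InputError("panel contains missing values; impute before estimation")
    p = data.p
    B = np.zeros((p, p))
    cov_coefs = np.zeros((len(covariate_names), p))
    lambdas = np.zeros(p)
    for j, node in enumerate(data.node_names):
        y = data.frame[node_column(node, "t2")].to_numpy(dtype=float)
        if np.isnan(y).any():
            raise InputError(f"missing values in outcome column for node {node!r}")
        try:
            coef, lam = fit_node(y, X_t1, C, options)
        except InputError as exc:
            raise InputError(f"node {node!r}: {exc}") from exc
        B[:, j] = coef[:p]
        if covariate_names:
            cov_coefs[:, j] = coef[p:]
        lambdas[j] = lam
    return CLPNetwork(
        node_names=list(data.node_names),
        B=B,
        n=data.n,
        covariate_names=covariate_names,
        covariate_coefs=cov_coefs if covariate_names else None,
        lambdas=lambdas,
        seed=options.seed,
    )
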