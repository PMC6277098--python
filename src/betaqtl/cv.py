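"""K-fold cross-validated selection of the robustness tuning parameter beta.

Beta trades efficiency (small beta) against robustness to outliers (large
beta).  Following the held-out beta0-divergence criterion, each candidate
beta is scored by fitting the no-QTL (single Gaussian) model on K-1 folds by
maximum beta-likelihood and evaluating, on the held-out fold, the negative
beta0-likelihood

    L'_{beta0}(theta_hat | D_k) =
        (1/beta0) [ 1 - (1/n_k) sum_{y in D_k} f(y|theta_hat)^beta0 / l_beta0 ],

aggregated over folds; the selected beta minimizes the aggregate.  Clean
Gaussian data drives the selection to the smallest grid value, while
contamination pushes it upward — the criterion itself diagnoses outliers.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .em import Theta, fit_null, log_l_beta, log_mixture_density

#: default candidate grid; spans the near-zero to strongly robust regimes
DEFAULT_BETA_GRID = (
    0.001, 0.005, 0.01, 0.02, 0.041, 0.06, 0.1, 0.15, 0.2, 0.3, 0.4, 0.5,
)


@dataclass(frozen=True)
class CVResult:
    beta_grid: np.ndarray
    scores: np.ndarray  # held-out beta0-divergence per grid point
    beta_opt: float
    K: int
    beta0: float
    seed: int | None


def _holdout_score(
    theta: Theta, Y: np.ndarray, X: np.ndarray, beta0: float
) -> float:
    """Held-out negative beta0-likelihood of the single-Gaussian null model."""
    n_k = Y.shape[0]
    means = (X @ theta.gamma)[:, None]
    probs = np.ones((n_k, 1))
    logf = log_mixture_density(Y, means, theta.sigma2, probs)
    logl = log_l_beta(means, theta.sigma2, probs, beta0)
    # (1 - f^beta0/l)/beta0, averaged; -expm1 keeps precision for small beta0
    return float(np.mean(-np.expm1(beta0 * logf - logl)) / beta0)


def kfold_indices(n: int, K: int, seed: int | None) -> list[np.ndarray]:
    """Seeded partition of range(n) into K folds of near-equal size."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, K)]


def cv_select_beta(
    Y: np.ndarray,
    X: np.ndarray,
    beta_grid=DEFAULT_BETA_GRID,
    K: int = 10,
    beta0: float = 0.1,
    seed: int | None = None,
) -> CVResult:
    """Select beta by K-fold cross-validation under the no-QTL model.

    ``X`` should match the scan's null model (intercept plus any selected
    cofactors).  Ties in the criterion resolve to the smallest beta.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = Y.shape[0]
    if K < 2:
        raise ValueError(f"need K >= 2 folds, got {K}")
    grid = np.sort(np.asarray(beta_grid, dtype=float))
    if grid.size == 0:
        raise ValueError("empty beta grid")
    folds = kfold_indices(n, K, seed)
    min_fold = min(len(f) for f in folds)
    if min_fold <= X.shape[1] + 1:
        raise ValueError(
            f"fold of size {min_fold} too small for a stable fit with "
            f"{X.shape[1]} covariates; reduce K={K}"
        )
    scores = np.empty(grid.size)
    for g, beta in enumerate(grid):
        total = 0.0
        for test_idx in folds:
            train = np.setdiff1d(np.arange(n), test_idx, assume_unique=False)
            res = fit_null(Y[train], X[train], beta=beta)
            total += len(test_idx) * _holdout_score(
                res.theta_hat, Y[test_idx], X[test_idx], beta0
            )
        scores[g] = total / n
    best = int(np.argmin(scores))  # first minimum = smallest beta on ties
    return CVResult(
        beta_grid=grid,
        scores=scores,
        beta_opt=float(grid[best]),
        K=K,
        beta0=beta0,
        seed=seed,
    )
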