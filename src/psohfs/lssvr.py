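"""Least-squares support vector regression (LS-SVR) with an RBF kernel.

LS-SVR replaces the standard SVR quadratic program with a squared loss and
equality constraints, so the dual solution comes from a single linear system

    [[0, 1^T], [1, K + I/gamma]] . [b; alpha] = [0; y]

where ``K`` is the Gram matrix, ``gamma`` the regularization weight and
``b`` the bias.  The kernel used throughout is the Gaussian RBF
``k(x, z) = exp(-||x - z||^2 / sigma2)``, with the squared width ``sigma2``
as the direct divisor.  Hyperparameters are chosen by grid search over
seeded, shuffled k-fold cross-validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg
from scipy.spatial.distance import cdist
from sklearn.model_selection import KFold

__all__ = [
    "LSSVRConfig",
    "LSSVRModel",
    "Metrics",
    "rbf_kernel",
    "kernel_matrix",
    "fit_lssvr",
    "predict",
    "cv_mse",
    "cv_mse_gram",
    "grid_search",
    "metrics",
]

#: default logarithmic grids spanning the search ranges [0.1, 1e5] (sigma2)
#: and [0.1, 1e4] (gamma), seven points per axis
DEFAULT_SIGMA2_GRID = tuple(np.logspace(-1.0, 5.0, 7))
DEFAULT_GAMMA_GRID = tuple(np.logspace(-1.0, 4.0, 7))


@dataclass(frozen=True)
class LSSVRConfig:
    """Kernel width sigma2, regularization gamma, and CV/grid settings."""

    sigma2: float = 10.0
    gamma: float = 100.0
    sigma2_grid: tuple[float, ...] = DEFAULT_SIGMA2_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma2 <= 0 or self.gamma <= 0:
            raise ValueError("sigma2 and gamma must be positive")
        if not self.sigma2_grid or not self.gamma_grid:
            raise ValueError("hyperparameter grids must be non-empty")
        if self.folds < 2:
            raise ValueError("folds must be at least 2")


@dataclass
class LSSVRModel:
    training_inputs: np.ndarray = field(repr=False)
    dual_coefficients: np.ndarray = field(repr=False)
    bias: float
    config: LSSVRConfig


def rbf_kernel(x: np.ndarray, z: np.ndarray, sigma2: float) -> float:
    """Gaussian RBF kernel exp(-||x - z||^2 / sigma2); in (0, 1]."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if x.shape != z.shape:
        raise ValueError("kernel arguments must have equal dimension")
    return float(np.exp(-np.sum((x - z) ** 2) / sigma2))


def kernel_matrix(X: np.ndarray, Z: np.ndarray, sigma2: float) -> np.ndarray:
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    return np.exp(-cdist(np.atleast_2d(X), np.atleast_2d(Z), "sqeuclidean") / sigma2)


def _solve_dual(K: np.ndarray, y: np.ndarray, gamma: float) -> tuple[float, np.ndarray]:
    """Solve [[0, 1^T], [1, K + I/gamma]] [b; alpha] = [0; y].

    Eliminates the bias against the SPD block H = K + I/gamma via a
    Cholesky factorization with two right-hand sides (y and 1):
    b = 1^T H^-1 y / 1^T H^-1 1, alpha = H^-1 (y - b 1).  Falls back to a
    dense solve of the full bordered system if H is numerically indefinite.
    """
    n = len(y)
    H = K.astype(float, copy=True)
    H.flat[:: n + 1] += 1.0 / gamma
    chol, info = scipy.linalg.lapack.dpotrf(H, lower=1, overwrite_a=1)
    if info == 0:
        rhs = np.column_stack((y, np.ones(n)))
        sol, info = scipy.linalg.lapack.dpotrs(chol, rhs, lower=1)
    if info != 0:  # numerically indefinite H: bordered dense solve
        A = np.zeros((n + 1, n + 1))
        A[0, 1:] = 1.0
        A[1:, 0] = 1.0
        A[1:, 1:] = K + np.eye(n) / gamma
        full_rhs = np.concatenate(([0.0], y))
        try:
            full_sol = scipy.linalg.solve(A, full_rhs)
        except scipy.linalg.LinAlgError as exc:  # pragma: no cover
            raise np.linalg.LinAlgError(
                f"singular LS-SVR system (cond={np.linalg.cond(A):.3e})"
            ) from exc
        return float(full_sol[0]), full_sol[1:]
    a_y, a_1 = sol[:, 0], sol[:, 1]
    b = a_y.sum() / a_1.sum()
    return float(b), a_y - b * a_1


def fit_lssvr(X: np.ndarray, y: np.ndarray, config: LSSVRConfig) -> LSSVRModel:
    """Solve the LS-SVR dual linear system for (bias, dual coefficients).

    As gamma grows the fit approaches exact interpolation of the training
    targets; the equality constraint forces the dual coefficients to sum
    to zero.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n != len(y):
        raise ValueError("X rows must match y length")
    if n < 2:
        raise ValueError("at least two training samples are required")
    K = kernel_matrix(X, X, config.sigma2)
    b, alpha = _solve_dual(K, y, config.gamma)
    return LSSVRModel(X, alpha, b, config)


def predict(model: LSSVRModel, X: np.ndarray) -> np.ndarray:
    """Evaluate sum_i alpha_i k(x_i, x) + b at the query points."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        return np.zeros(0)
    X = np.atleast_2d(X)
    if X.shape[1] != model.training_inputs.shape[1]:
        raise ValueError("query dimension does not match training dimension")
    K = kernel_matrix(X, model.training_inputs, model.config.sigma2)
    return K @ model.dual_coefficients + model.bias


def cv_mse_gram(K: np.ndarray, y: np.ndarray, config: LSSVRConfig) -> float:
    """Mean held-out MSE over seeded, shuffled k-fold CV on a precomputed
    Gram matrix (fold kernels are submatrices of the full Gram matrix)."""
    y = np.asarray(y, dtype=float).ravel()
    if config.folds > len(y):
        raise ValueError("more folds than samples")
    kf = KFold(n_splits=config.folds, shuffle=True, random_state=config.seed)
    errors = []
    for train_idx, test_idx in kf.split(y):
        b, alpha = _solve_dual(
            K[np.ix_(train_idx, train_idx)], y[train_idx], config.gamma
        )
        pred = K[np.ix_(test_idx, train_idx)] @ alpha + b
        errors.append(float(np.mean((pred - y[test_idx]) ** 2)))
    return float(np.mean(errors))


def cv_mse(X: np.ndarray, y: np.ndarray, config: LSSVRConfig) -> float:
    """Mean held-out MSE over seeded, shuffled k-fold cross-validation."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return cv_mse_gram(kernel_matrix(X, X, config.sigma2), y, config)


def grid_search(X: np.ndarray, y: np.ndarray, config: LSSVRConfig) -> LSSVRConfig:
    """Return the config minimizing cv_mse over the (sigma2, gamma) grid.

    Ties go to the smallest sigma2, then the smallest gamma.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    sqd = cdist(X, X, "sqeuclidean")
    best: tuple[float, float, float] | None = None
    for sigma2 in config.sigma2_grid:
        K = np.exp(-sqd / sigma2)
        for gamma in config.gamma_grid:
            err = cv_mse_gram(K, y, replace(config, sigma2=sigma2, gamma=gamma))
            key = (err, sigma2, gamma)
            if best is None or key < best:
                best = key
    assert best is not None
    return replace(config, sigma2=best[1], gamma=best[2])


@dataclass(frozen=True)
class Metrics:
    """Prediction accuracy summary: MSE, RMSE and MRPE (percent).

    ``mrpe`` is NaN with ``mrpe_defined=False`` whenever an observed value
    is zero (the relative error is then undefined).
    """

    mse: float
    rmse: float
    mrpe: float
    mrpe_defined: bool = True


def metrics(y: np.ndarray, y_pred: np.ndarray) -> Metrics:
    """MSE, RMSE = sqrt(MSE), and MRPE = mean |y' - y| / |y| x 100%."""
    y = np.asarray(y, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y.shape != y_pred.shape:
        raise ValueError("observed and predicted vectors must match in length")
    mse = float(np.mean((y - y_pred) ** 2))
    rmse = math.sqrt(mse)
    if np.any(y == 0):
        return Metrics(mse, rmse, float("nan"), mrpe_defined=False)
    mrpe = float(np.mean(np.abs((y_pred - y) / y)) * 100.0)
    return Metrics(mse, rmse, mrpe)
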