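"""Classical lasso baseline and its cross-validation-free tuner.

``solve_lasso`` minimizes the sum-form objective

    ||y - X beta||^2 + lam ||beta||_1

(no intercept — center/standardize beforehand if needed) via
coordinate descent.  ``tune_lasso`` replicates the benchmark protocol:
the penalty is chosen by random search over a log-uniform grid, each
candidate scored by out-of-bag RMSE across bootstrap resamples of the
training data, and the winner refit on the full data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso

logger = logging.getLogger(__name__)

__all__ = ["LassoFit", "solve_lasso", "lambda_max", "tune_lasso"]


@dataclass
class LassoFit:
    beta_hat: np.ndarray
    lam: float
    objective: float


def _objective(X, y, beta, lam) -> float:
    r = y - X @ beta
    return float(r @ r + lam * np.abs(beta).sum())


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest sum-form penalty at which the solution is identically zero,
    max_j |2 X_j^T y| (subgradient condition at the origin)."""
    return float(np.max(np.abs(2.0 * (X.T @ y))))


def solve_lasso(X: np.ndarray, y: np.ndarray, lam: float, tol: float = 1e-10) -> LassoFit:
    """Minimize ||y - X beta||^2 + lam ||beta||_1 (coordinate descent).

    scikit-learn's ``Lasso`` solves (1/2N)||y - X beta||^2 + alpha||beta||_1,
    so ``alpha = lam / (2N)``.  Exact zeros are reported as zeros.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"X has {X.shape[0]} rows but y has {y.shape[0]} entries")
    if lam < 0:
        raise ValueError(f"lam must be >= 0, got {lam}")
    N = X.shape[0]
    if lam == 0:
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
    else:
        est = Lasso(alpha=lam / (2.0 * N), fit_intercept=False,
                    tol=tol, max_iter=100_000)
        est.fit(X, y)
        beta = est.coef_.copy()
    return LassoFit(beta_hat=beta, lam=float(lam), objective=_objective(X, y, beta, lam))


def _draw_bootstrap(n: int, rng: np.random.Generator, y: np.ndarray):
    """Bootstrap index sets with a usable out-of-bag remainder; resamples
    with a constant in-bag y (or empty OOB) are redrawn."""
    for _ in range(100):
        idx = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), idx)
        if oob.size == 0 or np.ptp(y[idx]) == 0:
            logger.info("degenerate bootstrap resample redrawn")
            continue
        return idx, oob
    raise RuntimeError("could not draw a non-degenerate bootstrap resample")


def tune_lasso(
    X: np.ndarray,
    y: np.ndarray,
    grid_size: int = 1000,
    n_boot: int = 5,
    seed: int | None = None,
) -> LassoFit:
    """Random-search penalty selection scored on bootstrap out-of-bag error.

    Draws ``grid_size`` candidates log-uniformly on
    ``[1e-4 * lambda_max, lambda_max]``; for each bootstrap resample the
    candidates are fit pathwise (descending, warm-started) and scored by
    RMSE on the out-of-bag rows; the candidate with the lowest mean
    out-of-bag RMSE is refit on the full data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if grid_size < 1 or n_boot < 1:
        raise ValueError("grid_size and n_boot must be >= 1")
    n = X.shape[0]
    rng = np.random.default_rng(seed)

    lam_hi = lambda_max(X, y)
    if lam_hi == 0:  # y orthogonal to every column: the null model is exact
        return solve_lasso(X, y, 0.0)
    lams = np.exp(rng.uniform(np.log(1e-4 * lam_hi), np.log(lam_hi), size=grid_size))
    order = np.argsort(lams)[::-1]  # descending for warm starts
    lams_sorted = lams[order]

    scores = np.zeros(grid_size)
    for _ in range(n_boot):
        idx, oob = _draw_bootstrap(n, rng, y)
        Xb, yb = X[idx], y[idx]
        Xo, yo = X[oob], y[oob]
        est = Lasso(alpha=1.0, fit_intercept=False, tol=1e-6,
                    max_iter=10_000, warm_start=True)
        with warnings.catch_warnings():
            # scoring along the warm-started path tolerates loose solves
            warnings.simplefilter("ignore", ConvergenceWarning)
            for k, lam in enumerate(lams_sorted):
                est.alpha = lam / (2.0 * Xb.shape[0])
                est.fit(Xb, yb)
                r = yo - Xo @ est.coef_
                scores[k] += np.sqrt(np.mean(r**2))
    scores /= n_boot

    best_lam = float(lams_sorted[int(np.argmin(scores))])
    return solve_lasso(X, y, best_lam)
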