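"""Synthetic data generators for the benchmark experiments.

Three designs:

* :func:`gen_experiment1` — the classic sparse-regression setup:
  Gaussian features with AR(1) correlation ``0.5^|i-j|``, fixed
  coefficients ``(3, 1.5, 0, 0, 2, 0, ..., 0)`` and noise variance 5.
* :func:`gen_experiment2` — block-correlated design: two 20x20
  compound-symmetry blocks (features 1-20 and 21-40, off-diagonal rho),
  independent features beyond 40, random coefficients
  ``U[0.9, 1.1]`` on 1-10 and ``U[-1.1, -0.9]`` on 21-30 (redrawn each
  call), noise variance 10.
* :func:`gen_questionnaire_standin` — a SYNTHETIC stand-in emulating the
  shape of a small questionnaire study (n=73 respondents, p=44
  Likert-type items, a sparse 7-item signal).  It mimics shape and
  sparsity only, not any real instrument's item distributions.

All generators are fully deterministic given a seed.  Multivariate
normals are sampled via Cholesky factorization of the covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SimulatedDataset",
    "ar1_covariance",
    "block_covariance",
    "gen_experiment1",
    "gen_experiment2",
    "gen_questionnaire_standin",
]


@dataclass
class SimulatedDataset:
    """A train/test pair with its generating truth."""

    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    beta_true: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def X_full(self) -> np.ndarray:
        return np.vstack([self.X_train, self.X_test])

    @property
    def y_full(self) -> np.ndarray:
        return np.concatenate([self.y_train, self.y_test])


def ar1_covariance(p: int, rho: float = 0.5) -> np.ndarray:
    """Sigma[i, j] = rho^|i-j| (unit variances)."""
    idx = np.arange(p)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def block_covariance(p: int, rho: float, block: int = 20, n_blocks: int = 2) -> np.ndarray:
    """Block-diagonal covariance: ``n_blocks`` compound-symmetry blocks
    (diagonal 1, off-diagonal rho) followed by identity."""
    if not 0 <= rho < 1:
        raise ValueError(f"rho must lie in [0, 1), got {rho}")
    sigma = np.eye(p)
    for b in range(n_blocks):
        lo, hi = b * block, (b + 1) * block
        sigma[lo:hi, lo:hi] = rho
        np.fill_diagonal(sigma[lo:hi, lo:hi], 1.0)
    return sigma


def _sample_mvn(n: int, sigma: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    # covariance must be symmetric PSD before factorization
    if not np.allclose(sigma, sigma.T):
        raise ValueError("covariance is not symmetric")
    chol = np.linalg.cholesky(sigma)
    return rng.standard_normal((n, sigma.shape[0])) @ chol.T


def _assemble(X, beta, noise_sd, n_train, rng, meta) -> SimulatedDataset:
    y = X @ beta + rng.normal(0.0, noise_sd, size=X.shape[0])
    return SimulatedDataset(
        X_train=X[:n_train], y_train=y[:n_train],
        X_test=X[n_train:], y_test=y[n_train:],
        beta_true=beta, meta=meta,
    )


def gen_experiment1(
    p: int = 20,
    n_train: int = 50,
    n_test: int = 950,
    seed: int | None = None,
    rho: float = 0.5,
    noise_var: float = 5.0,
) -> SimulatedDataset:
    """AR(1)-correlated Gaussian design with fixed sparse coefficients."""
    if p < 5:
        raise ValueError(f"p must be >= 5, got {p}")
    rng = np.random.default_rng(seed)
    beta = np.zeros(p)
    beta[:5] = [3.0, 1.5, 0.0, 0.0, 2.0]
    X = _sample_mvn(n_train + n_test, ar1_covariance(p, rho), rng)
    meta = {"generator": "experiment1", "p": p, "rho": rho,
            "noise_var": noise_var, "seed": seed}
    return _assemble(X, beta, np.sqrt(noise_var), n_train, rng, meta)


def gen_experiment2(
    p: int = 40,
    rho: float = 0.5,
    n_train: int = 50,
    n_test: int = 950,
    seed: int | None = None,
    noise_var: float = 10.0,
) -> SimulatedDataset:
    """Block-correlated design with random sparse coefficients.

    ``beta_true`` is redrawn on every call: U[0.9, 1.1] on features 1-10,
    U[-1.1, -0.9] on 21-30, zero elsewhere.
    """
    if p < 40:
        raise ValueError(f"p must be >= 40, got {p}")
    if not 0 <= rho < 1:
        raise ValueError(f"rho must lie in [0, 1), got {rho}")
    rng = np.random.default_rng(seed)
    beta = np.zeros(p)
    beta[0:10] = rng.uniform(0.9, 1.1, size=10)
    beta[20:30] = rng.uniform(-1.1, -0.9, size=10)
    X = _sample_mvn(n_train + n_test, block_covariance(p, rho), rng)
    meta = {"generator": "experiment2", "p": p, "rho": rho,
            "noise_var": noise_var, "seed": seed}
    return _assemble(X, beta, np.sqrt(noise_var), n_train, rng, meta)


def gen_questionnaire_standin(
    n: int = 73,
    p: int = 44,
    seed: int | None = None,
    n_signal: int = 7,
    r2: float = 0.4,
) -> SimulatedDataset:
    """SYNTHETIC questionnaire-shaped data (n respondents, p Likert items).

    Items arise from a correlated latent Gaussian (AR(1), rho 0.3)
    discretized to small integer scales (mostly 5-point, every sixth
    item an 11-point 0-10 scale).  The response is a linear signal in
    ``n_signal`` items (alternating signs, magnitudes U[0.6, 1.0] on the
    standardized items) plus Gaussian noise sized for population R^2 of
    ``r2``.  The default split mirrors a 50-train / (n-50)-test design,
    so n must exceed 50.
    """
    if p < n_signal:
        raise ValueError(f"p must be >= {n_signal}, got {p}")
    if n <= 50:
        raise ValueError(f"n must be > 50 to allow a 50/{n}-50 split, got {n}")
    rng = np.random.default_rng(seed)

    latent = _sample_mvn(n, ar1_covariance(p, 0.3), rng)
    X = np.empty((n, p))
    for j in range(p):
        n_levels = 11 if j % 6 == 5 else 5
        # equal-probability bins of the standard normal
        cuts = np.quantile(latent[:, j], np.linspace(0, 1, n_levels + 1)[1:-1])
        X[:, j] = np.digitize(latent[:, j], cuts)

    signal_items = rng.choice(p, size=n_signal, replace=False)
    signs = np.where(np.arange(n_signal) % 2 == 0, 1.0, -1.0)
    mags = rng.uniform(0.6, 1.0, size=n_signal)

    x_sd = X.std(axis=0, ddof=0)
    x_sd = np.where(x_sd > 0, x_sd, 1.0)
    beta = np.zeros(p)
    beta[signal_items] = signs * mags / x_sd[signal_items]  # raw-item scale

    signal = X @ beta
    sig_var = signal.var()
    noise_sd = np.sqrt(sig_var * (1 - r2) / r2) if sig_var > 0 else 1.0
    y = signal + rng.normal(0.0, noise_sd, size=n)

    meta = {"generator": "questionnaire_standin", "p": p, "n": n,
            "noise_var": float(noise_sd**2), "seed": seed,
            "signal_items": np.sort(signal_items).tolist(), "target_r2": r2}
    return SimulatedDataset(
        X_train=X[:50], y_train=y[:50],
        X_test=X[50:], y_test=y[50:],
        beta_true=beta, meta=meta,
    )
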