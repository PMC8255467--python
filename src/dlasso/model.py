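"""Neural lasso ("dlasso") core model.

The classical lasso

    L(beta, lambda) = ||y - X beta||^2 + lambda ||beta||_1

is reparameterized as a two-node linear network: a weight layer ``w``
followed by a single trainable scalar ``gamma``, predicting ``gamma * X w``
with a *fixed* penalty constant ``lambda0`` on ``w``.  Writing
``gamma = lambda0 / lambda`` the two problems are equivalent
(``beta = gamma * w``), but in the network form the effective
regularization ``lambda = lambda0 / gamma`` is learned by gradient
descent jointly with the coefficients instead of being cross-validated.

Gradient optimizers never produce exact zeros under an L1 penalty, so
feature selection is enforced by a subgradient optimality test: weight
``j`` can be zero at a stationary point iff

    | 2 X_j^T (y - gamma * sum_{i != j} X_i w_i) |  <=  | lambda0 / gamma |

(the coordinate-wise KKT condition of the penalized problem).  During
training this test is evaluated periodically for all coordinates at once
and the satisfying weights are clamped to exactly zero until the next
check (where they may revive).

This module trains the *mean* form of the objective,

    (1/N) ||y - gamma X w||^2 + lambda0 ||w||_1,

which equals the sum form above with penalty constant ``N * lambda0``;
the trainer performs that conversion when calling the (sum-form) zeroing
test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DlassoConfig",
    "NetworkState",
    "FittedModel",
    "dlasso_objective",
    "zeroing_condition",
    "zeroing_mask",
    "train_dlasso",
    "extract_beta",
]

#: |gamma| outside this range means the effective regularization
#: lambda0/gamma has collapsed or exploded; a warning is logged.
GAMMA_WARN_HIGH = 1e6
GAMMA_WARN_LOW = 1e-6


@dataclass
class DlassoConfig:
    """Hyperparameters of the dlasso training loop.

    Parameters
    ----------
    lambda0 : float
        Fixed penalty constant of the reparameterized objective
        (mean form, per-observation scale).  It only sets the origin of
        the regularization search: the effective penalty is
        ``lambda0 / gamma`` and ``gamma`` is trained.
    epochs : int
        Full-batch gradient steps per restart.
    restarts : int
        Independent random re-initializations; the restart with the
        lowest unpenalized training MSE wins.
    learning_rate : float
        Adam step size.
    optimizer : str
        Name of the first-order method; only ``"adam"`` is implemented.
    zero_check_start, zero_check_every : int
        Epoch of the first subgradient zeroing check and the interval
        between checks.  A final check always runs after the last epoch.
        ``zero_check_start=None`` resolves to ``min(500, epochs)``.
    standardize : bool
        Column-standardize X and center y before training (coefficients
        are reported on the standardized scale; predictions are mapped
        back).
    seed : int or None
        Master seed; per-restart sub-seeds are derived deterministically.
    freeze_gamma : bool
        Diagnostic mode: keep ``gamma`` fixed at ``gamma_init`` so the
        network solves the classical lasso at ``lambda = lambda0``
        (useful for oracle comparisons).
    init_scale : float
        Half-width of the uniform weight initialization.
    gamma_init : float
        Initial value of ``gamma``.
    """

    lambda0: float = 1.0
    epochs: int = 1000
    restarts: int = 20
    learning_rate: float = 0.01
    optimizer: str = "adam"
    zero_check_start: int | None = None
    zero_check_every: int = 100
    standardize: bool = True
    seed: int | None = None
    freeze_gamma: bool = False
    init_scale: float = 0.05
    gamma_init: float = 1.0

    def __post_init__(self) -> None:
        if self.lambda0 <= 0:
            raise ValueError(f"lambda0 must be > 0, got {self.lambda0}")
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if self.restarts < 1:
            raise ValueError(f"restarts must be >= 1, got {self.restarts}")
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be > 0, got {self.learning_rate}")
        if self.zero_check_start is None:
            self.zero_check_start = min(500, self.epochs)
        if not 0 <= self.zero_check_start <= self.epochs:
            raise ValueError(
                f"zero_check_start must lie in [0, epochs], got "
                f"{self.zero_check_start} with epochs={self.epochs}"
            )
        if self.zero_check_every < 1:
            raise ValueError("zero_check_every must be >= 1")
        if self.optimizer.lower() != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")

    def with_(self, **kwargs) -> "DlassoConfig":
        return replace(self, **kwargs)


@dataclass
class NetworkState:
    """Trainable state of the network: weights, scalar gamma and the
    sparsity mask (``mask[j] is False`` means w[j] is clamped to zero)."""

    w: np.ndarray
    gamma: float
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.w.shape != self.mask.shape:
            raise ValueError(
                f"w has shape {self.w.shape} but mask has shape {self.mask.shape}"
            )
        if not np.isfinite(self.gamma) or self.gamma == 0:
            raise ValueError(f"gamma must be finite and nonzero, got {self.gamma}")
        if np.any(self.w[~self.mask] != 0):
            raise ValueError("masked weights must be exactly zero")


@dataclass
class FittedModel:
    """Result of :func:`train_dlasso`.

    ``beta_hat = gamma * w`` lives on the scale of the problem the
    network actually solved (standardized if ``config.standardize``);
    :meth:`coef_original` and :meth:`predict` map back to the raw data
    scale.
    """

    beta_hat: np.ndarray
    gamma: float
    effective_lambda: float
    train_mse: float
    loss_trace: np.ndarray
    restart_losses: np.ndarray
    config: DlassoConfig
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    w: np.ndarray = field(repr=False, default=None)
    mask: np.ndarray = field(repr=False, default=None)

    @property
    def support(self) -> np.ndarray:
        """Indices j with beta_hat[j] != 0 (exact zeros, never epsilon)."""
        return np.flatnonzero(self.beta_hat != 0)

    def coef_original(self) -> tuple[np.ndarray, float]:
        """Coefficients and intercept on the raw (unstandardized) scale."""
        beta = self.beta_hat / self.x_scale
        intercept = self.y_mean - float(beta @ self.x_mean)
        return beta, intercept

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        X_new = np.asarray(X_new, dtype=float)
        if X_new.ndim == 1:
            X_new = X_new[None, :]
        if X_new.shape[1] != self.beta_hat.shape[0]:
            raise ValueError(
                f"X_new has {X_new.shape[1]} columns but the model has "
                f"{self.beta_hat.shape[0]} features"
            )
        beta, intercept = self.coef_original()
        return X_new @ beta + intercept


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError(f"X must be 2-D, got shape {X.shape}")
    if X.shape[0] != y.shape[0]:
        raise ValueError(
            f"X has {X.shape[0]} rows but y has {y.shape[0]} entries"
        )
    return X, y


def dlasso_objective(
    w: np.ndarray, gamma: float, X: np.ndarray, y: np.ndarray, lambda0: float
) -> float:
    """Mean-form network objective (1/N)||y - gamma X w||^2 + lambda0 ||w||_1.

    ``lambda0 >= 0`` is accepted so the unpenalized limit can be
    evaluated; training itself requires ``lambda0 > 0``.
    """
    X, y = _check_xy(X, y)
    w = np.asarray(w, dtype=float).ravel()
    if w.shape[0] != X.shape[1]:
        raise ValueError(f"w has length {w.shape[0]} but X has {X.shape[1]} columns")
    if lambda0 < 0:
        raise ValueError(f"lambda0 must be >= 0, got {lambda0}")
    resid = y - gamma * (X @ w)
    return float(resid @ resid / X.shape[0] + lambda0 * np.abs(w).sum())


def zeroing_condition(
    X: np.ndarray,
    y: np.ndarray,
    state: NetworkState,
    lambda0: float,
    j: int,
) -> bool:
    """Coordinate-wise subgradient test for an exact zero at feature ``j``.

    Returns True iff ``|2 X_j^T (y - gamma * sum_{i != j} X_i w_i)| <=
    |lambda0 / gamma|`` — the KKT condition under which w[j] = 0 is
    optimal for the *sum-form* penalized problem with penalty constant
    ``lambda0``.  The partial residual excludes feature j, so the test
    does not depend on the current w[j].
    """
    X, y = _check_xy(X, y)
    if state.gamma == 0:
        raise ValueError("zeroing condition is undefined for gamma == 0")
    return bool(zeroing_mask(X, y, state, lambda0)[j])


def zeroing_mask(
    X: np.ndarray, y: np.ndarray, state: NetworkState, lambda0: float
) -> np.ndarray:
    """Vectorized :func:`zeroing_condition` over all coordinates.

    ``X_j^T (y - gamma * sum_{i!=j} X_i w_i) = X_j^T r + gamma ||X_j||^2 w_j``
    with the full residual ``r = y - gamma X w``, so one residual pass
    serves every j.
    """
    X, y = _check_xy(X, y)
    if state.gamma == 0:
        raise ValueError("zeroing condition is undefined for gamma == 0")
    gamma = state.gamma
    r = y - gamma * (X @ state.w)
    partial = X.T @ r + gamma * np.einsum("ij,ij->j", X, X) * state.w
    return np.abs(2.0 * partial) <= abs(lambda0 / gamma)


def extract_beta(state: NetworkState) -> np.ndarray:
    """Map network weights back to regression coefficients, beta = gamma * w."""
    return state.gamma * state.w


def _standardize(X: np.ndarray, y: np.ndarray):
    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0, ddof=0)
    x_scale = np.where(x_scale > 0, x_scale, 1.0)  # constant columns stay as-is
    y_mean = float(y.mean())
    return (X - x_mean) / x_scale, y - y_mean, x_mean, x_scale, y_mean


def _run_restart(
    X: np.ndarray,
    y: np.ndarray,
    config: DlassoConfig,
    rng: np.random.Generator,
    epoch_callback: Callable[[int, NetworkState], None] | None = None,
):
    """One full training run from a fresh initialization.

    Returns (state, train_mse, loss_trace) or None if the loss went
    non-finite.  Plain Adam on the mean-form objective; the L1 term
    contributes its subgradient (sign, with sign(0) = 0) so unmasked
    weights sitting at zero can still be pulled away by the smooth part.
    """
    N, p = X.shape
    lam_sum = N * config.lambda0  # sum-form constant for the zeroing test

    w = rng.uniform(-config.init_scale, config.init_scale, size=p)
    gamma = float(config.gamma_init)
    mask = np.ones(p, dtype=bool)

    lr, b1, b2, eps = config.learning_rate, 0.9, 0.999, 1e-8
    m_w = np.zeros(p)
    v_w = np.zeros(p)
    m_g = 0.0
    v_g = 0.0

    col_sq = np.einsum("ij,ij->j", X, X)
    loss_trace = np.empty(config.epochs)
    warned_gamma = False

    def check_epochs() -> set[int]:
        out = set()
        e = config.zero_check_start
        while e <= config.epochs:
            if e >= 1:
                out.add(e)
            e += config.zero_check_every
        out.add(config.epochs)  # always one final check
        return out

    checks = check_epochs()

    if epoch_callback is not None:
        epoch_callback(0, NetworkState(w=w.copy(), gamma=gamma, mask=mask.copy()))

    for epoch in range(1, config.epochs + 1):
        Xw = X @ w
        r = y - gamma * Xw
        g_w = (-2.0 * gamma / N) * (X.T @ r) + config.lambda0 * np.sign(w)
        g_w[~mask] = 0.0

        m_w = b1 * m_w + (1 - b1) * g_w
        v_w = b2 * v_w + (1 - b2) * g_w**2
        w = w - lr * (m_w / (1 - b1**epoch)) / (np.sqrt(v_w / (1 - b2**epoch)) + eps)
        w[~mask] = 0.0

        if not config.freeze_gamma:
            g_g = (-2.0 / N) * float(Xw @ r)
            m_g = b1 * m_g + (1 - b1) * g_g
            v_g = b2 * v_g + (1 - b2) * g_g**2
            gamma -= lr * (m_g / (1 - b1**epoch)) / (
                np.sqrt(v_g / (1 - b2**epoch)) + eps
            )

        if epoch in checks:
            resid = y - gamma * (X @ w)
            partial = X.T @ resid + gamma * col_sq * w
            zero = np.abs(2.0 * partial) <= abs(lam_sum / gamma)
            mask = ~zero
            w = np.where(mask, w, 0.0)

        resid = y - gamma * (X @ w)
        loss_trace[epoch - 1] = resid @ resid / N + config.lambda0 * np.abs(w).sum()

        if not np.isfinite(loss_trace[epoch - 1]):
            logger.warning("non-finite loss at epoch %d; aborting restart", epoch)
            return None
        if not warned_gamma and (abs(gamma) > GAMMA_WARN_HIGH or abs(gamma) < GAMMA_WARN_LOW):
            logger.warning(
                "gamma = %.3g: effective lambda = lambda0/gamma has "
                "collapsed or exploded", gamma,
            )
            warned_gamma = True

        if epoch_callback is not None:
            epoch_callback(epoch, NetworkState(w=w.copy(), gamma=gamma, mask=mask.copy()))

    train_mse = float(resid @ resid / N)
    state = NetworkState(w=w, gamma=gamma, mask=mask)
    return state, train_mse, loss_trace


def train_dlasso(
    X: np.ndarray,
    y: np.ndarray,
    config: DlassoConfig | None = None,
    epoch_callback: Callable[[int, NetworkState], None] | None = None,
) -> FittedModel:
    """Fit the neural lasso by multi-restart joint gradient descent.

    Each restart initializes (w, gamma) afresh, runs ``config.epochs``
    full-batch Adam steps on the mean-form objective with periodic
    subgradient zeroing, and the restart with the lowest *unpenalized*
    training MSE is kept.  ``epoch_callback(epoch, state)``, if given, is
    invoked after every epoch of every restart (used for diagnostics
    such as test-error traces; it sees standardized-scale states).
    """
    if config is None:
        config = DlassoConfig()
    X, y = _check_xy(X, y)
    N, p = X.shape
    if N < 2:
        raise ValueError(f"need at least 2 observations, got {N}")
    if p < 1:
        raise ValueError("X has no feature columns")

    if config.standardize:
        if np.ptp(y) == 0:
            raise ValueError("y is constant; cannot center a constant response")
        Xs, yc, x_mean, x_scale, y_mean = _standardize(X, y)
    else:
        Xs, yc = X, y
        x_mean = np.zeros(p)
        x_scale = np.ones(p)
        y_mean = 0.0

    seed_seq = np.random.SeedSequence(config.seed)
    restart_seeds = seed_seq.spawn(config.restarts)

    best = None
    restart_losses = np.full(config.restarts, np.nan)
    for k in range(config.restarts):
        rng = np.random.default_rng(restart_seeds[k])
        out = _run_restart(Xs, yc, config, rng, epoch_callback=epoch_callback)
        if out is None:
            continue
        state, train_mse, trace = out
        restart_losses[k] = train_mse
        if best is None or train_mse < best[1]:
            best = (state, train_mse, trace)

    if best is None:
        raise RuntimeError("all restarts diverged (non-finite loss)")

    state, train_mse, trace = best
    beta_hat = extract_beta(state)
    return FittedModel(
        beta_hat=beta_hat,
        gamma=state.gamma,
        effective_lambda=config.lambda0 / state.gamma,
        train_mse=train_mse,
        loss_trace=trace,
        restart_losses=restart_losses,
        config=config,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        w=state.w,
        mask=state.mask,
    )
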