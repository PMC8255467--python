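"""Performance metrics, paired tests and the benchmark/validation runners.

Metrics follow the benchmark conventions of sparse-regression simulation
studies:

* ``nrmse`` — test RMSE divided by the standard deviation (ddof=1) of
  the observed test response, so an oracle predictor attains the
  noise-to-signal floor sqrt(sigma^2 / var(y)) and the null model sits
  near 1.
* ``support_recall`` — proportion of truly nonzero coefficients
  estimated nonzero.
* ``support_precision`` — proportion of truly *zero* coefficients
  estimated zero (note: a proportion over the true zeros, not the
  usual positive-predictive value).

Zero/nonzero status is exact (both fitters produce bit-exact zeros);
no epsilon thresholding is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .baseline import tune_lasso
from .model import DlassoConfig, train_dlasso
from .simulate import SimulatedDataset, gen_experiment1, gen_experiment2

logger = logging.getLogger(__name__)

__all__ = [
    "nrmse",
    "support_recall",
    "support_precision",
    "PairedTest",
    "paired_comparison",
    "BenchmarkSummary",
    "run_benchmark",
    "epoch_trace",
    "RepeatedValidationResult",
    "repeated_validation",
]

METRICS = ("nrmse", "recall", "precision")


def nrmse(y_pred: np.ndarray, y_true: np.ndarray) -> float:
    """Root mean squared error normalized by sd(y_true) (ddof=1)."""
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    y_true = np.asarray(y_true, dtype=float).ravel()
    if y_pred.shape != y_true.shape:
        raise ValueError(f"length mismatch: {y_pred.shape} vs {y_true.shape}")
    if y_true.size < 2:
        raise ValueError("need at least 2 observations")
    sd = y_true.std(ddof=1)
    if sd == 0:
        raise ValueError("y_true is constant; normalized RMSE undefined")
    return float(np.sqrt(np.mean((y_pred - y_true) ** 2)) / sd)


def support_recall(beta_hat: np.ndarray, beta_true: np.ndarray) -> float:
    """Fraction of true nonzero coefficients estimated nonzero."""
    beta_hat = np.asarray(beta_hat).ravel()
    beta_true = np.asarray(beta_true).ravel()
    if beta_hat.shape != beta_true.shape:
        raise ValueError("coefficient vectors have different lengths")
    nz = beta_true != 0
    if not nz.any():
        raise ValueError("beta_true has no nonzero entries; recall undefined")
    return float(np.sum(nz & (beta_hat != 0)) / np.sum(nz))


def support_precision(beta_hat: np.ndarray, beta_true: np.ndarray) -> float:
    """Fraction of true zero coefficients estimated zero."""
    beta_hat = np.asarray(beta_hat).ravel()
    beta_true = np.asarray(beta_true).ravel()
    if beta_hat.shape != beta_true.shape:
        raise ValueError("coefficient vectors have different lengths")
    z = beta_true == 0
    if not z.any():
        raise ValueError("beta_true has no zero entries; precision undefined")
    return float(np.sum(z & (beta_hat == 0)) / np.sum(z))


@dataclass
class PairedTest:
    p_value: float
    t_stat: float
    significant_01: bool
    significant_05: bool
    degenerate: bool = False


def paired_comparison(metric_a: np.ndarray, metric_b: np.ndarray) -> PairedTest:
    """Two-sided paired t-test on per-repetition metric values.

    Zero-variance differences (including identical inputs) are a
    degenerate case: reported as p = 1, not significant.
    """
    a = np.asarray(metric_a, dtype=float).ravel()
    b = np.asarray(metric_b, dtype=float).ravel()
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    d = a - b
    if np.ptp(d) == 0:
        return PairedTest(p_value=1.0, t_stat=np.nan, significant_01=False,
                          significant_05=False, degenerate=True)
    t, p = stats.ttest_rel(a, b)
    return PairedTest(p_value=float(p), t_stat=float(t),
                      significant_01=p < 0.01, significant_05=p < 0.05)


@dataclass
class BenchmarkSummary:
    """Per-configuration benchmark result: per-repetition metric vectors,
    their means/sds, and paired dlasso-vs-lasso tests per metric."""

    experiment: int
    p: int
    rho: float | None
    reps: int
    seed: int | None
    values: dict = field(default_factory=dict)  # (method, metric) -> array
    paired: dict = field(default_factory=dict)  # metric -> PairedTest

    @property
    def methods(self) -> list[str]:
        return sorted({m for m, _ in self.values})

    def mean(self, method: str, metric: str) -> float:
        return float(np.mean(self.values[(method, metric)]))

    def sd(self, method: str, metric: str) -> float:
        return float(np.std(self.values[(method, metric)], ddof=1))

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per method x metric."""
        rows = []
        for (method, metric), v in sorted(self.values.items()):
            rows.append({
                "experiment": self.experiment, "p": self.p, "rho": self.rho,
                "method": method, "metric": metric,
                "mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1)),
                "reps": self.reps,
            })
        return pd.DataFrame(rows)

    def format_table(self) -> str:
        """Text table in the mean(sd) style with significance stars."""
        lines = [f"experiment {self.experiment}  p = {self.p}"
                 + (f"  rho = {self.rho}" if self.rho is not None else "")]
        header = f"{'method':<10}" + "".join(f"{m:>16}" for m in METRICS)
        lines.append(header)
        for method in self.methods:
            cells = []
            for metric in METRICS:
                v = self.values[(method, metric)]
                star = ""
                test = self.paired.get(metric)
                if test is not None and not test.degenerate:
                    if test.significant_01:
                        star = "**"
                    elif test.significant_05:
                        star = "*"
                cells.append(f"{np.mean(v):.3g}({np.std(v, ddof=1):.2g}){star:<2}")
            lines.append(f"{method:<10}" + "".join(f"{c:>16}" for c in cells))
        return "\n".join(lines)


def _fit_lasso_standardized(X_tr, y_tr, grid_size, n_boot, seed):
    """Tune/fit the classical lasso on standardized X and centered y;
    returns (beta on standardized scale, predict function)."""
    x_mean = X_tr.mean(axis=0)
    x_sd = X_tr.std(axis=0, ddof=0)
    x_sd = np.where(x_sd > 0, x_sd, 1.0)
    y_mean = y_tr.mean()
    Xs = (X_tr - x_mean) / x_sd
    fit = tune_lasso(Xs, y_tr - y_mean, grid_size=grid_size, n_boot=n_boot, seed=seed)

    def predict(X_new):
        return y_mean + ((X_new - x_mean) / x_sd) @ fit.beta_hat

    return fit.beta_hat, predict


def _generate(experiment, p, rho, seed):
    if experiment == 1:
        return gen_experiment1(p=p, seed=seed)
    if experiment == 2:
        if rho is None:
            raise ValueError("experiment 2 requires rho")
        return gen_experiment2(p=p, rho=rho, seed=seed)
    raise ValueError(f"unknown experiment {experiment!r}")


def run_benchmark(
    experiment: int,
    p: int,
    rho: float | None = None,
    reps: int = 100,
    config: DlassoConfig | None = None,
    seed: int | None = None,
    methods: tuple[str, ...] = ("dlasso", "lasso"),
    lasso_grid: int = 1000,
    lasso_boot: int = 5,
) -> BenchmarkSummary:
    """Repeat generate -> fit -> score and aggregate.

    Each repetition draws a fresh dataset (50 train / 950 test by
    default), fits the requested methods on the training rows, and
    records test nrmse plus support recall/precision against the
    generating coefficients.  Fully reproducible from ``seed``.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    if config is None:
        config = DlassoConfig()
    master = np.random.default_rng(seed)
    rep_seeds = master.integers(0, 2**31 - 1, size=(reps, 3))

    values = {(m, met): np.empty(reps) for m in methods for met in METRICS}

    for r in range(reps):
        data_seed, fit_seed, tune_seed = (int(s) for s in rep_seeds[r])
        for attempt in range(2):
            try:
                ds = _generate(experiment, p, rho, data_seed + attempt)
                if "dlasso" in methods:
                    model = train_dlasso(
                        ds.X_train, ds.y_train, config.with_(seed=fit_seed)
                    )
                    values[("dlasso", "nrmse")][r] = nrmse(
                        model.predict(ds.X_test), ds.y_test)
                    values[("dlasso", "recall")][r] = support_recall(
                        model.beta_hat, ds.beta_true)
                    values[("dlasso", "precision")][r] = support_precision(
                        model.beta_hat, ds.beta_true)
                if "lasso" in methods:
                    beta, predict = _fit_lasso_standardized(
                        ds.X_train, ds.y_train, lasso_grid, lasso_boot, tune_seed)
                    values[("lasso", "nrmse")][r] = nrmse(
                        predict(ds.X_test), ds.y_test)
                    values[("lasso", "recall")][r] = support_recall(
                        beta, ds.beta_true)
                    values[("lasso", "precision")][r] = support_precision(
                        beta, ds.beta_true)
                break
            except Exception:
                if attempt == 1:
                    raise
                logger.warning("repetition %d failed; retrying with derived seed", r)

    summary = BenchmarkSummary(experiment=experiment, p=p, rho=rho,
                               reps=reps, seed=seed, values=values)
    if "dlasso" in methods and "lasso" in methods:
        for met in METRICS:
            summary.paired[met] = paired_comparison(
                values[("dlasso", met)], values[("lasso", met)])
    return summary


def epoch_trace(
    dataset: SimulatedDataset,
    config: DlassoConfig | None = None,
    max_epochs: int = 5000,
) -> np.ndarray:
    """Test nrmse after every training epoch of a single restart.

    Entry ``e`` of the returned array (length ``max_epochs + 1``) is the
    test nrmse of the network state after epoch ``e``; entry 0 is the
    freshly initialized network (near 1 for a small-scale init).  Used
    to check that long training does not degrade test performance.
    """
    if max_epochs < 1:
        raise ValueError("max_epochs must be >= 1")
    if config is None:
        config = DlassoConfig()
    cfg = config.with_(restarts=1, epochs=max_epochs,
                       zero_check_start=min(config.zero_check_start, max_epochs))

    X_tr, y_tr = dataset.X_train, dataset.y_train
    X_te, y_te = dataset.X_test, dataset.y_test
    if cfg.standardize:
        x_mean = X_tr.mean(axis=0)
        x_sd = np.where(X_tr.std(axis=0) > 0, X_tr.std(axis=0), 1.0)
        y_mean = y_tr.mean()
        Xs_te = (X_te - x_mean) / x_sd
    else:
        x_mean, x_sd, y_mean = 0.0, 1.0, 0.0
        Xs_te = X_te

    series = np.full(max_epochs + 1, np.nan)

    def callback(epoch, state):
        pred = y_mean + Xs_te @ (state.gamma * state.w)
        series[epoch] = nrmse(pred, y_te)

    train_dlasso(X_tr, y_tr, cfg, epoch_callback=callback)
    return series


@dataclass
class RepeatedValidationResult:
    """Split-and-refit validation summary for dlasso and the
    all-predictor least-squares baseline."""

    reps: int
    n_train: int
    values: dict = field(default_factory=dict)  # (method, metric) -> array

    def mean(self, method: str, metric: str) -> float:
        v = self.values[(method, metric)]
        return float(np.nanmean(v))

    def sd(self, method: str, metric: str) -> float:
        v = self.values[(method, metric)]
        return float(np.nanstd(v, ddof=1))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"method": m, "metric": met, "mean": self.mean(m, met),
             "sd": self.sd(m, met), "reps": self.reps}
            for (m, met) in sorted(self.values)
        ]
        return pd.DataFrame(rows)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def repeated_validation(
    X: np.ndarray,
    y: np.ndarray,
    n_train: int = 50,
    reps: int = 100,
    config: DlassoConfig | None = None,
    seed: int | None = None,
) -> RepeatedValidationResult:
    """Repeated random train/test splitting for small-sample validation.

    Per repetition: a random ``n_train``-row training set, the rest held
    out; dlasso is fit and scored by the Pearson correlation between
    predicted and observed test responses plus the raw and normalized
    test RMSE.  An unpenalized least-squares fit on *all* predictors
    (with intercept; minimum-norm when n_train <= p) is scored alongside
    as the no-selection baseline.  Splits with a degenerate (constant)
    test response get a missing correlation, excluded from the means.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if not 1 < n_train < n:
        raise ValueError(f"n_train must lie in (1, {n}), got {n_train}")
    if config is None:
        config = DlassoConfig()
    master = np.random.default_rng(seed)

    metrics = ("corr", "rmse", "nrmse")
    values = {(m, met): np.full(reps, np.nan)
              for m in ("dlasso", "ols") for met in metrics}

    for r in range(reps):
        perm = master.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        fit_seed = int(master.integers(0, 2**31 - 1))

        model = train_dlasso(X[tr], y[tr], config.with_(seed=fit_seed))
        pred = model.predict(X[te])

        ones = np.ones((n_train, 1))
        coef = np.linalg.lstsq(np.hstack([ones, X[tr]]), y[tr], rcond=None)[0]
        pred_ols = coef[0] + X[te] @ coef[1:]

        for method, pr in (("dlasso", pred), ("ols", pred_ols)):
            c = _pearson(pr, y[te])
            if np.isnan(c):
                logger.warning("rep %d: degenerate correlation for %s", r, method)
            values[(method, "corr")][r] = c
            values[(method, "rmse")][r] = float(np.sqrt(np.mean((pr - y[te]) ** 2)))
            if np.ptp(y[te]) > 0:
                values[(method, "nrmse")][r] = nrmse(pr, y[te])

    return RepeatedValidationResult(reps=reps, n_train=n_train, values=values)
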