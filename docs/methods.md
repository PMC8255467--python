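# Methods

## Model and reparameterization

The package estimates a sparse linear model by recasting the lasso
objective. For data X ∈ ℝ^(N×p), y ∈ ℝ^N, the classical (sum-form)
problem is

    minimize over beta:   ||y − X·beta||² + lambda·||beta||₁ .

Substituting beta = gamma·w with gamma = lambda0/lambda gives an
equivalent problem in (w, gamma) in which the penalty constant lambda0
is *fixed* and the scalar gamma is free:

    minimize over (w, gamma):   (1/N)·||y − gamma·X·w||² + lambda0·||w||₁ .

The package trains this mean form (the per-observation scale keeps
gradients and the default learning rate independent of N); it equals
the sum form with penalty constant N·lambda0, and every comparison
against a sum-form solver uses exactly that conversion. Training
(w, gamma) jointly by gradient descent turns the effective
regularization lambda = lambda0/gamma into a learned quantity: no
cross-validation grid is ever formed. The architecture is deliberately
minimal — one linear weight layer, one scalar output weight, no biases,
no nonlinearities — so the estimator stays a linear model with an
interpretable coefficient vector beta_hat = gamma·w.

## Exact zeroing

First-order optimizers do not land weights exactly on the kink of the
L1 penalty, so a trained network alone never yields exact zeros. The
package therefore applies the coordinate-wise subgradient optimality
test: w_j = 0 is consistent with stationarity of the penalized problem
iff

    | 2·X_jᵀ( y − gamma·Σ_{i≠j} X_i·w_i ) | ≤ | lambda_pen / gamma | ,

where lambda_pen is the sum-form penalty constant (N·lambda0 inside the
trainer). The partial residual excludes feature j, so the test does not
depend on the current w_j. At each check the test is evaluated for all
coordinates simultaneously against the pre-check state (making the
outcome independent of coordinate order), the sparsity mask is rebuilt
from scratch — previously zeroed weights may revive — and masked weights
are clamped to exactly zero until the next check. Zeros in the reported
coefficients are therefore bit-exact, never thresholded small values.
At a classical-lasso minimizer this test reproduces the KKT zero/nonzero
partition exactly, which the test suite verifies against an independent
coordinate-descent solver.

## Training procedure and defaults

* **Optimizer** — full-batch Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8),
  learning rate 0.01. Sample sizes here are tens of rows, so full-batch
  gradients are natural; 0.01 converges within the standard 1000-epoch
  budget on the benchmark designs (see the trace diagnostic below). The
  L1 term contributes its subgradient, with sign(0) = 0 so an unmasked
  weight at zero can be pulled away by the smooth part.
* **lambda0 = 1** (mean form, standardized data). Since gamma is
  trained, lambda0 only sets the origin of the search for the effective
  penalty; it is user-configurable.
* **Epochs = 1000, restarts = 20** per fit, each restart from
  w ~ U(−0.05, 0.05) and gamma = 1, with per-restart sub-seeds derived
  deterministically from the master seed. The restart with the lowest
  *unpenalized* training MSE is selected.
* **Zeroing schedule** — checks every 100 epochs starting at epoch
  min(500, epochs), plus always one final check after the last epoch.
  The trace diagnostic shows test error is flat in training length, so
  the exact schedule is not critical; it is configurable.
* **Standardization (default on)** — columns of X are scaled to unit
  variance and y is centered using training statistics; coefficients are
  reported on the standardized scale and predictions (and
  `coef_original`) are mapped back. Benchmark metrics against the
  generating truth use the support (scale-invariant) and original-scale
  predictions.
* **Degenerate gamma** — |gamma| beyond 1e6 or below 1e-6 logs a warning
  (the effective penalty has collapsed or exploded); no constraint is
  imposed, because the learned-penalty formulation intentionally leaves
  gamma free and the diagnostic is more informative than a clamp.
* **Diagnostic mode** — `freeze_gamma=True` pins gamma at its initial
  value, reducing the trainer to a subgradient solver for the classical
  lasso at lambda = N·lambda0/gamma; the equivalence tests run this mode
  at learning rate 0.005 for 4000 epochs because plain Adam's terminal
  oscillation around the L1 kink is of the order of the learning rate,
  and 0.01 would be as large as the 1e-2 agreement tolerance being
  checked.

A restart whose loss becomes non-finite is abandoned with a warning;
if every restart diverges the fit raises an error.

## Classical-lasso baseline

The comparison method solves the sum-form lasso by coordinate descent
(scikit-learn's `Lasso`, penalty conversion alpha = lambda/(2N),
objective tolerance 1e-10; the unpenalized limit falls back to least
squares). Its penalty is chosen without cross-validation: 1000
candidates drawn log-uniformly on [1e-4·λ_max, λ_max] (λ_max =
max_j |2X_jᵀy| is the smallest penalty with an all-zero solution), each
scored by root-mean-squared error on the out-of-bag rows of 5 bootstrap
resamples of the training data, and the best candidate refit on the full
training set. Candidates are fitted in descending order with warm
starts, so the grid costs little more than one regularization path.
Degenerate resamples (constant in-bag response or empty out-of-bag set)
are redrawn.

## Simulated designs

Experiment-style generators reproduce two standard benchmark designs:

1. **AR(1) design** — X rows i.i.d. N(0, Σ) with Σ_ij = 0.5^|i−j|,
   beta = (3, 1.5, 0, 0, 2, 0, …, 0), noise variance 5, 50 training and
   950 test rows. The oracle normalized-rmse floor at p = 20 is
   √(5/26.25) ≈ 0.436 (var y = βᵀΣβ + 5 = 26.25).
2. **Block design** — Σ block-diagonal with two 20×20
   compound-symmetry blocks (unit diagonal, off-diagonal ρ) on features
   1–20 and 21–40 and identity beyond (features past 40 are pure noise;
   a literal zero covariance block would be degenerate), beta_j ~
   U[0.9, 1.1] for j = 1…10 and U[−1.1, −0.9] for j = 21…30 (redrawn
   each call), zero elsewhere, noise variance 10.

The noise levels are variances (σ² = 5 and 10): under the alternative
reading (σ = 5) the oracle error floor would already exceed the
benchmark error levels these designs are known to produce, so that
reading is internally impossible.

A third generator produces a **questionnaire-shaped stand-in**: n = 73
respondents, p = 44 Likert-type items obtained by discretizing a
correlated latent Gaussian (AR(1), ρ = 0.3) into 5- or 11-point scales,
and a response driven by 7 items (alternating signs, magnitudes
U[0.6, 1.0] on the standardized items) plus Gaussian noise sized for a
population R² of 0.4 — a moderate signal appropriate to psychometric
data. This is synthetic by construction: it emulates only the shape
(sample size, item count, discreteness, sparse signal) of a small
questionnaire study, not any real instrument's item distributions,
inter-scale structure or response biases. Results on it show the
method's small-sample behavior under a known sparse truth; they say
nothing about any particular clinical dataset.

## Metrics and benchmark protocol

* **nrmse** — test RMSE divided by the test response's standard
  deviation (ddof = 1). The raw-scale RMSE of a good fit is bounded
  below by the noise σ, which varies across designs; normalizing by
  sd(y) puts all configurations on a common noise-to-signal scale where
  the oracle floor is √(σ²/var y) and the null model sits at ≈ 1.
* **recall** — the fraction of truly nonzero coefficients estimated
  nonzero; **precision** — the fraction of truly *zero* coefficients
  estimated zero. Both use exact zero status (both fitters produce
  bit-exact zeros), no epsilon.
* **paired comparison** — two-sided paired t-test across repetitions,
  flagged at 0.05 and 0.01; zero-variance differences are reported as a
  degenerate case with p = 1.
* **benchmark runner** — per repetition: fresh dataset, both fits on
  the 50 training rows, metrics on the 950 test rows; means, standard
  deviations and paired tests over repetitions, all reproducible from a
  single seed. The full protocol uses 100 repetitions and 20 restarts;
  the shipped acceptance runs use 20 repetitions and 5 restarts, a
  scale at which the restart-to-restart variation is already far below
  the dataset-to-dataset variation.
* **epoch trace** — single-restart training with the test nrmse
  recorded after every epoch (entry 0 is the freshly initialized,
  near-null network). Used to verify that long training does not
  degrade test error.
* **repeated validation** — repeated random train/test splits
  (default 50 training rows), recording the Pearson correlation between
  predicted and observed test responses plus raw and normalized RMSE,
  for the neural lasso and for an all-predictor least-squares baseline
  (with intercept; the minimum-norm solution when the training set is
  smaller than the predictor count). Splits with a constant test
  response yield a missing correlation, excluded from the averages. Raw
  RMSE is reported alongside the normalized version because correlation
  and raw RMSE are the conventional summaries in the repeated-validation
  setting, but raw RMSE is only comparable within one response scale.

## Numerical choices and edge cases

* Constant feature columns get scale 1 during standardization (their
  coefficients are necessarily zero); a constant response cannot be
  centered and is an error.
* Multivariate normal sampling uses Cholesky factorization of the
  covariance after a symmetry check; covariances used here are positive
  definite by construction.
* CSV I/O writes floats with `%.17g` and parses with correctly-rounded
  conversion, so dataset files round-trip bit-exactly.
* All stochastic components (generators, restarts, bootstrap, splits)
  derive sub-seeds deterministically from a single integer seed;
  identical seeds give bit-identical results.

## Known limitations

* The learned penalty can drift toward zero as gamma grows: the trained
  solution at fixed epochs is partly governed by early stopping rather
  than a stationary point, which is inherent to the formulation. The
  reported `effective_lambda` makes this observable.
* Squared-error loss only; no GLM variants, minibatching or deeper
  architectures.
* Selection by minimum training MSE across restarts favors the least
  regularized restart; with homogeneous restarts (the observed regime)
  this is harmless, but pathological configurations could overfit.
* The questionnaire stand-in is a shape emulation; conclusions about
  real questionnaire data require the real data.
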