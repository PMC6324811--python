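# Methods

## Model

Let `y_i` (i = 1..N) be non-negative integer counts scored over positive
exposures `c_i`, with a partitioned design: `J` unpenalized covariates
`x_ij` forced into the model and `K` penalized covariates `x_ik` subject to
selection (P = J + K, typically P >> N). Both families use the log link
with `log(c_i)` as a fixed-coefficient offset, so the model is a rate
model:

    mu_i = c_i * exp(gamma0 + x_ij' gamma + x_ik' beta)

Poisson: `Var(Y_i) = mu_i`. Negative binomial (NB, the gamma–Poisson
mixture): `Var(Y_i) = mu_i + alpha * mu_i^2`, where `alpha >= 0` is the
heterogeneity (the inverse of the classical dispersion `phi`); `alpha -> 0`
recovers the Poisson. All Gamma-function ratios in the NB mass function are
evaluated through `gammaln`; for `alpha < 1e-5` the ratio
`Gamma(y + 1/alpha)/Gamma(1/alpha)` is instead computed as the exact finite
sum over integer `y`, which keeps the likelihood accurate to ~1e-8 into the
Poisson limit (the naive log-gamma difference loses ~1e-5 per observation
there).

`alpha` is floored at 1e-8 rather than exactly 0 so every NB expression
stays defined; at the floor the NB and Poisson likelihoods agree to within
O(alpha * sum(y^2)), i.e. they are numerically indistinguishable.

## The GMIFS path

The penalized block is column-standardized (mean 0, sd 1; scaling constants
retained for back-transformation) and expanded to `[X : -X]`, so a signed
update is always a non-negative increment on one of 2K columns. The path:

1. Start at `beta = 0`; fit `(gamma0, gamma)` by maximum likelihood;
   initialise `alpha` by the plain moment ratio (below).
2. At each step, compute the expanded score
   `x~' (y - mu) / (1 + alpha*mu)` and increment by `epsilon` the
   coefficient with the largest gradient (ties: lowest column index, for
   reproducible paths).
3. Refit `(gamma0, gamma)` by Newton's method holding `beta` fixed
   (analytic gradient and Hessian, warm-started, gradient-infinity-norm
   tolerance 1e-8, max 100 iterations; the Hessian weights are
   `mu(1+alpha*y)/(1+alpha*mu)^2`, so the inner problem is concave).
4. Re-estimate `alpha` (NB only; see below).
5. Stop when `|l(s+1) - l(s)| < tau`, when the number of nonzero
   *differenced* coefficients (`beta_k - beta_{K+k}`) exceeds N - 1, or at
   `max_steps` (default 50,000 — the algorithm is incremental and needs a
   hard guard).

Defaults `epsilon = 0.001`, `tau = 1e-5`. Reported coefficients live on
the standardized scale; `coef_original()` back-transforms
(`beta_orig = beta_std / sd`, intercept shifted by
`-sum(beta_std * mean / sd)`). Unpenalized covariates are deliberately not
standardized: they are forced in, so their scale cannot affect selection.

Every step's record carries the log-likelihood, `alpha`, the refit
`(gamma0, gamma)`, the nonzero count, and AIC/BIC with
`df = (#nonzero differenced beta) + J + 1 + 1{NB}` — every estimated
quantity counts, including `alpha`, at every step including step 0.

### Heterogeneity updates along the path

The public moment estimator is the plain ratio implied by
`Var = mu + alpha*mu^2`:

    alpha_hat = sum[(y_i - mu_i)^2 - mu_i] / sum[mu_i^2]

It is consistent (absolute error < 0.05 at n = 1e5 for alpha in 0.3–0.5)
and is used to initialise the path. As the **per-step** update, however,
the plain ratio is unstable: early in the path the marginal residuals
contain all of the unexplained signal variance, the ratio badly
overestimates `alpha` (values of 2–4 when the conditional truth is 0.3),
and the resulting heavy damping of the gradient can feed back until the
path drifts downhill from the null model and terminates uselessly. The
default per-step update is therefore the NB Pearson chi-square moment
equation at the current residual degrees of freedom:

    sum (y_i - mu_i)^2 / (mu_i * (1 + alpha*mu_i)) = N - p,

solved for `alpha` by bracketed root finding, with `p` the current number
of mean parameters. This update weights residuals exactly as the score
does, which makes the alpha/coefficient feedback self-consistent: across
hundreds of simulated datasets it produced no degenerate paths. It is also
df-aware: near the N - 1 stopping boundary `alpha_hat` grows, which damps
further (over)fitting. The plain ratio, a one-dimensional
maximum-likelihood update at fixed means, and a fixed-alpha path remain
available via `fit(alpha_update=...)`.

A consequence worth knowing: the end-of-path `alpha` under the default
update can be large (the residual df has shrunk), and the `alpha` reported
for a *selected* model is the step-specific estimate — e.g. a BIC-selected
model typically carries an `alpha` close to the conditional truth.

### Model selection

AIC/BIC minima are exact argmins over the stored path (ties to the earlier,
sparser step). `select("cv")` minimises a per-step cross-validation curve:
each fold refits the path on the training portion, held-out error is
accumulated per step (fold paths truncated to the shortest), and the step
with the smallest mean error is chosen. `cross_validate()` answers the
different question "how well does a selection rule generalise": it applies
AIC or BIC within each training fold and averages the held-out error of the
per-fold selected models; `folds=None` means N-fold (leave-one-out).
Prediction error defaults to mean absolute error `|y - mu_hat|`; squared
error is available (`metric="mse"`). Fold assignment is a seeded
permutation, so CV is deterministic given its seed.

## Over-dispersion diagnostics

All four run on the unpenalized mean model (offset + forced-in covariates).

* **Boundary likelihood-ratio test** of `alpha = 0`: both families fit by
  full maximum likelihood (the NB by profiling the likelihood over
  `log alpha` with the coefficients refit at each candidate, the boundary
  always evaluated explicitly — this stays well-behaved when the truth is
  Poisson and `alpha_hat` sits on the boundary). Because the null places
  `alpha` on the parameter boundary, the statistic's null law is the
  mixture `0.5*chi2_0 + 0.5*chi2_1`; the mixture p-value is primary and the
  plain `chi2_1` p-value is also reported, as some software quotes it.
* **Score test** (auxiliary-regression form): regress
  `((y - mu_hat)^2 - y)/mu_hat` on `mu_hat` without intercept after a
  Poisson fit; one-sided t test on the slope.
* **Lagrange multiplier test**:
  `LM = (sum[(y - mu_hat)^2 - y])^2 / (2 * sum mu_hat^2)`, referred to
  `chi2_1`.
* **Pearson dispersion**: Pearson chi-square over residual df; values
  clearly above 1 flag over-dispersion.

All three tests hold empirical type-I error within [0.02, 0.09] at nominal
0.05 over 500 Poisson-simulated datasets of N = 500, and the boundary LR
test rejects essentially always at N = 200 when `alpha = 0.5`.

## Synthetic-data generators

The generators emulate two study designs used to evaluate selection
methods for over-dispersed counts:

* **Independent design** — N = 100 observations, P = 500 i.i.d. standard
  normal predictors, 5 true predictors with coefficients `±log(delta)`
  (signs alternating +,-,+,-,+; `delta` in {1.5, 1.75}), intercept
  `gamma0 = 0.5`, NB responses with `alpha` in {0.3, 0.5}; 200 replicates
  by default.
* **Block-correlated design** — N = 50, P = 5000 features in 125 blocks of
  40; within-block correlations drawn N(0, 0.28), clipped to (-0.99, 0.99),
  symmetrized, unit diagonal, then each block repaired to the nearest
  positive-definite correlation matrix by eigenvalue flooring at 1e-4 and
  renormalisation to unit diagonal. True coefficients `±log(2)`, one true
  feature per chosen block, `alpha = 0.35`. Worth stating plainly: a
  40x40 symmetric matrix filled with i.i.d. N(0, 0.28) off-diagonals is
  almost never positive definite, and the repair is not a small
  perturbation — it shrinks the realised off-diagonal sd from 0.28 to
  about 0.16. The drawn (pre-repair) values are retained on the returned
  object so both distributions are inspectable.

Responses are drawn through the gamma–Poisson mixture, which reproduces
`Var(Y) = mu + alpha*mu^2` within Monte-Carlo error across the `mu` range
(checked by decile). Replicate r of a study uses
`default_rng([base_seed, r])`, so replicates are independent and
individually reproducible; the harness evaluates prediction error on an
independently generated test set of the same size and design (a
generalisation measure, not resubstitution). External comparator paths
(e.g. a lasso path from another package) plug in as callables and are
scored at the first step whose coefficient L1 norm reaches the GMIFS
selection's — the L1-matched comparison that makes a penalty-grid method
comparable to a stagewise path.

What the generators do **not** emulate: real expression data are not
Gaussian, correlation is not block-diagonal, true effects are not exactly
five or of equal magnitude, and counts often carry extra zero inflation.
Passing tests therefore demonstrate algorithmic correctness and behaviour
under the stated stochastic models, not performance guarantees on any
particular cohort.

## Selection behaviour and known limitations

* On the independent design at `alpha = 0.3`, `delta = 1.75` (20
  replicates), AIC selection recovers all five true predictors in the
  median replicate but keeps roughly 25–50 false positives — about half
  the N - 1 budget — while BIC keeps the true-predictor recovery with a
  median of ~2–5 false positives. Greedy stagewise fitting earns ~1
  likelihood unit per spurious feature quite easily at N = 100, and AIC's
  per-df price of 2 does not deter it; if sparsity matters, use BIC or CV.
  This ordering (BIC sparser than AIC, both far sparser than
  penalty-grid Poisson comparators) is the behaviour the method is known
  for.
* The incremental path costs O(N*K) per step and paths routinely run for
  thousands of steps; N = 100, P = 500 fits take a few seconds. The
  simulation harness and tests use 20-replicate versions of the 200-
  replicate designs and short-path settings where only contracts (not
  converged estimates) are under test; these sizes are stated in the
  relevant docstrings.
* Inference (standard errors, p-values) on selected coefficients is out of
  scope, as are zero-inflated/truncated/quantile count models and
  elastic-net mixing.
* The exact moment formula behind the published dispersion initialiser and
  the exact software variants behind the score/LM tests are not uniquely
  pinned down in the literature this package follows; the choices above
  are documented, configurable where they matter, and validated by
  simulation calibration.
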