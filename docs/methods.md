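# Methods

This note documents the model implemented by `slcm`, the assumptions it
makes, the numerical choices behind the implementation, what the
synthetic-data generator does and does not emulate, and known limitations.

## 1. Model

### 1.1 Measurement model

Counts are treated as realizations of a counting process observed under
varying exposure. Conditional on individual *i*'s random effects, the count
at occasion *w* follows the NB2 distribution

    y_iw | b_i ~ NB2(mu_iw, phi_w),    Var(y|b) = mu + phi * mu^2,

in the mean–dispersion parameterization (`phi` relates to the usual
negative-binomial "size" by `size = 1/phi`; Poisson is the `phi -> 0`
limit). The log of the exposure enters the linear predictor with its
coefficient fixed at one, so the expected count is proportional to
exposure and the growth function lives on the log-rate-per-unit-exposure
scale. With a single count indicator per occasion, the item intercept is
fixed at zero and the item slope at one; regression disturbances are not
represented separately — all unexplained variability is absorbed into the
occasion-specific dispersion `phi_w`.

### 1.2 Structural model

The target trajectory is linear–linear with an estimated changepoint and
zero-order continuity, written with min/max operators so continuity holds
identically rather than approximately:

    f(t) = beta0 + beta1 * min(t, gamma) + beta3 * max(0, t - gamma).

Time is coded as months since the origin (age 18 months); assessment ages
are binned into 3-month windows and coded by the window's lower bound, so
t ∈ {0, 3, ..., 51} on the default grid. Under zero-order continuity the
phase-2 intercept is not free: `beta2 = beta0 + beta1 * gamma`.

A growth parameter is *linear* if ∂f/∂θ does not contain θ and *nonlinear*
otherwise (`classify_linearity` applies this rule symbolically). The
unconstrained two-phase model has five free per-individual parameters
(four linear, one nonlinear changepoint); continuity eliminates one,
leaving four.

The structured-latent-curve (SLCM) reformulation takes a first-order
Taylor expansion of f around the population parameters. The basis
(factor-loading) matrix has columns

    [1,  min(t, gamma),  max(0, t - gamma),  (beta1 - beta3) * 1[t > gamma]],

evaluated at population values with the random changepoint deviation
centered at zero, so every random effect — including the changepoint's —
enters the linear predictor linearly:

    log mu_iw = log u_iw + f(t_w; beta) + Lambda(t_w; beta) b_i,
    b_i ~ MVN(0, T).

For the linear parameters the expansion is exact; for the changepoint it
is a first-order approximation, which is also exactly the data-generating
process the synthetic generator uses (see §3). At `t == gamma` the
changepoint column takes its left value (0), consistent with
`max(0, t - gamma) = 0` there; the likelihood surface therefore has kinks
in `gamma` exactly at bin times, which is why initialization places the
starting knot at a bin midpoint.

### 1.3 Dispersion trajectory

`phi_w` varies over occasions but not individuals. Three forms:

- **free** — one parameter per occasion (W parameters);
- **log-linear** — `phi(t) = exp(d0 + d1 t)` (2 parameters);
- **exponential decay with nonzero asymptote** —
  `phi(t) = delta3 + (delta1 - delta3) * delta2^t` (3 parameters), with
  `delta1 > delta3 > 0` and `delta2 ∈ (0, 1)`; `delta1` is exactly the
  dispersion at the origin and `delta3` the asymptote, and the trajectory
  is strictly decreasing and positive.

The decay factor `delta2` is deliberately *not* reported as "percent
decrease in phi per month": that phrasing is ambiguous between
proportional decay of `phi` and of `phi - delta3` (only the latter is
exact), so reports carry the coefficients themselves.

Imposing a trajectory reduces the covariance-structure parameter count
from W to 2 or 3; the intended workflow mirrors model building in
practice: fit per-bin dispersions (or the free form) first, inspect their
shape, then refit with the trajectory imposed.

### 1.4 Assumptions

Correct specification of the random-effect distribution (multivariate
normal), the conditional response distribution (NB2), the log link and
the linear predictor; independent individuals; conditional independence
of occasions within individual given b_i; measurement invariance over
individuals and occasions; exposures measured essentially without error.
Missing assessments are handled by marginal likelihood under MAR — each
individual contributes whatever occasions they have; nothing is imputed.

## 2. Estimation

### 2.1 Marginal likelihood

Each individual contributes

    l_i = log ∫ Π_w NB2(y_iw; mu_iw(b), phi_w) MVN(b; 0, T) db,

approximated by adaptive Gauss–Hermite quadrature: the integrand's mode
b̂_i is found by a damped Newton iteration (the posterior is log-concave,
so this is reliable), the curvature at the mode scales and rotates a
tensor-product Gauss–Hermite grid, and the integral is accumulated by
log-sum-exp. Multi-dimensional nodes whose joint normalized weight falls
below 1e-10 are pruned. The default is 7 nodes per dimension; 15 (the
reference-software default) is available by flag. The 1-D implementation
agrees with a 100,000-point dense-grid integral to better than 1e-6 (this
is a test).

### 2.2 Optimization

The total marginal log-likelihood is maximized directly by L-BFGS-B
rather than by EM — both target the same optimum; direct maximization
composes better with the unconstrained internal parameterization:

- `gamma` via a bounded logistic transform onto
  `[min t + 3, max t - 3]` (one bin width of margin, preventing boundary
  collapse of the knot);
- `T` via log standard deviations (diagonal, the default) or a
  log-Cholesky factor (full);
- `expdecay` coefficients via `(log(delta1 - delta3), logit(delta2),
  log(delta3))`; free dispersions via logs.

The analytic gradient treats the adaptive centering/scaling as fixed when
differentiating (the standard fixed-adaptation approximation; its error
shrinks with quadrature resolution and is verified against finite
differences in tests at ~1e-3 relative). For full (non-diagonal) T the
outer gradient falls back to finite differences.

Starting values are data-driven: pooled bin-level log rates are fit by
two-segment least squares over a grid of candidate knots at bin midpoints;
T diagonals start at 0.1·|fixed effect|; dispersions start from per-bin
method-of-moments estimates. Because the likelihood is discontinuous in
`gamma` at bin times (see §6), the converged fit is re-polished by warm
L-BFGS restarts from the adjacent knot regions (`gamma` ± half a bin
width), keeping the best — without this, roughly one fit in six stalls in
a neighbouring basin. A fit is flagged non-converged if the optimizer
fails or the changepoint pins at its transform boundary.

### 2.3 Standard errors and empirical Bayes

Model-based SEs invert the observed information (numeric Hessian of the
marginal log-likelihood via finite differences of the analytic gradient).
Cluster-robust SEs use the sandwich: bread = inverse observed information,
meat = sum of outer products of per-individual score vectors. Both are
mapped to the natural scale by the delta method. Parameters pinned at an
optimizer bound (variance components collapsed to ~0) are profiled out of
the information matrix; non-positive directions of the information
(typically the changepoint variance at coarse quadrature) are dropped from
the inverse rather than inverted, with a warning.

Per-individual random effects are reported as posterior modes with
Laplace standard deviations — the same quantities that center the adaptive
quadrature. Individual-vs-population classifications use the *sign* of the
EB intercept and phase-1 slope effects; exact zeros are reported as a
separate "at average" class.

### 2.4 Identification

The mean structure offers W observed occasion means against the free
population growth parameters (4 for the continuity-constrained model); the
covariance structure offers W(W+1)/2 observed (co)variances against the
unique elements of T plus the dispersion-trajectory coefficients (10 + 3 =
13 for the full model with decay trajectory). Both structures must be
overidentified for the model to be. `check_identification` reports the
counts and statuses; with W = 18 the full model is comfortably
overidentified. Empirical identification can still degrade with few
occasions per individual — the changepoint variance is the first casualty.

## 3. Synthetic data

The generator draws, per individual: an assessment count uniform on
{2, ..., 5}; that many 3-month windows uniformly without replacement
(MCAR) from ages [18, 72); exposures from a negative binomial with mean
120 shifted to a floor of 25, independent of age; random effects from
MVN(0, T); and counts from NB2 via the gamma–Poisson mixture with the
linear predictor of §1.2. The default truth is `beta0 = -5.8,
beta1 = 0.25, beta3 = 0, gamma = 10` (changepoint at age 28 months),
`T = diag(0.2, 0.005, 0.002, 4)`, decay dispersion `(2.5, 0.9, 0.2)` —
chosen once to mirror the qualitative shapes reported for this kind of
child-language data (a rate of a few events per 1,000 utterances at 18
months rising steeply to a plateau around 28 months; dispersion collapsing
from ~2.5 toward ~0.2). These are testing defaults, not empirical
estimates.

What the generator does *not* emulate: corpus-level clustering (corpora do
not appear in the model), the empirical exposure distribution beyond its
floor and age-independence (the shifted negative binomial is a labelled
stand-in), age-dependent attendance, and anything about transcripts or
morpheme extraction. A green recovery test therefore establishes that the
estimator recovers the parameters of *this* data-generating process — it
says nothing about robustness to design features the generator omits.

Because the generator uses the SLCM basis for the changepoint random
effect, generator and fitted model agree exactly; recovery studies test
estimation, not the adequacy of the first-order approximation to a "true"
subject-specific changepoint model.

## 4. Numerical choices and tie-breaks

- Log-space pmfs throughout via log-gamma; no factorials; `log(r + mu)`
  via `logaddexp` to avoid overflow at extreme linear predictors.
- Normalization/KLD support: extended until the model tail mass is below
  1e-12 (pmf checks) or the model-implied marginal's cumulative mass
  exceeds 1 - 1e-9 (KLD); model-implied marginal probabilities are floored
  at 1e-300 with a warning if an observed count still lands on zero mass.
- The per-bin KLD averages the fitted pmf over the bin's *per-record*
  exposures rather than a single representative exposure, because exposure
  varies record to record. (Whether the original workflow used the
  exposure-averaged marginal is not documented; this is our choice.)
- BIC sample size: the number of records in a bin (per-bin GLMs) or the
  number of individuals (SLCM fits).
- All-zero-count bins: the Poisson intercept MLE sits at -infinity; a +0.5
  continuity-corrected boundary fit is reported with a warning, and the
  NB2 dispersion is flagged unidentified.
- Duplicate assessments within a (child, window) are resolved by uniform
  random selection under the caller's seed; records below the exposure
  floor are dropped before deduplication.
- Every stochastic stage takes an explicit seed; identical seeds reproduce
  byte-identical outputs end to end.

## 5. Time budgets in the test suite

Simulation-based suites are scaled to run on one CPU: a single
50-replicate study at N = 300 with reduced (3-node) quadrature and
changepoint basin refinement serves both the bias and the
interval-coverage checks; quick structural checks use small N at 3 nodes. The quadrature resolution is a numerical-accuracy
knob, not part of the stated data-generating world; the generator's
parameters and all test bands are never adjusted for runtime.

## 6. Known limitations

- Only the two-phase degree-1 trajectory with zero-order continuity is
  fittable; `GrowthSpec` can *describe* more phases, higher degrees and
  discontinuous knots (and `classify_linearity`/parameter counting handle
  them), but the evaluators and the fitter do not.
- The changepoint variance is weakly identified at coarse quadrature and
  in designs with few early assessments; expect flat likelihood ridges,
  occasionally non-positive observed information in that direction (see
  §2.3), and wide SEs.
- **Wald intervals undercover for the changepoint and the phase-1 slope.**
  In recovery simulations at N = 300 with 2–5 assessments per child and
  changepoint variance 4, the MLE's across-dataset spread of `gamma` is
  roughly twice the average observed-information SE: the likelihood is
  strongly non-quadratic along the curved `beta1`–`gamma` ridge, so
  nominal-95% Wald intervals for `beta1` and `gamma` cover at only about
  75–85% (while `beta0` and `beta3` are calibrated). This persists at
  every quadrature resolution, the point estimates are exact maximizers
  (verified by derivative-free polish), and the SEs match independent
  value-only Hessians — it is a property of the model/design, not of the
  implementation. Fits whose `gamma` lands exactly on a bin-time kink make
  it worse: the finite-difference curvature there straddles the kink and
  the reported `gamma` SE is not meaningful. Profile-likelihood or
  bootstrap intervals should be preferred for these two parameters; they
  are not implemented here.
- The marginal likelihood is *discontinuous* in `gamma` exactly at bin
  times: observations with `t == gamma` flip their changepoint loading
  under the left-value tie-break, which creates small attracting atoms at
  bin times (a fitted `gamma` can legitimately land exactly on a bin
  boundary). The knot initialization at bin midpoints avoids starting on
  these kinks.
- Covariates on growth factors, distal outcomes, zero-inflation,
  individual-varying dispersion, higher-order continuity, and person-fit
  diagnostics are out of scope.
- The fixed-adaptation gradient approximation can stall L-BFGS slightly
  short of the exact optimizer fixed point on very flat surfaces;
  tightening `tol` and raising the node count restores agreement (the
  exposure-rescaling contract test runs in exactly this regime).
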