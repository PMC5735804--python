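# Methods

## The model

Health-care cost outcomes are *semicontinuous*: a probability mass at
exactly zero (non-users) together with a continuous, right-skewed
distribution of positive costs (users). `tweediecost` models such outcomes
with a single-distribution GLM based on the Tweedie family with
mean–variance power `p` strictly between 1 and 2,

    E(Y|x) = mu(x) = exp(x'b),        Var(Y|x) = phi * mu(x)^p.

For `p` in (1, 2) the Tweedie distribution is a compound Poisson–Gamma: a
Poisson number `M ~ Pois(lam)` of utilization events, each with an iid
Gamma(`alpha`, scale `beta`) cost, summing to `Z = X_1 + ... + X_M`.  The
compound parameters are tied to the GLM parameters by

    lam = mu^(2-p) / (phi (2-p)),   alpha = (2-p)/(p-1),   beta = phi (p-1) mu^(p-1),

so `Pr(Z = 0) = exp(-lam)` falls as the mean rises — zeros and low expected
costs are explained by the same linear predictor, unlike in two-part models
where a separate logistic equation handles the zeros.

## Density evaluation

The Tweedie density has no closed form.  For `z > 0` it is the mixture sum
over the latent event count,

    f(z) = sum_{m>=1} Pois(m; lam) * Gamma(z; m*alpha, beta),

which this package evaluates directly in log space.  The log-term sequence
in `m` is unimodal; the code locates the dominant index (`m* ≈
z^(2-p)/(phi(2-p))`), covers a window wide enough that excluded terms are
below 1e-17 of the peak, and log-sum-exps the window.  When the dominant
index is large the bump is locally Gaussian with sd `sigma =
sqrt(m*/(1+alpha))`; the sum is then taken over every k-th term with
`k = sigma/6` and multiplied by `k`.  By Poisson summation the aliasing
error of that stride is `O(exp(-2 pi^2 (sigma/k)^2)) ≈ 1e-300`, i.e. the
strided sum is exact at double precision while the work per observation
stays bounded (~100–200 terms) at any cost scale.  The Wright generalized
Bessel function that appears in the exponential-dispersion-model normalizer
is never evaluated as a named special function; the mixture series is the
same quantity.

The power parameter is restricted to [1.01, 1.999] at construction (the
mapping above divides by `(p-1)` and `(2-p)`); the upper end of that range
exists for checking the Gamma limit `p -> 2`, while model *fitting*
searches the interior interval [1.05, 1.95].

## Estimation

Fitting follows the standard profile-likelihood scheme for this family:

1. For fixed `p`, the coefficients solve the quasi-likelihood score
   equations of a log-link GLM with variance function `mu^p` (IRLS,
   delegated to statsmodels); they do not depend on `phi`.
2. Given the fitted means, `phi` is estimated by maximizing the exact
   series log-likelihood in one dimension (bounded search in `log phi`
   over [1e-4, 1e4], absolute tolerance 4e-3 on the log scale, seeded by
   the Pearson moment estimate).
3. The profile log-likelihood over `p` is maximized by a 10-point grid on
   [1.05, 1.95] followed by bounded Brent refinement to 1e-3 (the grid
   guards against local optima; in practice the profile is smooth and
   unimodal).  Hitting a bound is recorded as a warning flag in the fit
   metadata, not an error.

AIC counts `phi` and `p` as estimated parameters (`k = n_coef + 2`), since
both are maximized over; the count is configurable (`count_aux`) because
published AICs do not always state this convention.  Coefficient covariance
is the quasi-likelihood sandwich-free form `phi_hat (X'WX)^{-1}`.
Cross-validation refits warm-start the `p` search in a ±0.1 bracket around
the full-data estimate (tolerance 3e-3); the profile is flat at that scale,
so this affects only run time.

## Competitor models

* **Two-part**: logistic regression on `1{y>0}` plus a positive-part model
  on the `y>0` rows; combined AIC is the sum of the parts (disjoint
  parameters, factorizing likelihood), and `E[y|x]` multiplies the two
  parts.  Under (quasi-)complete separation — which genuinely occurs when
  zeros are carved from the lowest costs of a nearly deterministic cost
  ordering — the logistic MLE diverges; the reported log-likelihood is then
  computed from fitted probabilities clipped to [1e-10, 1-1e-10] (finite,
  near-zero deviance) and a `separation` flag is set.
* **Positive parts**: Gamma (log-link GLM; shape by exact MLE given the
  fitted means) and generalized Gamma in the log-location–scale Prentice
  form with parameters (location `x'b`, scale `sigma`, shape `q`): `q=1`
  is Weibull, `q=sigma` is Gamma, `q -> 0` is log-normal.  The MLE runs
  L-BFGS-B from log-normal starting values (`q` starting at 1, restart at
  0.5), with `q` bounded to [0.03, 10] so the fitted mean
  `exp(x'b) (q^2)^(sigma/q) Gamma(q^-2 + sigma/q)/Gamma(q^-2)` exists; the
  lower bound is numerically indistinguishable from the log-normal corner.
* **Tobit**: type-I *censored* normal MLE (zeros contribute
  `Phi(-x'b/sigma)`, positives a normal density term).  The model is often
  described loosely as "truncated"; the likelihood above is the Tobit
  definition.  With no zeros present it reduces to ordinary least squares.
* **Poisson**: log-link GLM fitted to dollar costs; the log-likelihood uses
  the continuous extension `log Gamma(y+1)` of the factorial, the only
  extension consistent with the GLM deviance, and coincides with the
  textbook fit on integer outcomes.

## Marginal effects

The marginal effect of covariate `j` is the derivative of the model's mean
function at the covariate means: `b_j exp(xbar'b)` (log links), `b_j
p(1-p)` (logistic), `b_j Phi(xbar'b/sigma)` (Tobit censored-mean estimand;
the latent-mean alternative `b_j` is available).  Dummy covariates are
differentiated like continuous ones so that a single derivative-style
column is reported per model.  Standard errors propagate the full parameter
covariance (including `sigma`, `q` where the mean depends on them) through
a numerical Jacobian of the effect vector (delta method).  Two-part models
report their parts separately.

## Model comparison

AIC (each model's own exact likelihood; two-part combined) measures fit of
the whole distribution; 5-fold cross-validated RMSE of `E[y|x]` measures
prediction.  Folds are formed by shuffling row indices with the run seed
(no stratification, but the split is redrawn if a training fold would lose
an outcome class entirely).  Neither metric compares across datasets, so
replicated studies are summarized by rank values: per dataset the best of
the five models gets rank 1 and the worst rank 5 (ties, a measure-zero
event, broken by model name), and ranks are summed over replicates.  Mean
absolute error is implemented but not ranked.

Diagnostics: `mean_variance_bins` groups observations into 5%-quantile bins
of fitted mean and returns each bin's sample mean and variance of the
outcome (the log–log slope across bins estimates the variance power); and
`model_quantiles` simulates the fitted model over resampled covariate rows
to compare model-implied quantiles with observed ones (Q-Q), conventionally
dropping the outlier-dominated last percentile.

## The synthetic-data generator

The Monte Carlo design generates positive costs from a Gamma GLM with log
link: three covariates drawn from U(2,8), U(-10,1), U(-2,0), slopes (no
intercept) from U(-2,1), and `Y ~ Gamma(shape = exp(x'b)^2/theta, rate =
exp(x'b)/theta)` with `theta = 30`, giving conditional mean `exp(x'b)` and
constant conditional variance `theta`.  Zeros are injected either by
replacing a random subset of rows with non-users whose covariates are
redrawn from U(3,6), U(-2,3), U(-1,1) (*low correlation* between users and
non-users), or by zeroing the rows with the lowest generated costs,
leaving covariates untouched (*high correlation*).  Zero proportions span
0.05–0.7; the reference design is 100 replicates of N=5000.

Two generator decisions were genuinely open and are resolved as follows.
First, the linear predictor has no intercept (only the three slopes are
specified) while the *fitted* models do include one — mild, realistic
misspecification.  Second, slope draws can produce degenerate cost scales:
`exp(x'b)` overflows beyond `|x'b| > 15`, and per-observation Gamma shapes
`exp(2 x'b)/theta` below about 0.5 make draws underflow to exact zeros in
double precision (at shape 6e-4 more than half of all draws collapse to 0),
which would silently corrupt the zero-injection bookkeeping and the
user/non-user labels.  The generator therefore redraws the slope vector
until `max x'b <= 15` and `min shape >= 0.5` (typically a few dozen
redraws; the count is reported).  This conditioning is the package's own
resolution of an under-determined design point; it implies every simulated
dataset has conditional mean costs of at least a few dollars.

What the generator does *not* emulate about real cost data: covariate
dependence between users and non-users beyond the two stylized mechanisms,
measurement error, heavy-tailed per-event costs beyond the Gamma, repeated
measurement within individuals, and any causal structure.  Passing the
simulation tests therefore shows correct behaviour *under the stated
design*, not validity on any particular real dataset.

## Study sizes used in the automated checks

The automated suite runs the comparison study at a scaled size — 20
replicates of n=2000 per setting (and the acceptance script at 10
replicates of n=1500) — chosen so the full suite completes comfortably on a
single CPU; the full reference design (100 x 5000 across seven zero
proportions and both scenarios) is available through the CLI (see README)
and takes a few hours on one core.  Rank-sum comparisons are stable at the
scaled size for the orderings the tests assert, but individual rank sums
move by a few units across seeds.

## Numerical choices and degenerate inputs

* Exact zeros in the outcome are detected by equality; costs are never
  rounded or log-transformed on input.
* All-zero outcomes are rejected (no positive support to fit); all-positive
  outcomes are legal everywhere except the logistic part, which requires
  both classes and names the missing one.
* Rank-deficient design matrices are rejected up front.
* `cross_validated_rmse` re-raises any model failure naming the fold;
  the study driver logs failed replicates, excludes them from ranking, and
  aborts if more than 20% fail.
* Hessian-based covariances (Tobit, generalized Gamma) fall back to a
  pseudo-inverse with a metadata flag when the observed information is not
  positive definite at the optimum.

## Known limitations

* Power parameters outside (1, 2) (Normal, Poisson, inverse-Gaussian
  members, and the `p > 2` heavy-tail range) are out of scope; only the log
  link is supported for the Tweedie mean, as alternative links are
  numerically fragile in this likelihood.
* The generalized Gamma is restricted to `q > 0` (plus the near-log-normal
  boundary); the `q < 0` branch has no finite mean for `sigma >= 1/|q|`
  and is not needed to nest the Gamma/Weibull/log-normal cases used here.
* AIC comparisons across software depend on likelihood constants and on
  whether auxiliary parameters are counted; both conventions are stated
  above and configurable where relevant.
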