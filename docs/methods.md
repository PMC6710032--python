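# Methods

## The optimizer

The swarm minimizes an objective f over a rectangular region
R = ∏_d [lo_d, up_d]. Initialization draws positions uniformly over R and
velocities uniformly over (−|up−lo|, |up−lo|) componentwise. Each
iteration updates, for every particle i,

    v_i ← ω v_i + φ_p r_p (p_i − x_i) + φ_g r_g (g − x_i)
    x_i ← x_i + v_i

where p_i is the particle's best-known position, g the swarm's, and
(r_p, r_g) a fresh pair of U(0,1) draws. The box constraint is enforced by
elimination: a particle whose updated position has any coordinate outside
R is replaced by a fresh uniform draw of the full position vector; its
velocity is kept. This keeps every function evaluation feasible and
continually reseeds the box, which resists collapse of the whole swarm
into one local basin — the property the Monte Carlo study exercises.

Design choices that the update leaves open:

* **Acceleration draws.** One scalar pair (r_p, r_g) per particle per
  iteration, shared across dimensions (the algorithm-listing convention;
  the alternative of one pair per dimension changes nothing qualitative).
* **Coefficients.** ω = 0.5, φ_p = φ_g = 1.5 by default — inside the
  standard convergence region ω < 1, φ_p + φ_g < 4(1+ω)/2. All three are
  exposed on `PSOConfig`.
* **Ties.** The global best is replaced only on strict improvement, so
  ties resolve to the earliest-encountered, lowest-index particle.
* **Non-finite objectives.** A particle whose objective evaluates
  non-finite (including the +∞ an infeasible likelihood returns) is
  redrawn, up to 100 rounds; persistent failure raises.

**Stopping.** The run ends when at least N iterations (`min_iterations`,
default 500) have completed *and* the sample variance (n−1 denominator) of
the last ⌈prop · iterations⌉ global-best values is ≤ e (`stop_variance`,
default 1e-4); `prop` defaults to 0.2 and the window is taken over
iterations-so-far, not over N. A window of length 1 counts as zero
variance. Because the update alone guarantees no termination, a hard cap
`max_iterations` (default 50 N) returns the best-so-far with
`converged=False`.

**Reproducibility.** One seedable numpy Generator drives a whole run.
Monte Carlo replicates derive child seeds from the master seed through
`SeedSequence.spawn`, so the result multiset is independent of the worker
count (replicates are joblib-parallel but order-preserving).

## Distributions and likelihood

A `DistributionSpec` is a pdf/cdf pair with an open support interval
(default (0, ∞)) and an optional parameter box. Two families are built in,
with parameter orders chosen so reported vectors align with the family
definitions used throughout:

* exponentiated Weibull, parameters (α, β, a), cdf {1 − e^−(αx)^β}^a on
  (0, ∞), closed-form quantile (1/α)[−ln(1 − u^{1/a})]^{1/β};
* Kumaraswamy-beta, parameters (β, a, α, b), cdf 1 − {1 − I_x(α, β)^a}^b on
  (0, 1), with I_x the regularized incomplete beta function.

The Kumaraswamy-beta density is evaluated in log space. Near the upper
support endpoint the factor 1 − G^a (G the beta cdf) is a 0·∞
indeterminate in direct arithmetic; it is computed as −expm1(a · log G)
away from G = 1 and as a · sf(x) (via `logsf`) when a · log G is within
1e-8 of zero. This matters: at the largest flood observation the beta cdf
sits within machine epsilon of 1, and naive evaluation there loses ~7e-5
of log-likelihood — enough to shift information criteria in their fourth
decimal.

The negative log-likelihood is −Σ log f(x_i; θ); any parameter vector
giving a non-positive or non-finite density returns +∞, which the swarm
treats as "resample" and local optimizers as a barrier. Data outside the
declared support abort the fit with the offending index — points are never
silently dropped.

Sampling inverts the cdf: closed form where a quantile is declared,
bracketed Brent root-finding otherwise. `validate_spec` checks a supplied
pair is a genuine distribution (quadrature of the pdf to 1 within 1e-3,
cdf monotonicity and limits, numeric cdf-derivative against the pdf) and
reports messages rather than raising.

## Fitting and the adequacy report

`LifetimeModel(data, dist).fit(...)` minimizes −log L and assembles a
`LifetimeFitResults`. Methods: the swarm (default; requires an explicit
parameter box — no silent default box is invented), or
BFGS / Nelder-Mead / CG via `scipy.optimize.minimize` with library-default
settings, and SANN via basinhopping with Nelder-Mead inner steps (a
stochastic global analogue of a simulated annealer). Single-letter aliases
P/B/N/S/C are accepted. A known MLE can be supplied to bypass optimization
entirely. A local fit never reports a point worse than its starting
values; the convergence flag follows the optimizer's own criterion.

The probability transform for W\*/A\*: v_i = F(x_(i); θ̂) at the sorted
data, clamped to [1e-10, 1−1e-10] with a warning if the fitted cdf reaches
0 or 1 exactly; y_i = Φ⁻¹(v_i); u_i = Φ((y_i − ȳ)/s_y) with the n−1
standard deviation. n ≥ 2 is required, and a degenerate transform
(s_y = 0) raises. W², A² and the small-sample corrections follow the
formulas in the README.

The CAIC and HQIC penalty forms (2k(k+1)/(n−k−1) on top of AIC;
2k ln ln n) reproduce both reference output blocks exactly and fix CAIC's
domain to n > k+1 (NaN with a warning otherwise).

The KS test is the two-sided one-sample test against the fitted cdf
(scipy's exact small-sample p-value where valid; asymptotic with a warning
under ties). Because the cdf's parameters are estimated from the same
data, the p-value is anti-conservative; it is reported as-is, as is
conventional for this report, and should be read as descriptive.

Standard errors are sqrt of the diagonal of the inverse central-difference
Hessian of −log L at the estimate, with per-parameter step
max(1e-5, 1e-4·|θ_j|). Components whose inverse-Hessian diagonal is not
positive come back NaN with a warning. After a swarm fit the errors are
omitted by default (the swarm carries no curvature information); they can
be requested via `compute_se=True`.

### A caution on ridge likelihoods

The flood-level example is deliberately hard: the four-parameter
Kumaraswamy-beta likelihood for that sample has no interior maximum — it
rises along a flat ridge on which (β, a) grow without bound while the
fitted cdf barely changes. Where a quasi-Newton method stops on such a
ridge is an artifact of its gradient steps and line search, not a property
of the data: different well-regarded implementations stop at visibly
different "MLEs" with likelihood differences of 1e-3 and parameter
differences of tens of percent, and the observed-information standard
errors there are numerically indefinite. The package reports whatever the
chosen optimizer returns, flags non-convergence, and leaves the judgement
to the adequacy statistics — which are nearly invariant along the ridge.
This is precisely the situation the box-constrained swarm is for: bounding
the search region regularizes the problem, at the cost of making the
reported optimum a constrained one.

## TTT transform

T(i/n) = [Σ_{k≤i} X_(k) + (n−i) X_(i)] / Σ X_(k) on the order statistics,
with (0, 0) prepended; requires n ≥ 2 strictly positive values, ties
allowed. The curve is exactly scale invariant and non-decreasing for
positive samples. Shape classification (convex/concave/bathtub) is a
visual judgement; `concavity_summary()` emits only the sign pattern of
second differences, labelled heuristic.

## Synthetic data and what the tests show

Test lifetimes come from inverse-cdf sampling of the built-in families.
The parameter-recovery study uses exponentiated Weibull samples at
(α, β, a) = (0.5, 2, 1.5) with n = 500 — a well-identified, moderately
skewed lifetime configuration — fitted by the swarm over the box
(0.001, 10)³ with 50 particles and at least 100 iterations, 50 seeds. Under
those conditions each parameter's median absolute relative error stays
below 15% and ±2·SE intervals cover the truth for ≥ 80% of seeds. The
null-calibration check simulates from the hypothesized model with known
parameters, so it exercises the probability transform and the corrected
statistics but not estimation noise in θ̂. Synthetic draws are i.i.d. and
uncensored; real lifetime data with censoring, ties from coarse
measurement, or covariate structure are outside what these tests
demonstrate.

The Monte Carlo study runs 200 swarm replicates per objective (S = 150,
e = 1e-4, N = 50, prop = 0.1) — a desk-scale problem size chosen so the
study completes in seconds while still populating all four Himmelblau
basins and reaching Rastrigin values below 1 in ≥ 70% of replicates.

## Known limitations

* Censored data, covariates and bootstrap standard errors are out of
  scope; hazard-shape classification is not automated.
* KS p-values with estimated parameters are anti-conservative (above).
* Only global-best swarm topology and box constraints are implemented;
  maximization is done by negating the objective.
* On unbounded or ridge-shaped likelihoods the local methods' stopping
  points are implementation artifacts (see the caution above); prefer the
  swarm with a scientifically motivated parameter box.
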