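# Methods

## Model

A two-arm randomized trial records K correlated binary outcomes per
subject (success = 1). The joint response of subject *i* is one of
Q = 2^K configurations, enumerated as the rows of the configuration
matrix **H** in strictly descending binary order; the all-failure row Q
is the reference category. Category probabilities follow a multinomial
logistic model

φ_iq(x_i) = exp(ψ_iq) / (Σ_{r<Q} exp(ψ_ir) + 1),  ψ_iq = x_i'β_q,  β_Q ≡ 0,

with design vector x_i containing an intercept, the treatment indicator
T_i, covariates, and treatment-covariate interactions. Because the model
is saturated over joint configurations at any fixed covariate value, the
outcome correlation structure is free to differ between subpopulations —
the property that distinguishes it from multivariate logit models with a
shared dependence parameter.

Priors are independent normals per non-reference category,
β_q ~ N(b_0q, B_0q), default b_0q = 0 and B_0q = diag(10): weakly
informative on the log-odds scale, enough to regularize separable data
without influencing well-identified fits.

## Posterior sampling

Each β_q is conditionally conjugate after Pólya-Gamma augmentation. Per
sweep and per category q = 1..Q−1 the sampler computes the per-subject
log-sum offset C_iq = log Σ_{r≠q} exp(ψ_ir) (reference included as
exp(0)), draws ω_iq ~ PG(1, ψ_iq − C_iq), sets κ_iq = I(c_i = q) − 1/2,
and updates β_q from the multivariate normal with precision
X'Ω_q X + B_0q^{-1} and matching mean with working response
κ_iq + ω_iq C_iq. Chains start at β = 0 (overdispersed prior draws
optional); PSRF diagnostics guard against under-dispersed starts.

PG(1, z) variables are drawn exactly with a Devroye-type alternating-
series rejection sampler (truncated-exponential / truncated-inverse-
Gaussian proposal mixture around the crossover point 0.64), compiled
with numba; there is no truncated-sum approximation, so augmented draws
carry no systematic bias into the error-rate studies. The sampler is
validated in the test suite against the exact identities
E[PG(1,z)] = tanh(z/2)/(2z) and the matching variance formula.

Linear predictors are clipped at ±30 before exponentiation — beyond that
point the probabilities are 1 within double precision and the clip only
prevents overflow in degenerate (e.g. separable) configurations.

Convergence: per-parameter potential scale reduction factors use the
classic between/within-chain variance ratio; the multivariate statistic
is the Brooks–Gelman largest generalized eigenvalue form, reported on
the sqrt scale with the (p+1)/p between-chain factor used by the common
R implementation so that values are comparable to the customary ≤ 1.10
rule of thumb.

## Transformation chain

Every retained draw (never a posterior summary) is pushed through:
ψ → φ (inverse multinomial logit, max-subtraction stabilized);
φ → θ, θ_k = Σ_{q∈U_k} φ_q over the 2^(K−1) configurations with outcome
k = 1 (this sum preserves the correlation encoded in φ); per-arm
θ → δ = θ_1 − θ_0; optionally δ_w = Σ w_k δ_k with simplex weights.
Point summaries are posterior means and central 95% quantile intervals
(deterministic, unlike HPD intervals, which are not needed for the
decision procedure).

## Populations

Fixed-value subpopulations plug a covariate profile into each draw for
both counterfactual arms (T forced to 0 and 1, interactions recomputed).
Interval subpopulations use empirical marginalization: per draw, φ is
evaluated at each selected subject's covariates under both counterfactual
arms and averaged within arm. Subjects from both randomized arms enter
both counterfactual averages — randomization makes the pooled covariate
sample representative, and restricting to the subject's own arm would
only add noise. Interval endpoints are closed. Fixed values outside the
observed covariate range are allowed with an extrapolation warning.
The posterior itself is always fit on all subjects; only covariate rows
are subset, which is why the regression approach outperforms stratified
analysis when strata are small.

## Decision procedure

Rules on the K-variate difference δ: Any (at least one endpoint better),
All (every endpoint better), Compensatory (weighted sum better).
Thresholds for a target type-I rate α: p_cut = 1 − α (All,
Compensatory), 1 − α/K (Any, Bonferroni-corrected); two-sided tests
halve α. Strict inequalities at region boundaries.

The operative statistic compared against p_cut is the Compensatory
region probability P(δ_w > 0 | y), and for Any/All the *endpoint-wise*
posterior probabilities max_k / min_k P(δ_k > 0 | y). This is a
deliberate design choice: the endpoint-wise form is the exact Bayesian
analog of the Bonferroni (Any) and intersection-union (All) tests whose
multivariate-normal power approximations drive the sample-size
procedure, and it is the form under which the corrected thresholds
deliver the target type-I rate. The joint probability of the union
region {max_k δ_k > 0} is *not* α-calibrated: under a two-endpoint
independent null, comparing it with 1 − α/K rejects with probability
≈ (α/2)(1 − ln(α/2)) ≈ 0.117 at α = 0.05. Both joint-region
probabilities remain available (`region_membership`,
`posterior_region_prob`) for reporting; for the Any rule a two-sided
test can in principle trigger both directions, which is reported as a
flagged double trigger rather than suppressed.

When outcomes are coded as failures (lower is better), callers select a
left-sided test instead of recoding data.

## Sample sizes

Any/All: power is a K-variate normal rectangle probability with the
user-supplied outcome correlation matrix as the correlation of the
endpoint-wise statistics; c_k combines the rule-specific normal quantile
with the effect over its pooled binomial standard error. The Any-rule
rectangle is the probability that *no* endpoint rejects, so power is its
complement (the sign convention consistent with the K = 1 collapse to
the standard two-proportion formula, confirmed by Monte-Carlo). The
minimal integer n is found by geometric bracketing plus binary search,
equivalent to unit stepping (asserted by test). MVN rectangles use
scipy's algorithm with absolute tolerance 1e−8 and a fixed internal
seed, so returned n is reproducible.

Compensatory: the closed two-proportion form on the weighted margins
θ_Tw = Σ w_k θ_Tk, with ceil rounding. Known property: treating w·y as
a Bernoulli variable overstates its variance (θ_w(1−θ_w) ≥ w'Σw, with
equality only under perfectly positively correlated outcomes), so the
returned n is conservative for interior weights — at w = (0.75, 0.25),
ρ = 0.2 the realized power at the computed n is ≈ 0.9 rather than 0.80.
The formula is kept in its standard form; the test suite asserts the
conservative direction rather than exact calibration.

## Synthetic-data generator

A DGM specifies, per arm and per anchor covariate value (z ∈ {0, 1}
binary, z ∈ {−1, +1} continuous), the marginal success probabilities θ
and a common pairwise outcome correlation ρ ∈ {−0.2, 0, +0.2} by
default. Margins are converted to joint cells with the bivariate-
Bernoulli identity φ_11 = θ_1θ_2 + ρ√(θ_1(1−θ_1)θ_2(1−θ_2)) (for K = 3
the pairwise cells are fixed the same way and the triple-success cell
sits at the midpoint of its feasibility interval — any point in that
interval matches the pairwise specification). Infeasible (θ, ρ)
combinations raise an error naming the violated cell. The four (T,
anchor) cells are then inverted exactly through the model
ψ_q = β_0q + β_Tq T + β_1q z + β_2q zT (a 4×4 linear solve per
category; round-trip exact to 1e−10), covariates are drawn
Bernoulli(0.5) or standard normal, and responses are multinomial with
the implied φ_i(x_i).

Ground truth in the manifest: conditional effects at the anchors are
closed-form; the average effect is the exact 0.5/0.5 φ-mixture for the
binary covariate and a 128-node Gauss–Hermite quadrature over the
standard-normal law for the continuous one (interval effects use
Gauss–Legendre against the truncated normal). Quadrature rather than
Monte-Carlo keeps manifests deterministic; the test suite confirms the
manifest against empirical frequencies from 10^6 generated subjects.

Effect-size presets (control margins at 0.5; conditional differences at
the low/high anchors):

* ES1 — null everywhere: δ_lo = δ_hi = (0, 0).
* ES2 — heterogeneous, null average: δ_lo = (−0.20, −0.10),
  δ_hi = (+0.20, +0.10).
* ES3 — positive average, low-anchor conditional effect larger:
  δ_lo = (0.30, 0.15), δ_hi = (0.10, 0.05).
* ES4 — positive average, low-anchor conditional effect smaller:
  δ_lo = (0.10, 0.05), δ_hi = (0.30, 0.15).

These are package defaults chosen to reproduce the qualitative regimes
(null; cancelling heterogeneity; CATE above/below the average effect)
at magnitudes typical of trial simulation studies; any cell can be
overridden through `CellSpec`.

What the generator does *not* emulate: real trials have covariate
measurement error, missing outcomes, non-logistic dose-response shapes
and more than one covariate. Passing operating-characteristic tests
therefore demonstrates calibration *when the model class contains the
truth*, not robustness to misspecification.

## Reference estimators

Stratified multivariate Bernoulli–Dirichlet ("mB"): per arm, joint-
category counts plus a near-Haldane Dirichlet(0.01) prior give the φ
posterior directly; subpopulation effects discard out-of-stratum rows.
Univariate logistic ("uLR"): one binary PG fit per outcome (prior
N(0, 10)); per-outcome δ_k draws are paired by draw index into joint
draws, deliberately encoding the independence assumption whose cost the
comparison measures. Its draw count matches the multivariate fit's for
comparability.

## Simulation harness

`run_scenario` executes seeded repetitions of one DGM × method ×
(population, rule) grid cell and tabulates superiority proportions with
binomial standard errors, per-endpoint and weighted bias against the
manifest truth, and PSRF summaries. Per-repetition seeds are spawned
from the master seed with `SeedSequence.spawn`, so entire grids are
reproducible bit-for-bit. Individual repetition failures are logged and
tolerated up to 1% of the run. Production MCMC defaults are 2 chains ×
10,000 iterations after 1,000 burn-in; the packaged studies use reduced
lengths (see below).

## Problem sizes used in the packaged studies

The repetition studies shipped in the test suite and the acceptance
script run at desk scale, chosen so that Monte-Carlo error is small
relative to each tolerance: null type-I studies use the Dirichlet
estimator at 2,000 repetitions and n = 1,000/arm; power studies 1,000 to
2,000 repetitions at the a priori n; bias studies 100 to 250 repetitions
of multivariate fits (500 iterations after 150 burn-in, single chain) at
n = 1,000/arm; convergence checks 20 two-chain fits at 1,250 iterations;
null-CATE method comparisons 500 repetitions per regression estimator
(750 iterations after 250 burn-in) at n = 400/arm. Binomial MC standard
error at 2,000 repetitions and p = 0.05 is 0.005; at 500 repetitions and
p = 0.8 it is 0.018.

## Known limitations

* Joint-cell construction supports K ≤ 3 in the generator (the model
  and sampler themselves handle K up to 10).
* Only one covariate per DGM; the analysis model accepts several.
* The Compensatory sample-size form is conservative for interior
  weights (see above).
* Empirical marginalization inherits sampling variability from the
  covariate rows it averages over; very narrow intervals can rest on
  few subjects (the effect object reports how many).
* No interim analyses, non-inferiority margins, Bayes factors, or
  model-fit diagnostics beyond MCMC convergence.
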