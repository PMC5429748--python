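# Methods

## The acquisition model

A trial exposes a flock to two hidden food patches. Two *informed*
birds (demonstrators) know how to find such patches from the start;
the remaining naive birds discover each patch at some latency, or never
(censored at the trial horizon, 30420 s). For naive bird *i* at patch
*p* the discovery hazard is multiplicative in an asocial and a social
part:

    lambda_i(t) = lambda0_p(t) * exp(beta' x_i + u_f(i) + v_i) * (1 + s_p * T_i(t)),
    T_i(t) = sum_j a_ij * w_j * z_j(t).

- `a_ij` — following rate of *i* toward *j* (followings/hour) from the
  pre-training following network. The exposure uses *i*'s out-edges:
  attraction operates through the observer's tendency to follow the
  informed bird. The transposed orientation is available
  (`orientation="transpose"` in `build_oada_data`) since the direction
  is a modelling choice, not an observable.
- `w_j` in (0, 1] — transmission weight: *j*'s total feeder visits
  scaled to the flock maximum, a proxy for how often *j* performs the
  trait once informed. Weights scale the demonstrating side only; they
  do not modify a bird's own asocial rate (that is what the
  `feeding_activity` covariate is for).
- `z_j(t)` — informed status: 1 for demonstrators from t = 0 and for
  naive birds after their own discovery.
- `s_p >= 0` — social-transmission parameter of patch *p*, in units of
  (followings/hour)^-1: `s_p * a_ij * w_j` is the hazard multiplier
  contributed by one informed flock-mate. `s` and the network scale are
  only jointly identified; multiplying all edges by `c` divides `s` by
  `c` and leaves the likelihood unchanged.
- Covariates: sex (male = 1), age (years), feeding activity (z-scored
  total visits; the partial likelihood is invariant to shifts, the
  z-scale keeps the coefficient O(1)).
- `u_f ~ N(0, sigma2_flock)`, `v_i ~ N(0, sigma2_ind)` — "individual
  nested in flock" log-normal frailties.

## Order-only partial likelihood, pooling and stratification

Only the *order* of acquisitions enters the likelihood: at each event
the probability that the observed bird is the acquirer is
`lambda_i / sum_r lambda_r` over the risk set, so `lambda0_p` cancels
and any time-varying baseline shape is irrelevant (verified by the
baseline-invariance tests: strictly monotone latency transforms leave
the likelihood and all estimates unchanged).

The per-flock diffusions are combined into one dataset. By default the
strata are the two patch ranks, with flocks *pooled*: events across
flocks are merged in latency order and risk sets span every still-naive
bird of the stratum. Because all flocks share the same trial clock and
the same within-patch baseline, the merged next-event probabilities are
exactly the competing-exponentials probabilities, so pooling is valid
and uses cross-flock ordering information; flock heterogeneity belongs
to the flock frailty. `pooling="stratify_flock_by_patch"` gives the
fully stratified alternative (each flock x patch its own baseline),
which is always valid but discards cross-flock information. Cross-flock
latency ties are broken by (flock id, bird id); within a flock the
generator produces strictly increasing latencies and real data ties are
rejected at validation.

Censored birds carry the horizon and remain in every risk set of their
stratum; demonstrators never enter risk sets. A patch never exploited
yields a diffusion with zero events and all-naive censoring.

## Random effects

Frailties are integrated out by a Laplace approximation: an inner
Newton step maximizes the penalized partial log-likelihood in
(u, v) (the information matrix of a multinomial-logit event model plus
the Gaussian precision), and the marginal adds the usual
`-1/2 log det(Sigma) - 1/2 log det(H_pen)` correction. This is the
penalized-partial-likelihood scheme of mixed-effect proportional-hazards
fitting, and it is an approximation. With variances at zero it reduces
exactly to the fixed-effects OADA (tested to 1e-5 at a variance floor of
e^-16). Variances are optimized on the log scale within [e-12, e6];
estimates at the lower bound are effectively zero.

## Optimization, boundaries and intervals

`s` is maximized on its natural scale under a box constraint `s >= 0`
(L-BFGS-B with analytic gradients in the fixed-effects case), with a
deterministic three-point multistart (s0 = 0.1, 1, 5) against local
optima; `beta` is unconstrained. Estimates below 1e-6 are flagged
"constrained to 0". Profile 95% confidence intervals invert
`2 * (logL_max - logL_profile) = 3.8415`, re-optimizing all other
parameters, with Brent root-finding after geometric bracket expansion;
for `s` the lower bound is clipped at 0 (reported as exactly 0 when the
profile never drops before the boundary) and a side where the profile
never drops within the search range is returned open-ended (infinite) —
small weakly informative datasets do produce such intervals. Tolerances:
1e-12 relative on the objective, 1e-6 on interval bounds.

AICc bookkeeping: `k` = free `s` parameters + number of covariates +
estimated variance components; `n` = total acquisition events. Both are
conventions (other counts are defensible); `n` can be overridden via
`fit_oada(..., aicc_n=...)`. Akaike weights are normalized over
converged models only; non-converged fits are excluded from ranking and
kept separately. Asocial models are network-free, so one asocial fit is
shared per covariate subset and its support is reported separately from
the two network types.

## Permutation statistics

The three Monte-Carlo tests mirror "approximative" resampling tests: a
linear rank statistic, B random within-stratum rearrangements (default
19999), `Z = (T - mean T*) / sd T*` standardized by the resample
distribution (not an asymptotic formula), and the add-one estimate
`p = (b + 1)/(B + 1)`, which is a valid p-value for any B and gives
`p >= 1/(B + 1)`. Two-sidedness compares `|T - mean T*|` because the
stratified rank-sum statistics are not centered at zero. Ranks are
computed within strata with mid-ranks for ties; the signed-rank test
uses the Pratt convention (zeros ranked, then dropped). Exhaustive
enumeration replaces sampling on request for small instances. The
binomial test is the exact minimum-likelihood two-sided version: the sum
of point probabilities not exceeding the observed one within a 1e-7
relative tolerance; the first-feeder null defaults to
informed-per-flock / flock-size = 0.2.

## The synthetic generator

The generator emulates the reference study design: 10 flocks x 10 adult
birds (5 males, 5 females), 2 informed per flock (one of each sex), a
two-day (20 h) pre-training period at a central feeder, two hidden
patches, censoring at 30420 s.

Pre-training behaviour: each bird initiates feeder visits as a Poisson
process (mean 6/h, Gamma(1.2)-heterogeneous across birds); at each
initiation every other bird follows within (0, 5) s with probability
0.9 x (own sociability) x (pairwise preference), capped at 0.95, or
arrives independently 5-30 s later with probability 0.12; 3% of
initiations are exact-tie group arrivals with no initiator. Pairwise
preferences are Gamma(0.12)-distributed, concentrating each bird's
following on a few flock-mates. These rates were calibrated once
against the reference study's descriptive statistics — mean number of
discoverers per patch (~7.5/8 naive at the socially transmitted patch,
~4/8 at the other) and the published out-strength distribution
(≈ 8 ± 7.5 followings/h; the generator achieves 6.8 ± 5.1, the upper
tail being limited by the per-event probability cap). Without the
pairwise-preference structure the networks are near-uniform, which
contradicts the observed strength dispersion and leaves `s` so weakly
identified that its MLE is badly skewed.

Arrival clusters are spaced (>= 40 s between initiations, independent
arrivals > 5 s apart) so the 5-s windowing rule recovers the planted
follower pairs *exactly*; the planted events and visit counts are
returned as ground truth and tested against the detector.

Diffusions are simulated sequentially from the model itself (waiting
time exponential in the summed hazard, acquirer categorical), using the
*detected* following network and the realized transmission weights, so
the estimation target and the generative truth coincide. Baseline
hazards are constant (2.0e-5 and 2.2e-5 per bird per second); constant
baselines cannot reproduce both the observed discovery *times* and
discoverer *counts* of real trials (whose baselines evidently rose over
the day), and the counts were chosen because OADA only uses the order.
Patch labels carry the generative truth (patch 1 = the transmitting
patch); `assign_patch_strata` implements first-feeding-latency ranking
for observational latency tables.

What the generator does not emulate: spatial movement, aggression and
seed depletion, time-varying sociability, observation error in bird
identity, and informed birds feeding first (demonstrators never appear
as acquirers, so the first-feeder binomial test on synthetic data
always sees zero informed first-feeders). Passing tests therefore
establish correctness of the inference machinery under the model, not
robustness to these real-data features.

## Problem sizes used in tests and the acceptance script

Parameter recovery runs 200 replicate studies at the reference
conditions (s = (1.5, 0), beta_sex = 0.4, no frailty) in the test
suite and 80 in the acceptance script, each with a reduced model grid
(sex-only covariate set, 9 models); type-I error uses 1000 (tests) or
400 (script) null simulations with B = 199 resamples. These sizes give
Monte-Carlo standard errors comfortably inside the asserted bands while
keeping a full run in minutes on one CPU.

## Known limitations

- The Laplace frailty approximation is untested against an exact
  integrator at large variances; variance estimates are known to be
  harder to recover than fixed effects in partial-likelihood models.
- `s` estimates are right-skewed at small information; report the
  profile interval, not the point estimate alone.
- The support-ratio arithmetic treats non-converged fits as absent;
  with many non-convergences the support percentages would be
  conditional on convergence.
- Exhaustive permutation modes enumerate naively and are only meant for
  instances with at most a few hundred rearrangements.
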