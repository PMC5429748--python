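# flocknbda

Network-based diffusion analysis (NBDA) for multi-patch foraging
experiments in bird flocks, in the order-of-acquisition (OADA) variant.

The package answers the question an experiment with captive flocks of
house sparrows poses: when two hidden food patches become available and
a couple of flock-mates already know how to find such patches, does the
order in which naive birds first feed follow their *social connections*
— who habitually follows whom to a feeder — or only their individual
characteristics?

## The model

Each naive bird *i* discovers a patch with hazard

```
lambda_i(t) = lambda0_patch(t) * exp(beta' x_i + u_flock + v_i) * (1 + s_patch * T_i(t))
T_i(t)      = sum_j a_ij * w_j * z_j(t)
```

where `a_ij` is the rate (followings/hour) at which *i* follows *j* in a
directed weighted following network measured in an independent context,
`w_j` is *j*'s transmission weight (feeder visits scaled to the flock
maximum), `z_j` indicates that *j* is informed (a trained demonstrator
from *t* = 0, or a bird that already discovered the patch), `s_patch` is
the social-transmission parameter of the patch, `x_i` are covariates
(sex, age, feeding activity) and `u, v` are flock- and individual-level
random effects. Fitting uses the Cox-type partial likelihood on the
*order* of acquisition only (so the baseline `lambda0` cancels — OADA is
insensitive to its shape), with the per-flock diffusions combined into
one dataset and stratified by patch so each patch keeps its own
baseline. Five scenarios map `s` onto the two patches (none, shared,
separate, patch-1 only, patch-2 only); crossed with covariate subsets
and network type (observed following network vs homogeneous
all-connections-equal) they form a 72-model grid ranked by AICc and
Akaike weights. Around the core model the package provides:

- a synthetic-data generator with known parameters (rosters, feeder
  arrival logs with planted following events, two-patch diffusions);
- following-event detection (arrival within 5 s of an initiator),
  network construction, in-/out-strength, transmission weights;
- profile-likelihood confidence intervals (`s >= 0` boundary handled
  exactly) and likelihood-ratio tests against asocial models;
- Monte-Carlo ("approximative") stratified permutation tests
  (Wilcoxon-Pratt signed-rank, Mann-Whitney, Spearman; default
  B = 19999) and the exact minimum-likelihood binomial test.

## Worked example

```python
import flocknbda as fn
from flocknbda.oada import ModelSpec, build_oada_data

ds = fn.generate_dataset(fn.SyntheticScenario(beta_true={"sex": 0.4}, seed=1))
data = build_oada_data(ds.diffusions, ds.networks, ds.roster)
spec = ModelSpec(scenario="s_patch1_only", covariates=("sex",))
fit = fn.fit_oada(spec, data)
print(fit.summary())
print(fn.profile_ci(spec, data, fit, "s1"))
```

prints (seed 1):

```
logL=-423.453, AICc=851.01, s1=1.387, s2=0, beta[sex]=0.4339
(0.568..., 3.553...)
```

The data were simulated with `s1 = 1.5` (each following/hour toward an
informed bird multiplies the discovery rate by `1 + 1.5 * w`), `s2 = 0`
and a male discovery advantage of `exp(0.4)`; the fit recovers all
three: `s1 = 1.39` with 95% profile CI [0.57, 3.55] covering the truth,
`s2` structurally zero, and `beta_sex = 0.43`. A likelihood-ratio test
against the matching asocial model on the same data gives
`chi2_1 = 36.35, p = 1.7e-09`: the acquisition order tracks the
following network. See `examples/` for network construction, the AICc
model grid with category support, and the permutation statistics.

A thin CLI wraps the pipeline end to end:
`flocknbda run --out out/ --seed 1` (also `simulate`, `networks`,
`select`, `stats`).

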