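# Methods

## Model

The observable unit is a twin family: zygosity (MZ/DZ) and two twins'
ordinal responses to I items with K ordered categories. Writing `theta_j`
for the latent trait of individual *j*:

* **Measurement.** GPCM: category `k` (0-based) of item *i* has
  unnormalised log-weight `alpha_i (k theta_j - B_ik)`, `B_ik` the
  cumulative sum of thresholds with a structural first threshold of 0.
  PCM fixes `alpha_i = 1`; GRM (cumulative logit, strictly ordered
  cutpoints) is available in the stand-alone psychometric stage.
* **Biometric decomposition.** `theta = A + C + D + E`. A is one draw per
  MZ family; for DZ families `A = sqrt(sigma2_A/2) (z_family + z_twin)`,
  which induces the additive-genetic correlation of exactly 0.5. C (ACE) is
  family-shared; D (ADE) shares a quarter of its variance within DZ pairs.
* **Interaction (AxE/GxE).** `Var(E_j | g_j) = exp(beta0 + beta1 g_j)` with
  `g = A` (AE/ACE) or `g = A + D` (ADE). The exponential keeps the variance
  positive; `beta1` is a log-linear interaction slope whose sign gives the
  direction of the effect.
* **Identification.** Latent mean 0, first threshold of every item 0. With
  free discriminations *and* free variance components the scale is not
  identified by those two constraints alone. The sampler anchors the first
  item's discrimination at 1 as its working representative, but the joint
  posterior retains a weakly identified scale direction through that single
  anchor item (`theta * c`, `alpha / c`, variances `* c^2` nearly preserve
  the likelihood), whose slow drift and right skew would otherwise leak
  into the variance components at desk-scale cohorts. Every retained draw
  is therefore mapped to the representative with **geometric mean
  discrimination = 1** (an exact likelihood-preserving transformation:
  `s = geomean(alpha)`, `sigma2 -> s^2 sigma2`, `beta0 -> beta0 + 2 ln s`,
  `beta1 -> beta1 / s`, `alpha -> alpha / s`, thresholds `* s`), which
  cancels the ridge draw-by-draw. Reported biometric parameters live on
  this geometric-mean scale; the generator's default bank has geometric
  mean discrimination exactly 1 so generating values sit on the reporting
  scale. Scale-free quantities (heritability, effect size) are unaffected
  by any of this.

**Priors** (proper, weakly informative, configurable via `PriorSpec`):
half-normal(scale 2) on the latent-component SDs; normal(0, sd 10) on
`beta0`, `beta1` and free thresholds; lognormal(0, 1) on non-anchor
discriminations.

**Derived quantities** use plug-in posterior means: `h2 =
sigma2_A / (sigma2_A + sigma2_C + exp(beta0))` (the E part evaluated at
g = 0), total phenotypic variance as that denominator, and the interaction
effect size `exp(beta1 sqrt(sigma2_A))`. The summary table also reports the
posterior mean of the per-draw h2 ratio, which is typically a point or two
lower than the plug-in value because the ratio is a concave transform.

## Posterior computation

`run_chains` is an adaptive Metropolis-within-Gibbs sampler. Every block is
a Gaussian random walk on an unconstrained scale (log for variances and
discriminations), with per-coordinate step sizes adapted towards 0.44
acceptance during burn-in and frozen afterwards (so the post-burn-in chain
is a fixed Markov kernel). Updates are vectorised across conditionally
independent coordinates: all individuals' `theta_j` at once, all MZ family
A-values at once, DZ shared/unique parts, all items' discriminations, and
thresholds in two interleaved column groups proposed jointly per item. The
GPCM likelihood table is a numba kernel, and the two threshold column
groups alternate across iterations; a cohort of 600 families runs at ~3 ms
per iteration on one core. Missing responses are sampled from their
GPCM full conditional each iteration (treated as sampled nodes, not
marginalised). Defaults: 2 chains, 5,000 burn-in, 10,000 retained draws,
no thinning. Initial states are jittered per chain; a non-finite initial
density triggers re-initialisation with fresh jitter (bounded retries).

Convergence is monitored by the classic potential scale reduction factor
per hyperparameter (between/within-chain variances, threshold 1.1); failure
sets a `converged=False` flag rather than raising, since non-stationarity
(seen in practice for ADE variants) is itself a reportable result.
`hpd_interval` is the empirical shortest window containing the target mass.

**Sampler validation.** On the continuous-trait subcase (trait observed,
no IRT layer) the posterior moments of `sigma2_A` and `exp(beta0)` match an
independent 2-D grid posterior built from bivariate-normal family
likelihoods to within Monte-Carlo error; the joint density matches a
brute-force grid integration on a one-family instance; with item parameters
frozen at truth, the hyperparameters are recovered within one posterior SD
at 600 families.

## Two DIC focuses

The deviance recorded along the chains is `-2 log p(observed responses |
theta, item parameters)` — conditional on all sampled quantities, the
convention general-purpose Gibbs samplers use, with the point estimate at
posterior means. This is the DIC reported per fit.

For *comparing nested genetic models* that focus is structurally
uninformative: the genetic hyperparameters do not appear in the conditional
deviance, so adding an interaction slope costs nothing and the comparison
degenerates to simulation noise. `twinaxe.marginal` therefore also computes
a hyperparameter-focused deviance, `-2 log p(y_family | sigma2_A, sigma2_C,
beta0, beta1; item parameters)`, integrating all latent components out by
fixed Gauss-Hermite quadrature (9 latent nodes per dimension, 11 trait
nodes; MZ: one additive node set, DZ: shared + unique sets, ACE: an extra
shared-environment set — quadrature bias cancels between models evaluated
on the same data and rule). Its Dbar averages a few dozen evenly thinned
hyperparameter draws (40 in the comparison path), the point estimate uses
posterior means. `compare_genetic_models`
additionally evaluates every model against one *common* item bank (the
average of the fits' posterior-mean banks): the models share the
measurement layer, and plugging each fit's own bank into its deviance would
add several units of independent noise — more than the single-parameter
penalty that separates, say, AE from AE+AxE. With strong interaction the
two focuses agree on the winner; near the null only the hyperparameter
focus reliably prefers the sparser model, and even then the decision rides
on an essentially chi-squared(1) evidence draw, so a minority of replicates
favouring the larger model is expected behaviour, not a defect.

## Psychometric stage

`fit_irt` is marginal maximum likelihood with a standard-normal latent
density and 61-node Gauss-Hermite quadrature (the conventional scale for
stand-alone marginal IRT; the genetic stage uses the geometric-mean
discrimination identification instead). EM alternates posterior node weights per respondent
with per-item L-BFGS M-steps on expected category counts; the M-step never
accepts a worse objective, so the marginal log-likelihood is monotone.
One randomly selected twin per family (seeded) enters, respecting the
independence assumption; missing responses drop out of the likelihood
(full-information ML). Categories never observed are collapsed into their
lower neighbour by default (recorded on the fit object). GRM cutpoints stay
strictly ordered through a log-increment parametrisation. AIC ranks PCM /
GPCM / GRM. Item information is `alpha^2 Var(category | theta)` for the
partial-credit family and the cumulative-logit form for GRM; classical
statistics (Cronbach's alpha, item-rest correlations, MZ/DZ sum-score
correlations) use complete responders only.

## Synthetic cohorts

The generator emulates the cohort the analysis was designed for: 415 MZ +
669 DZ pairs (scaled variants use 250 + 350), nine 7-category items,
per-family missingness pattern (95% complete, 2% one missing score, 1%
several, 2% one twin's full set) placed completely at random, and the AxE
latent structure at the generating values `sigma2_A = 0.25, exp(beta0) =
0.19, beta1 = 2.20` (hyperactivity-like, AE) and `sigma2_A = 0.27,
sigma2_C = 0.31, exp(beta0) = 0.51, beta1 = 2.16` (inattention-like, ACE).
The default item bank has discriminations 0.8-1.2, normalised to
geometric mean exactly 1, and thresholds spread over roughly +/-2 trait SDs
with small item shifts; no calibration population is published for the real
scales, so the bank is calibrated to the generated trait scale itself.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: informative (non-MCAR) missingness, rater or
sibling-contrast effects, sex-specific parameters, multidimensionality,
item misfit of real SWAN/SDQ responses, and sampling/exclusion artefacts of
a real cohort.

## Numerical choices and limitations

* Deviance is recorded over observed responses only; imputed values enter
  the sampler state but not the deviance.
* HPD ties resolve to the lowest window; model-selection ties flag all tied
  models in name order.
* Reporting on the geometric-mean-discrimination scale removes the
  scale-ridge drift from the biometric draws; what remains is the genuine
  posterior uncertainty of the relative discriminations, which shrinks
  with both items and families.
* ADE / ADE+GxE are implemented (generator, density, sampler) but the
  dominance posterior mixes poorly — the convergence flag frequently
  raises, consistent with reported experience for these variants — and the
  hyperparameter-focused deviance does not cover ADE.
* The spec-level `io_cli` surface is `io.py` + `pipeline.py` + the `twinaxe`
  click CLI; configs round-trip through JSON/YAML and pipeline manifests
  record seeds, versions and output hashes for reproducibility.

## Problem sizes used by the shipped runs

Analysis drivers fit 250 MZ + 350 DZ pairs with 2 chains x (3,000 burn-in +
3,000 retained); the recovery checks use 2 chains x 5,000 retained on the
same cohort size (3,500 burn-in across 10 replicates in the test suite,
5,000 across 5 replicates in `scripts/acceptance.py`); model-selection
checks run 100 MZ + 140 DZ with 2 chains x (600 + 800). These sizes keep
every stage to minutes on a single core while leaving the Monte-Carlo error
well inside the tolerances the checks assert.
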