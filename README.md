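# twinaxe

One-step Bayesian twin analysis of ordinal questionnaire data, for
behaviour-genetics researchers who want to test **genotype–environment
interaction (AxE)** without the artifacts that sum scores introduce.

## The problem and the model

Classical twin designs decompose the variance of a phenotype into additive
genetic (A), shared/common environmental (C) and unique environmental (E)
parts by contrasting monozygotic (MZ) and dizygotic (DZ) twin pairs. When
the phenotype is measured by a handful of ordinal items (e.g. ADHD
hyperactivity or inattention scales), analysing sum scores confounds trait
variance with heteroscedastic measurement error — floor and ceiling effects
alone can create a *spurious* interaction between genes and environment.

`twinaxe` therefore fits the measurement model and the biometric model
jointly, in one step. The latent trait of twin *j* is

```
theta_j = A_j + C_j + E_j,        A MZ-shared; corr(A) = 0.5 across DZ co-twins
```

and the unique-environmental variance is log-linear in the genetic value —
the AxE interaction:

```
Var(E_j | A_j) = exp(beta0 + beta1 * A_j)
```

so `beta1 > 0` means environmental influences matter more for individuals
with a higher genetic predisposition. Item responses follow the generalized
partial credit model (GPCM): category *k* of item *i* has log-weight
`sum_{h<=k} alpha_i (theta - beta_ih)` with `beta_i1 = 0` and the latent
mean fixed at 0; the scale is identified by reporting every draw on the
representative with geometric-mean item discrimination 1 (see
`docs/methods.md`). The
joint posterior is sampled by an adaptive Metropolis-within-Gibbs scheme
(2 chains by default), missing item scores are imputed every iteration,
and models are compared by DIC. Derived quantities:

* narrow-sense heritability `h2 = sigma2_A / (sigma2_A + sigma2_C + exp(beta0))`,
* interaction effect size `exp(beta1 * sqrt(sigma2_A))` — the factor by which
  the E-variance grows one genetic SD above the mean,
* pointwise credibility bands of `exp(beta0 + beta1 g)`.

Because no individual-level twin data are distributed, the package ships a
first-class synthetic-cohort generator (`twinaxe.simulate`) that reproduces
the cohort structure the analysis assumes: 415 MZ + 669 DZ pairs, nine
7-category items, ~95% complete families, and the AxE latent structure.

## Worked example

```python
import numpy as np
import twinaxe as tx
from twinaxe.simulate import default_item_bank, hyperactivity_truth

truth = hyperactivity_truth()        # AE+AxE: s2A=0.25, exp(b0)=0.19, b1=2.2
design = tx.CohortDesign(n_mz=250, n_dz=350)
table, latents = tx.simulate_cohort(truth, design, default_item_bank(), seed=42)

fit = tx.run_chains(
    table,
    tx.ModelSpec(flavour="AE", interaction=True),
    tx.MCMCSettings(n_chains=2, burn_in=5000, n_iter=5000),
    seed=11,
)
print(tx.summarize(fit).round(2).to_string(index=False))
```

which prints (seeds as above):

```
                parameter  mean   sd  hpd_lo  hpd_hi significant
                 sigma2_a  0.20 0.03    0.14    0.26         NaN
                    beta0 -1.53 0.14   -1.81   -1.26        True
                    beta1  2.29 0.24    1.79    2.76        True
                exp_beta0  0.22 0.03    0.16    0.28         NaN
             h2 (plug-in)  0.48  NaN     NaN     NaN         NaN
      h2 (posterior mean)  0.48 0.06    0.36    0.59         NaN
total phenotypic variance  0.42  NaN     NaN     NaN         NaN
          AxE effect size  2.79  NaN     NaN     NaN         NaN
```

Read this as: at this reduced cohort size the generating slope
(`beta1 = 2.2`), additive variance (`sigma2_A = 0.25`, here 0.20 with HPD
[0.14, 0.26]) and baseline E-variance (`exp(beta0) = 0.19`) are all
recovered inside their 95% HPD intervals. The positive, significant `beta1`
says twins with a higher genetic value show more unique-environmental
variance; the effect size ~2.8 means the E-variance roughly triples one
genetic SD above the mean, and about half the phenotypic variance is
additive-genetic (h2 ~ 0.48 vs the generating 0.57 — inside the posterior's
uncertainty at 600 pairs).

The numbered drivers under `analysis/` run the full narrative — cohort
simulation, psychometric stage (Cronbach's alpha, PCM/GPCM/GRM by AIC, item
information), genetic fits for both symptom dimensions, DIC comparison, and
derived-quantity tables — writing their outputs under `results/`. The same
stages are scriptable via the `twinaxe` CLI
(`simulate | irt-fit | fit | compare | report | pipeline`).

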