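# msatbot

Coalescent-ABC and heterozygosity-excess inference of recent population
bottlenecks from microsatellite genotype panels.

Many long-lived vertebrate populations — pinnipeds are the motivating
case — were driven through severe but short commercial-exploitation
bottlenecks within the last ~10–70 generations.  Such declines leave
transient genetic signatures in multilocus microsatellite data:
allelic states are lost faster than gene diversity, producing
heterozygosity excess, depressed M-ratios and a deficit of rare
alleles.  `msatbot` turns these signatures into quantitative inference
for panels of the kind assembled from published studies (tens to
thousands of individuals, 5–35 loci per species), entirely from
GenePop-format text files.

## What it computes

**Two complementary bottleneck measures per species:**

1. **Heterozygosity excess (Cornuet–Luikart).** For each polymorphic
   locus, the equilibrium heterozygosity `H_eq` given the observed
   allele count `k` is estimated from coalescent simulations of a
   constant-size population (mutation models: SMM, TPM70/80/90, GSM).
   The statistic `prop_het-exc` — the fraction of loci with
   `He > H_eq` — is 0.5 for a stable population, above 0.5 after a
   recent decline and below 0.5 after an expansion.

2. **Approximate Bayesian computation.** Two demographies are
   contrasted: a *bottleneck* model (present size `N_e` back to
   `t_bot_end`, bottleneck size `N_e_bot ~ U[1, 500]` until
   `t_bot_start`, then historical size `N_e_hist`) and a
   *non-bottleneck* model (`N_e` switching to `N_e_hist` at `t_hist`);
   `N_e, N_e_hist ~ lognormal(10.5, 1)`, times uniform on 10–70 (start)
   and 1–30 (end) generations, `mu ~ U[1e-5, 1e-4]`,
   GSM parameter `~ U[0, 0.3]`.  Five summary statistics (mean over
   loci of allele number `k`, allele size range `r`, Nei gene diversity
   `He`, M-ratio `M = k/(r+1)`, and the proportion of alleles below 5%
   frequency) are matched between the observed panel and a simulated
   reference table by MAD-scaled Euclidean rejection.  Model choice
   uses a weighted multinomial logistic regression on the accepted
   statistics (posterior bottleneck probability `p_bot`); parameters
   are estimated by Beaumont local-linear regression adjustment on
   log/logit scales.  Cross-validation, prior-predictive
   goodness-of-fit and posterior predictive checks quantify what the
   data can and cannot resolve.

The simulation engine is a numba-compiled single-population Kingman
coalescent with piecewise-constant size and generalized-stepwise
mutation (Poisson mutations per branch; step size geometric, sign
symmetric), fast enough to build 10^5-row-per-model reference tables in
about a minute on one CPU.

The ABC machinery is exposed as scikit-learn-style estimators
(`ABCModelClassifier.fit(X, y).predict_proba(obs)`,
`ABCLocalLinearRegressor.fit(X, theta).posterior(obs)`), so it composes
with sklearn pipelines and model selection; the module-level functions
wrap them for table-centric use.

## Worked example

```python
import numpy as np
from msatbot import (DemographicParams, build_reference_table,
                     simulate_dataset, model_posterior, param_posterior,
                     point_estimates, prop_het_excess, TPM80, mean_sumstats)

rng = np.random.default_rng(42)
table = build_reference_table(n_per_model=20_000, rng=rng)

truth = DemographicParams("bottleneck", ne=30_000, ne_hist=30_000,
                          mu=5e-5, gsm_par=0.1, ne_bot=25,
                          t_bot_start=60, t_bot_end=5)
ds = simulate_dataset(truth, n_ind=40, n_loci=14, rng=rng,
                      species_id="demo_seal")

obs = mean_sumstats(ds)
choice = model_posterior(obs, table, tolerance=0.0125)
print(f"p_bot = {choice.p_bot:.3f}  (preferred: {choice.preferred_model})")

post = param_posterior(obs, table, "bottleneck", tolerance=0.0125)
est = point_estimates(post).loc["ne_bot"]
print(f"Ne_bot mode = {est['mode']:.0f}  "
      f"95% CI = [{est['ci_low']:.0f}, {est['ci_high']:.0f}]")

hx = prop_het_excess(ds, TPM80, n_sims=1000, rng=rng)
print(f"prop_het_exc (TPM80) = {hx.prop_het_exc:.2f}")
```

Output:

```
p_bot = 1.000  (preferred: bottleneck)
Ne_bot mode = 18  95% CI = [4, 130]
prop_het_exc (TPM80) = 0.73
```

The species was simulated through a severe bottleneck
(`N_e_bot = 25`); the ABC model choice identifies the bottleneck model
with near certainty, the posterior mode of `N_e_bot` (18, CI 4–130)
brackets the truth, and the majority of loci show heterozygosity
excess (0.73 > 0.5).

## Command line

```
msatbot synth            # synthetic multi-species panel + truth manifest
msatbot simulate-table   # build an ABC reference table (CSV + sidecar)
msatbot analyze          # full per-species report (JSON)
msatbot het-excess       # Cornuet–Luikart test for one panel
msatbot cv-model         # model-choice cross-validation
msatbot cv-param         # parameter prediction errors
msatbot gof              # prior-predictive goodness of fit
msatbot ppc              # posterior predictive statistics
msatbot panel-report     # collate species reports into one table
```

Every verb takes `--seed`; all outputs are CSV/JSON.

## Documentation

`docs/methods.md` describes the models, the numerical choices, the
synthetic-data generator and known limitations.
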