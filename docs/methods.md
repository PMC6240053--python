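# Models and methods

This note documents the models implemented in `msatbot`, the numerical
and design choices behind them, what the synthetic-data generator does
and does not emulate, and the known limitations of the inference.

## Demographic models

Both models describe a single panmictic diploid population with
piecewise-constant effective size, looking backwards in time:

* **Bottleneck model** (7 parameters): present size `N_e` from now
  until `t_bot_end`, bottleneck size `N_e_bot` between `t_bot_end` and
  `t_bot_start`, historical size `N_e_hist` before that.  All changes
  are instantaneous.
* **Non-bottleneck model** (5 parameters): `N_e` until `t_hist`, then
  `N_e_hist`.

Default priors (all independent):

| parameter     | prior                    | units                        |
|---------------|--------------------------|------------------------------|
| `N_e`         | lognormal(10.5, 1)       | diploid individuals          |
| `N_e_hist`    | lognormal(10.5, 1)       | diploid individuals          |
| `N_e_bot`     | U[1, 500]                | diploid individuals          |
| `t_bot_start` | U[10, 70]                | generations before present   |
| `t_bot_end`   | U[1, 30]                 | generations before present   |
| `t_hist`      | U[10, 70]                | generations before present   |
| `mu`          | U[1e-5, 1e-4]            | mutations/locus/generation   |
| `GSM_par`     | U[0, 0.3]                | multistep mutation proportion|

The lognormal sizes have median `exp(10.5) ≈ 36,300` — thousands to
tens of thousands for most draws, occasionally hundreds of thousands.
Because `N_e` and `N_e_hist` are drawn independently in *both* models,
the non-bottleneck model also covers long-term declines and
expansions; only the bottleneck model contains a transient severe
reduction.  The pair `(t_bot_start, t_bot_end)` is rejection-resampled
until `t_bot_end < t_bot_start`: the independent uniforms otherwise
permit inverted epochs, which have no demographic meaning.  Rejection
preserves each marginal's support (though not exact uniformity near
the overlap).

Sizes are truncated below at one diploid individual.  The lognormal
priors are effectively untruncated (P(N < 1) ≈ 1e-25).

## Coalescent and mutation simulation

Genealogies follow the continuous-time Kingman coalescent with
pairwise coalescence rate `1/(2N(t))` per generation.  Epoch
boundaries are handled through the memorylessness of the exponential:
a waiting time that overshoots the current epoch is redrawn from the
boundary at the next epoch's rate.  Node times are in generations.

Microsatellite mutation is generalized stepwise: the mutation count on
a branch is Poisson(`mu` × branch length); each mutation moves the
allele by a signed step, direction symmetric, magnitude `S` geometric
with `P(S = s) = (1 − g) g^(s−1)` on `s ≥ 1`.  Under this convention
`g` (the GSM parameter) literally equals the proportion of multistep
(`|S| ≥ 2`) mutations.  Two-phase models (TPM) draw a single-step
mutation with probability `p_single` and otherwise a geometric
magnitude whose parameter `q` solves `(1 − q)/q² = v` for the
configured variance `v` (default 0.30; `v = 0.30` gives
`q ≈ 0.805`).  The strict SMM is the `p_single = 1` limit.

The root allele is fixed at 100 repeat units and tip states are
floored at one unit; no upper allele-size boundary is imposed.  All
statistics are shift-invariant, so the root reference is arbitrary.
Diploid genotypes pair gene copies by consecutive sample index, which
is equivalent to random pairing by exchangeability.

The hot loops (genealogy, mutation, per-locus statistics, the
conditional equilibrium-heterozygosity simulation, and the HWE
permutation test) are numba-compiled; building a reference table of
2 × 10^5 rows (40 individuals × 10 loci each) takes roughly a minute
on one CPU.  An independent cross-check against msprime's coalescent
(tree-height moments under a three-epoch demography) is part of the
test suite.

## Summary statistics

Five per-locus statistics, averaged over loci, drive the ABC:

* allele count `k`;
* allele size range `r` (repeat units);
* Nei gene diversity `He`; the default is the unbiased estimator
  `(2n/(2n−1))(1 − Σ p̂²)` over gene copies, matching common software
  defaults; the plug-in form is available via `unbiased=False`
  (exposed because the estimator used upstream of any given published
  table is rarely documented);
* M-ratio `M = k/(r + 1)`;
* proportion of alleles at sample frequency strictly below 5%.

Missing genotypes are excluded per locus (pairwise deletion).
bp-encoded panels are converted to repeat units first: per locus the
motif is estimated as the modal gap among sorted distinct allele sizes
(ties to the smaller gap; single-allele loci fall back to the declared
motif), and each allele maps to the nearest unit — an approximation
that tolerates imperfect repeat periodicity.

Two resampling standardisations make unequal panels comparable:
diversity reporting resamples 10 individuals with replacement 1000
times (mean and 2.5/97.5-percentile CI of Ho, allelic richness, He,
low-frequency-allele proportion); the ABC observables resample 40
individuals 1000 times and average the five-statistic vector.  Panels
smaller than the resample size are used whole, unsampled.

## Data QC

Each locus is tested for Hardy–Weinberg deviation twice: a chi-square
of observed genotype counts against expectations from sample allele
frequencies (no pooling of rare genotype classes — the df is
`k(k+1)/2 − k`; pooling conventions vary across software and none is
adopted here), and a Monte-Carlo exact test that permutes gene copies
among individuals and compares the Levene conditional probability of
the resulting genotype table (default 10,000 permutations, minimum
1000).  A locus is *deviating* only when both tests are significant
after Bonferroni correction; the default correction is table-wide
across all testable loci in the run (monomorphic loci are excluded
from the denominator), with per-dataset and uncorrected modes
available.  Flagged loci are reported; dropping them is an explicit
sensitivity toggle, as is restricting a panel to an externally
supplied cluster of individuals.

## ABC

**Rejection.** Statistics are scaled by their median absolute
deviation over the whole reference table (normal-consistent MAD; a
zero-MAD statistic is dropped from the distance with a warning).  The
`ceil(tolerance × n_rows)` rows closest to the observation in
Euclidean distance are accepted; ties break deterministically by row
index.  The default tolerance 5e-4 is interpreted per analysis table
(at the full simulation scale of 10^7 rows per model it retains 5000
rows); the pipeline rescales it upward automatically when a
desk-scale table would otherwise yield fewer than 500 accepted rows.

**Model choice.** Accepted-label proportions give the rejection
estimate; the default refines it by multinomial logistic regression of
the model label on the scaled statistics over the accepted rows,
weighted by the Epanechnikov kernel `1 − (d/d_max)²`, evaluated at the
observed vector.  The regression is fitted with a negligible ridge
penalty (`C = 1e6`) for numerical stability; degenerate fits (a single
label among accepted rows, separation failures) fall back to the
rejection proportions and are flagged.

**Parameter estimation.** Beaumont local-linear adjustment: each
parameter is transformed — log for the unbounded lognormal sizes,
logit onto the prior support for every uniformly bounded parameter
(`N_e_bot`, `mu`, `GSM_par`, all times) — then regressed on the scaled
statistics over the accepted rows by Epanechnikov-weighted least
squares; the adjusted draw is the fit at the observation plus the
residual, back-transformed.  The logit (rather than log) transform for
`N_e_bot` and `mu` is deliberate: it guarantees every adjusted draw
respects its prior support, which a log transform cannot for
upper-bounded parameters.  Because the times are adjusted
independently, an adjusted pair can violate `t_bot_end <
t_bot_start`; draws are nudged back into the valid ordering only when
they are used to re-simulate (posterior predictive).  Singular designs
fall back to a small ridge and are flagged.  Point estimates: mode =
argmax of a Silverman-bandwidth Gaussian KDE over the weighted
adjusted draws on a 512-point grid; median and 95% CI from weighted
quantiles.

**Validation machinery.**  Leave-one-out cross-validation for model
choice reports both the mean posterior probability assigned to each
model and the correct-classification rate (argmax); the two differ
materially and the rate is what a confusion matrix summarises.
Parameter cross-validation uses rejection-only estimation (posterior
median of accepted draws, pseudo-observation excluded) and normalises
the squared error by the variance of the sampled true values, so 0 is
perfect and ~1 means prior-level information.  Goodness of fit uses
the median accepted distance as statistic, with a null distribution
from pseudo-observations drawn from the fitted model's own rows.
Posterior predictive checks resample whole rows of the adjusted
posterior (weighted, preserving cross-parameter dependence) and
re-simulate one panel per draw.

## Equilibrium heterozygosity conditional on allele number

`H_eq | k` is estimated by first calibrating a scaled mutation rate
`theta*` such that the expected allele count of an `n`-copy
constant-size sample equals the observed `k` (bisection on
`log theta` against Monte-Carlo pilots of 400 simulations per
iteration), then simulating unconditionally at `theta*` and retaining
the Nei heterozygosity of replicates with exactly `k` alleles.  An
alternative scheme — placing mutations sequentially on a fixed
genealogy and stopping at the first time `k` alleles segregate — was
implemented and rejected: stopping at first passage favours
mutation-poor configurations and biases `H_eq` low by several percent,
which pushes the stable-population excess proportion to ~0.64.

A locus is in *excess* when `He` exceeds the **median** of its `H_eq`
draws.  The median is the default (the mean is available) because
`P(He > median) = 1/2` exactly for a stable population, whereas the
left skew of the conditional `H_eq` distribution makes the mean-based
rate systematically exceed 1/2 even under a perfectly matched mutation
model (measured: 0.59 ± 0.04 versus 0.51 ± 0.04 across replicate
200-locus stable panels).  `H_eq` draws are shared between loci with
identical (gene-copy count, allele count) since the conditional
distribution depends on nothing else.  Default 10,000 simulations per
locus; the validation suite uses 1000 for speed.

## Synthetic data generator

`generate_panel` emulates a heterogeneous multi-species panel: per
species, sample size and locus count are drawn from discretised
log-uniforms split at the target medians (median 253 individuals on
16–2386; median 14 loci on 5–35), the demography is a prior draw from
the configured model (about 11 of 30 species bottlenecked by
default), and genotypes are simulated by the same coalescent engine.
A truth manifest records every generating parameter and seed.  Missing
genotypes are off by default and can be enabled up to 20% for
robustness checks.

What the generator does **not** emulate: genotyping error and allele
dropout, population structure and admixture (real panels were cleaned
to their largest genetic cluster), linkage between loci, locus-specific
mutation rates and motif heterogeneity, and ascertainment bias in
locus choice.  Passing tests therefore demonstrate correctness of the
inference under the model's own assumptions, not robustness to these
real-data complications — the HWE/cluster toggles exist precisely
because real panels violate them.

## Validation scales and expected accuracy

The validation suite builds reference tables of 10^5 rows per model
(the full-scale design of 10^7 per model is supported through chunked,
seed-stamped building).  Measured at this scale with 5-statistic
matching: the non-bottleneck model is correctly classified for ~82–88%
of pseudo-observations; the bottleneck model for ~73–80%.  The
bottleneck rate is limited by genuine prior overlap, not table size:
it is unchanged between 10^5 and 10^6 rows per model and acceptance
counts of 100–1000, and misclassification concentrates at bottleneck
intensities `(t_bot_start − t_bot_end)/(2 N_e_bot) < 0.03`, i.e.
draws whose bottleneck is too mild to distinguish from the
non-bottleneck model's own size variation.  Rejection-ABC prediction
errors at this scale: ~0.6 for `N_e_bot` (informative), below 1 for
`mu` and `GSM_par`; near or above 1 for `N_e` and the times.

## Determinism

Every stochastic entry point takes a numpy `Generator` (or seed);
kernel seeds are derived from it, and chunked table building derives
per-chunk seeds so results are independent of chunking.  Fixed seeds
reproduce tables, reports and test statistics bit-for-bit on a given
platform.

## Known limitations

* Single population, no migration or structure; microsatellites only.
* The GSM step-size convention (`g` = multistep proportion) is one of
  several in circulation; it is isolated behind `MutationModelSpec`.
* The `H_eq` conditioning via `theta*(k)` is the classical
  approximation; the conditional distribution depends weakly on theta,
  so residual calibration error of a few percent in `prop_het-exc`
  is possible.
* Local-linear adjustment can mildly degrade when the posterior is
  strongly curved within the accepted neighbourhood; widening the
  tolerance trades this against regression bias.
* The mode of a bounded parameter's KDE can sit at the support edge
  for flat posteriors (e.g. `N_e_bot` under a weak signal).
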