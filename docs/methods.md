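# Methods

## The problem

Birth weight is shaped both by the fetus's own genotype and by the
maternal genotype acting through the intrauterine environment. Because a
child inherits half of each maternal allele pair, the two genotypes are
correlated (r = 0.5), and a naive regression of birth weight on either
one mixes both effects. `bwburden` implements a rare-variant gene-burden
pipeline over two analysis arms — participants reporting their *own*
birth weight (fetal arm) and mothers reporting their *first child's*
birth weight (maternal arm) — and then decomposes the two marginal
burden estimates into conditional fetal and maternal effects.

## Burden model

For each gene g and collapsing mask m, the carrier statistic is the
indicator

    X_i = 1{ sample i carries >= 1 alt allele at >= 1 qualifying variant }

(allele-count coding is available via `coding="count"`; at MAF < 0.1%
the two almost always coincide). Qualifying variants must pass genotype
QC, belong to the mask's consequence classes (PTV requires LOFTEE
high confidence; damaging missense requires CADD >= 25 — dialect
variants are documented in `bwburden.masks`), and be strictly rarer than
MAF 0.1% in-sample within the arm. Gene x mask combinations with fewer
than 10 carriers are not tested. The association model is OLS:

    z(BW)_i = beta * X_i + covariates_i + e_i

with z the within-arm z-score of derived birth weight (kg) after
exclusions, and covariates age, age², ten principal components,
sequencing-batch indicators, and sex in the sex-combined fetal arm.
beta is therefore in phenotype SD units per carrier; p-values come from
the t distribution with residual degrees of freedom (exact at simulated
sample sizes, indistinguishable from the normal at biobank scale).

The reference analyses at biobank scale use whole-genome mixed models to
absorb relatedness and stratification; the synthetic cohorts here contain
unrelated samples and no stratification, for which OLS estimates the
same quantity. No relatedness adjustment is implemented; this is a known
limitation for real, related data.

## Phenotype derivation

Own birth weight is the mean of repeated visit reports; offspring birth
weight prefers a hospital record over self-reports. Records are excluded
for multiple births, discordant repeats (range > 1 kg; a ">= 1 kg"
dialect is available via `discordance_inclusive`), and extreme derived
values (< 1 kg, or >= 7 kg with the upper bound inclusive). Exclusions
are applied in that order and every exclusion is counted by reason in
the run log.

## Genotype QC

Per-call: SNV calls with DP < 7 or GQ < 20 (indels: DP < 10 or GQ < 20)
are set missing. The source description of this rule is grammatically
ambiguous between AND and OR; the disjunctive reading is the default, as
in common exome-QC practice, and the conjunctive one is available via
`QCThresholds(rule="and")`. Heterozygous SNVs are tested for 50/50
allele balance with an exact binomial on AD_alt out of AD_ref + AD_alt
(not DP); the two-sided p is the symmetric doubled tail capped at 1 —
at p0 = 0.5 all common two-sided definitions coincide — and p <= 1e-3
sets the call missing. Calls with zero informative reads are skipped and
logged. Per-variant: > 50% missingness drops the variant. Two optional
screens target replication-style whole-genome data: a no-intercept
regression of AD_alt on genotype-weighted depth w(GT)·DP (w = 0, 0.5, 1)
whose slope below 0.5 marks a spurious variant (skipped below 5 carrier
calls), and a pass-through AAscore column dropping variants scoring
<= 0.8.

## Maternal/fetal decomposition

With genotype correlation 0.5 and a shared per-mask effect, the marginal
expectations are E[b_F] = beta_F + beta_M/2 and E[b_M] = beta_M +
beta_F/2. The weighted linear model inverts this linear map:

    beta_F_adj = (4 b_F - 2 b_M)/3,     beta_M_adj = (4 b_M - 2 b_F)/3

with variances by propagation, var(beta_F_adj) = (16 se_F² + 4 se_M² -
16 rho se_F se_M)/9 and symmetrically for the maternal side. rho is the
correlation of the two marginal estimates induced by sample overlap
(women contributing to both arms); it defaults to 0 and is configurable.
Genes are labelled fetal_only / maternal_only / both / neither by the
adjusted p-values at alpha = 0.05. The inversion assumes equal effects
across a mask's variants; under heterogeneous per-variant effects the
adjusted estimates are biased, which the simulator can demonstrate by
planting per-gene effects on subsets of variants via custom masks.

## Follow-up tests

* **Sex dimorphism** — stratified burden fits (sex covariate dropped, no
  per-stratum carrier minimum; a stratum without carriers is reported
  not-estimable), compared by z = (b_F - b_M)/sqrt(se_F² + se_M²) with a
  two-sided normal p; dimorphic at p < 0.05. The normal is the large-df
  limit of the two-sample t-test and reproduces the reference dimorphism
  p-value to two significant figures from rounded inputs.
* **Conditional attenuation** — the phenotype is residualised on the
  covariates, then regressed on carrier status alone and on carrier
  status plus a GWAS sentinel dosage jointly; an absolute relative
  change of the carrier estimate above 10% flags attenuation (sign flips
  count). The two-step residualise-then-fit procedure is deliberate; for
  covariates orthogonal to carrier and dosage it agrees with the joint
  model to numerical precision.
* **Replication concordance** — an exact two-sided sign test (doubled
  tail) on the signs of paired discovery/replication betas; zero betas
  are dropped and counted.
* **Multiplicity** — exome-wide significance is 0.05 / (gene x mask
  tests summed across masks, per arm); the candidate-gene screen uses
  Benjamini-Hochberg step-up at 0.05.

## The synthetic duo cohort

The generator emulates the study's data structure, not any particular
population:

* **Genetics.** Maternal genotypes are Binomial(2, af) under HWE; the
  child receives one maternal allele transmitted uniformly at random and
  one population draw (Bernoulli(af)). Fathers are not modelled; the
  population draw is recorded so Mendelian consistency is checkable, and
  it suffices to induce the r = 0.5 dosage correlation for any allele
  frequency. Variants are independent (no LD), laid out one gene per
  100 kb block.
* **Phenotype.** latent = sum over genes of beta_F·child_carrier +
  beta_M·mother_carrier + covariate effects + N(0, noise_sd), in SD
  units; optional sex-specific fetal betas replace beta_F per child sex.
  Covariate effects apply to z-scored covariates (defaults around
  0.01–0.08 SD — small, realistic nuisance structure). The default
  noise_sd = 1 makes the latent scale approximately the phenotype SD
  scale (planted genetic and covariate variance is < 1%, so recovered
  effects are attenuated by < 1% after standardisation). The latent
  value maps to kg as 3.5 + 0.5·latent (conventional term birth-weight
  mean/SD; the source study does not print its cohort's distribution),
  so the kg-domain exclusion rules are exercisable.
* **Reporting.** Each child reports own birth weight at 2 visits with
  0.05 kg noise; mothers report the same birth at 2 visits and a more
  accurate (0.02 kg) hospital record exists for 50% of them. Injected at
  configurable rates, all disjoint in mechanism: discordant repeats (a
  1.5 + |N(0, 0.5)| kg offset on the last visit, chosen to exceed the
  1 kg exclusion threshold robustly), extreme values (drawn below 1 or
  at/above 7 kg), and multiple-birth flags. Rates are invented plumbing
  to exercise the derivation rules; they are not calibrated to any
  cohort.
* **Reads.** DP ~ Poisson(30) (floor 1); low-depth calls (1%) redraw
  from 1 + Poisson(3). GQ ~ U{60..99}, degraded to U{0..19} at 1%.
  Heterozygous AD_alt ~ Binomial(DP, 0.5), or Binomial(DP, 0.2) at
  variants flagged allele-biased; hom-ref/hom-alt calls get AD_alt = 0 /
  DP. Calls go missing at 0.5%. AD_ref + AD_alt always equals DP in the
  simulator; the QC layer does not rely on that.

What passing tests on this cohort do **not** show: robustness to
relatedness and population structure, LD between qualifying variants,
annotation error (consequences are taken as given), genotyping platform
differences between arms, or real reporting-bias structure (recall bias
correlated with phenotype). The generator's artifacts are independent
and unconfounded by design.

## Reference scenario and problem sizes

The default five-gene architecture plants effects taken from published
examples of each qualitative pattern: opposing fetal/maternal effects
(-0.311 / +0.430 SD), a positive fetal effect concentrated in one splice
variant (0.218 SD), a strongly sex-dimorphic negative effect (-1.710
female / -0.177 male), a moderate fetal-only effect (0.330), and a null
gene. Per-variant frequencies (2–5 x 10⁻⁴) are set so that in-sample
MAF stays below the 0.1% cutoff and expected carrier counts clear the
10-carrier floor at the default 5,000 duos. Statistical property checks
use 500 replicates of 12,000-duo cohorts (effect recovery), 2,000
simulated null genes of 300 samples (type-I error), and exhaustive
enumeration for the exact tests; these sizes give Monte-Carlo standard
errors a few times smaller than the planted effects while keeping the
whole suite runnable on a laptop. At these scales small planted effects
(0.2–0.3 SD on ~20 carriers per gene at n = 5,000) are *not* expected to
reach exome-wide significance in the worked example — only the
large-effect dimorphic gene is — mirroring the power regime of
rare-variant discovery generally.

## Numerical choices

* Exact binomial tails via scipy's binom cdf/sf; doubled-tail two-sided
  definition throughout (allele balance, sign test).
* Standardisation uses the sample SD (ddof = 1); z-scoring is idempotent
  and applied once per arm.
* OLS via statsmodels (pinv-based, rank-adjusted df); a carrier vector
  without variance in the aligned analysis set raises rather than
  returning a degenerate fit.
* The missingness filter drops at strictly greater than 50%; the MAF
  filter retains at strictly less than 0.1%; CADD and carrier-count
  thresholds are inclusive (>= 25, >= 10). Boundary semantics are
  pinned by unit tests.
* All randomness flows from one integer seed through named
  `SeedSequence` streams (genotypes, covariates, noise, reporting,
  reads), so components can be regenerated independently and reruns are
  byte-identical; the seed is recorded in the emitted VCF header.
* Run logs conserve counts (records in = records out + exclusions by
  reason) by construction and exclude wall time from serialisation so
  outputs stay deterministic.
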