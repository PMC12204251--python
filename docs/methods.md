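# Methods

`cesscan` detects candidate driver genes of clonal expansion in
spermatogonia (CES) from de novo mutation counts in disease-ascertained
trio cohorts, corroborated by population allele-frequency structure.
This note records the models implemented, the tunable parameters and
their defaults, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## The ascertainment bound

For a variant V and a disease D with prevalence P(D), Bayes' rule gives

    #obs / #exp  ≈  P(V|D) / P(V)  =  P(D|V) / P(D)  ≤  1 / P(D),

because penetrance P(D|V) cannot exceed 1.  With a conservative
prevalence lower bound P\*(D) (default 0.01 for neurodevelopmental
disorders, i.e. a maximal ascertainment fold of 100), any gene or
variant whose observed de novo count significantly exceeds expectation
× 1/P\*(D) cannot be explained by ascertainment: something raised its
effective mutation rate.  CES — positive selection on driver mutations
in sperm stem cells, which multiplies the transmitted mutation rate by
a factor κ ≥ 1 — is the mechanism the package targets.  Embryonic
lethality can only deflate observed counts, so the tests are
conservative with respect to it.

## Mutational expectations

Per-site baseline rates μ_v (Roulette-style, unscaled and dimensionless)
are converted to cohort-scale expected counts by normalising against
the observed synonymous de novo count NS:

    λ_v = NS · μ_v / Σ_{v∈S} μ_v ,        λ_A = Σ_{v∈A} λ_v ,

with S the admissible synonymous sites.  This absorbs cohort size,
coverage and parental age.  Sites are admissible at "high" or "TFBS"
quality; classes are LoF (high-confidence flag plus stop-gain or
essential-splice consequence), synonymous (only synonymous labels, no
splice involvement), and missense (pathogenicity score strictly above
0.1).  Genes with overlapping CDS are resolved by an exact
maximum-weight independent set on the overlap graph (weight = CDS
length), which retains the longer gene of an overlapping pair; ties are
broken toward the lexicographically smallest gene-id set so that runs
are reproducible.  The tie-break is our choice; nothing in the science
dictates it.

## Overdispersion control

Synonymous counts are compared under Poisson and Negative Binomial
models, the latter parametrised by mean λ_v and variance λ_v(1+γ)
(Poisson–Gamma mixture; size λ_v/γ need not be integer).  γ is
estimated by bounded scalar maximisation on [1e-8, 10] (log scale,
`xatol` 1e-10); the NB is accepted when it gains more than one
log-likelihood unit (AIC with one extra parameter).  The binomial
coefficient is evaluated as Σ_{j<n} log(r+j), exact for integer counts
and stable when r = λ/γ is huge — plain log-gamma differences lose more
than the 1e-6 tolerance we hold the γ→0 limit to.  Regionally
correlated rate errors are probed separately with the gene-level
statistic χ² = Σ_g (n_g − λ_g)²/λ_g on G−1 degrees of freedom.  Sites
with λ_v = 0 carry no information and are excluded (counted).  A
non-obvious corner: all-zero counts at substantial total expectation
drive γ̂ to the upper bound with a real AIC preference for the NB —
uniform zeros are themselves extreme overdispersion evidence.

## Subcohort homogeneity

Gene-level LoF counts across subcohorts are compared under four models:
multinomial with probabilities fixed at synonymous-count proportions
(0 parameters), free multinomial (C−1), Dirichlet-multinomial centred
on the fixed proportions (1: concentration), and free
Dirichlet-multinomial (C).  Concentration is optimised on a log scale
in [1e-3, 1e6]; model 4 by joint L-BFGS-B over (log-concentration, mean
logits) initialised from the model-2 MLE and the model-3 concentration.
When the optimum is the multinomial limit, the concentration is
reported as infinity with the limiting multinomial likelihood, which
keeps the nesting chain (model 4 ≥ model 3 ≥ model 1) exact rather than
approximate.  Genes with zero row totals contribute zero log-likelihood
and are retained.

## Candidate sets

* **GoF** (per missense variant): upper-tail Negative Binomial test
  against null mean λ_v/P\*(D) with γ = 0.004; Bonferroni over the
  genome-wide number of candidate missense variants, BH q-values within
  the tested family (default report threshold FDR 0.2).
* **LoF-1** (per gene): exact Poisson upper tail against λ_g/P\*(D);
  Bonferroni at 0.05 over the number of genes with an admissible LoF
  site; BH q at FDR 0.1 also reported.
* **LoF-2** (per gene): exact Poisson test against plain λ_g (no
  prevalence scaling), BH across all tested genes; candidates need
  q < 0.1 **and** weak population constraint, LOEUF > 0.5.  The logic:
  a gene both LoF-hypermutable in trios and LoF-tolerated in the
  population is mutating faster than its annotated rate rather than
  escaping selection.
* Enrichment ratios carry Poisson-conjugate 95% intervals from a
  Jeffreys Gamma(1/2, 0) prior (posterior Gamma(n+1/2, 1)), well
  defined at zero counts (lower limit 0) and asymptotically Wald-like.
* Trio-vs-sperm comparison: conditional on n+m observed LoF variants in
  the two datasets, the sperm share is Binomial with success
  probability λ_m/(λ_m+λ_n); both one-sided exact tails are reported
  (sperm excess flags embryonic deleteriousness, trio excess flags
  disease ascertainment), Bonferroni over the genes tested (those with
  ≥1 variant in both datasets).
* Transmission power: paternal-origin fraction under CES is
  p(κ) = bκ/(bκ+1−b) from κ-fold odds inflation of the baseline
  b = 0.75; the exact one-sided binomial test's power is computed by
  enumeration.  Being non-randomized and discrete, its power is exactly
  monotone in κ but sawtooths in the number of variants whenever the
  critical value increments; realised size stays at or below α.

The GoF null can be switched (`gof_null`) between the cohort-scaled
λ_v (default, keeping the variant- and gene-level tests on one scale)
and the raw rate μ_v.

## Population allele-frequency decomposition

Under recurrent mutation and strong heterozygote selection s, the
population frequency of a LoF allele is approximately
Gamma(shape 4N_e μ, scale 1/(4N_e s)); sampling n haploid genomes gives
Gamma-Poisson counts k with

    E(k)   = κ · n·E(μ)/s,
    Var(k) = κ · n·E(μ)/s · (1 + n/(4N_e s)) + κ² (n/s)² Var(μ).

κ multiplies the Gamma shape (mutation input) but not the scale
(selection), so the mean-based estimator κ/s = mean(k)/(n·mean(μ))
responds linearly to CES while the drift estimator
(E_μ[Var(k|μ)] − E(k))/E(k) = n/(4N_e s) does not.  The
rate-heterogeneity variance term is estimated as slope²·Var(μ) with the
slope from the through-origin Poisson regression Σk/Σμ.  Note the
κ-squared form of the heterogeneity term: it follows from
Var_μ[E(k|μ)] with E(k|μ) = κnμ/s.  Genes are compared by ordinary
least squares of log(κ/s-estimate) on log(drift estimate); CES genes
surface as positive residuals.  Genes with nonpositive drift estimates
(possible from sampling noise) are flagged and excluded from the
log-log regression but reported.

Only sites with unscaled μ > 1 (CpG-like) in genes with ≥ 10 such sites
enter this analysis.  This is not cosmetic: the information lives in
high-recurrence sites.  The per-gene sample-variance estimator is
severely biased downward when the per-site Gamma shape 4N_e μ is far
below ~0.05 (few sites ever recur), and only approaches its asymptotics
when expected per-site allele counts reach the tens.  The recovery
tests therefore run in that strong-recurrence regime (per-generation
rates of order 1e-6 at N_e = 1e4, n = 1e6, s = 0.05, 200 sites/gene);
at realistic genome-wide average rates the per-gene estimates are
qualitative, which is also why the method restricts itself to CpG-dense
genes.

## SFS-based selection estimation

Allele counts are binned at fixed boundaries
[0,1,2,...,11,16,24,36,100] (k = 0 is the reference bin; counts at or
above the last boundary join the top bin, rare under strong selection
and logged).  The neutral model ties the log-odds of bin i versus
monomorphism linearly to the rate: log P(K∈i|μ)/P(K=0|μ) = β_i^μ μ,
fitted on synonymous sites by multinomial-logit maximum likelihood
(analytic gradient, L-BFGS-B, coefficient bounds ±100 guard empty
bins).  The selection model subtracts β_i^s √s_het, fitted on LoF sites
with the neutral slopes frozen and per-gene prior mean s_het values as
the covariate; the square-root link is part of the model.  A shared
β^s across rate bins is assumed.  Per-gene s_het is then re-estimated
by bounded 1-d maximum likelihood on [0,1] — a vectorised 41-point grid
(plus 0.01/0.1/0.5 multi-start values) with a bounded scalar polish,
robust to the flat stretches the profile likelihood can have.

The CES signature here is a *downward* bias: counts generated at an
inflated rate κμ but modelled at μ look less depleted than they should,
so the likelihood drags s_het below the prior, increasingly with κ.
This sign requires β^μ and β^s to point the same way across bins —
higher rates push mass into higher-count bins, and selection pulls it
back — which is how real frequency spectra behave and how the generator
defaults are oriented (β_i^μ = 0.02·i, β_i^s = 4 + i).

## Synthetic-data generator

The generator emulates, with one seed fanned out into fixed per-stage
streams (SeedSequence spawn keys): heavy-tailed site rates (log-normal
body, median 0.3, σ_log 0.8, plus a 20% CpG-like point mass log-uniform
on [2, 30]); per-gene CES inflation κ and ascertainment folds capped at
1/P\*(D), applied to functional classes only (synonymous sites are the
neutral yardstick); Poisson or exact Poisson-Gamma per-site de novo
counts (rate ~ Gamma(λ/γ, γ), matching the NB variance λ(1+γ));
multinomial or Dirichlet-multinomial subcohort allocation with weights
(0.32, 0.60, 0.08) mimicking three cohorts of very different size; a
synonymous scaler NS of 8000 events at cohort scale; Gamma-Poisson
population allele counts (defaults N_e = 1e4, s = 0.05, n = 1.6e6
haploid; clamped at n with a logged tally; configurations implying
E(q) > 0.1 are refused as outside the approximation's regime); and
per-gene Poisson sperm-sequencing-like counts that see κ but not
ascertainment, with an embryonic-deleteriousness mode that deflates
trio LoF counts only.  The unscaled-rate-to-per-generation conversion
(`rate_scale`, default 1.5e-7) is chosen so CpG-like sites recur at
sample counts of order 10–100 — the informative regime discussed above.

What the generator does **not** emulate: sequence context and real
mutational signatures, X/Y chromosomes, indels, demography and growth
(the Gamma approximation stands in for the full diffusion), variant
calling artefacts, relatedness, and recruitment structure beyond
subcohort labels.  Tests passing on these data show the estimators are
correct under the stated models, not that the models capture every
property of real cohorts.

## Problem sizes and determinism

The test suite's simulation scales are its study conditions: 1e5 sites
for dispersion recovery (per-site expectations of order 1, the scale at
which γ ≈ 0.004 is identifiable), 400 genes × 500 replicates for χ²
calibration, 400 genes × 40 replicates per model for homogeneity
selection, 100 genes × 200 CpG-like sites for the popgen decomposition,
1e5 sites for SFS coefficient recovery, and 20 planted studies of 1030
genes (1000 null, 20 ascertainment-only at the fold-100 bound, 10 CES
at κ = 17) for end-to-end discrimination.  All randomness flows from
fixed seeds; multi-coefficient recovery is asserted through joint 95%
Wald regions (the multidimensional analogue of ±2 standard errors), and
replicate-level claims carry binomial slack consistent with their
replicate counts.

## Known limitations

* The per-gene popgen decomposition is a moment method; its variance
  estimator is biased low outside the strong-recurrence regime and the
  drift term can go nonpositive by chance (flagged, not hidden).
* AIC model selection is not consistent: even under the null
  multinomial, the richer models are preferred with probability ~0.2
  in aggregate; the homogeneity tests assert the achievable ≥80% rate.
* Exact one-sided tests on discrete counts are conservative; their
  realised size and power sawtooth with the count, as noted for the
  transmission test.
* The SFS model's log-odds are linear in μ; with pre-binned input rates
  this should be applied at bin midpoints, and extrapolation far
  outside the fitted μ range is unreliable.
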