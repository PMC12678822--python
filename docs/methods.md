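# Methods

## The simulation model

Each population consists of `n_pop` diploid individuals (default 1000, in
line with effective sizes reported for natural populations). A single
quantitative trait is controlled by `k` additive loci (no dominance or
epistasis): the genotypic value of an individual is the sum of its `2k`
allelic effect values, and the phenotype adds a fresh environmental
deviation `N(0, sigma_e2)` every generation, so the phenotypic variance
partitions as `sigma_T2 = sigma_g2 + sigma_e2`.

One generation consists of:

1. **Viability selection.** Fitness is Gaussian around the current optimum
   `theta` with width `omega`, scaled to 1 at the optimum:
   `w(z) = exp(-(z - theta)^2 / (2 omega^2))`. Each individual survives an
   independent Bernoulli trial with probability `w(z)` — any phenotype can
   survive, but some are more likely to. `omega = 0` is allowed and treated
   as the indicator of an exact optimum match, which is why a handful of
   populations drawn with extremely small `omega` die during the burn-in.
2. **Reproduction.** Survivors are sampled uniformly with replacement into
   random pairs (selfing prohibited; fewer than two survivors is
   extinction) until exactly `n_pop` offspring exist. Each parent
   contributes one gamete per offspring.
3. **Recombination.** Per gamete, the crossover count is
   Poisson(`mu_r`) with positions uniform over the `k - 1` inter-locus
   boundaries (an even number of crossovers in one boundary cancels); the
   copy starts from either parental haplotype with probability 1/2. All
   loci sit on one linear map; `mu_r` of 3 or 5 mimics a trait whose loci
   are spread over several chromosomes.
4. **Mutation (continuum of alleles).** Per gamete, the mutation count is
   Poisson(`k * mu_m`) with `mu_m = 1e-4` per allele; mutated loci are
   chosen uniformly without replacement and each receives an *additive*
   increment `N(0, m2)`. `m2` is set from the drawn mutational
   heritability so that `2 k mu_m m2 = sigma_m2`: the expected new genetic
   variance per generation is the same regardless of `k`. The additive
   increment (rather than replacing the allele value) is what makes the
   injected variance exactly `sigma_m2`.

A run is `stab_gens` generations of stabilising selection (`theta = 0`,
default 10,000, bringing the population to mutation–selection–drift
balance) followed by directional selection: `theta` increases by
`delta_env` every generation, independently of the population's response,
until extinction or a cap (default 240,000 directional generations).

**Initialisation.** Allelic values are seeded i.i.d.
`N(0, sigma_g2_init / 2k)` with `sigma_g2_init = h2 * sigma_T2`, so the
founding genetic variance matches the drawn heritability; the burn-in then
moves the variance to the population's own equilibrium. The equilibrium
variance therefore generally differs from the drawn `h2 * sigma_T2`
(at `n = 1000` the drift–mutation component pushes it upward on a
timescale of ~`2 n` generations); this is recorded, not corrected, and all
trait scaling uses the *realized* equilibrium sd.

## Input parameter distributions

Each population draws a fixed set of starting conditions:

| parameter | distribution | units / range | default interpretation |
|---|---|---|---|
| `sigma_T2` | Exponential(mean 0.018), rejection-truncated to [0.01, 0.09] | log-scale trait variance | meta-analytic fit to field trait variances |
| `h2` | Weibull(shape 1.6, scale 0.4), truncated to [0.01, 0.99] | broad-sense heritability | meta-analytic fit |
| `sigma_m2/sigma_e2` | Gamma(shape 1.1, scale 0.004) | mutational heritability, mean 0.0044 | meta-analytic fit; a Gamma rather than an exponential so the mode is positive |
| `omega` | Uniform(0, 10) | trait units | calibrated so realized selection intensities match field meta-analyses |
| `delta_env` | Uniform(0, 0.3) | trait units / generation | same calibration |

The Exponential parameter is the *mean* (0.018), since the empirical
sample means (0.017–0.022) are on the mean's scale. Truncation is by
rejection, never clipping, to avoid point masses at the bounds. The
log-normal(-2.56, 1.19) distribution of field directional-selection
gradients is retained only as a reference density
(`params.directional_selection_reference`) for validating realized
selection intensities; it is not a sampled input.

## Derived statistics

All rates are in units of the realized equilibrium phenotypic sd
(`eq_trait_sd`, the mean phenotypic sd over the last 1,000 stabilising
generations; approximately haldanes). Using the realized sd (not the drawn
`sigma_T`) keeps the rates and the critical-rate estimator consistent with
the population the burn-in actually produced.

- **Trait rate**: (final − onset census phenotypic mean) / directional
  generations survived / `eq_trait_sd`. Endpoint differences, not
  regression slopes.
- **Lag**: two variants. `lag_mean` is the mean scaled gap
  (optimum − mean)/sd over the directional phase; `lag_rate` is the net
  growth of the gap per generation, constructed so that
  `lag_rate = rate_env − rate_trait` exactly. The `lag_rate` variant is
  the one compared against the 1:1 line in the binned summaries.
- **50%-mortality cutoff**: because the model returns populations to
  carrying capacity every generation, outright extinction requires losing
  essentially everyone at once; as few natural populations recover from
  >50% mortality in one generation, the first directional generation with
  mortality > 0.5 serves as an alternative extinction cutoff, with rates
  recomputed over the truncated lifetime.
- **Offspring per surviving parent**: `No = n_pop / mean survivor count`,
  averaged over the directional phase (matching the constant-size
  assumption of the critical-rate derivation); a stabilising-window
  variant is available for sensitivity checks.
- **Critical rate**: from quasi-deterministic theory,
  `k_c = sigma_g2/(sigma_g2 + V_s) * sqrt((V_s + sigma_g2) *
  ln(No * omega / sqrt(V_s + sigma_g2)))` with `V_s = omega^2 + sigma_e2`,
  `sigma_g2` the equilibrium genetic variance, scaled by `eq_trait_sd`.
  Undefined (nan) when the log argument is ≤ 1 — such a population cannot
  sustain any environmental change.
- **Mutation-adjusted rate**: survivors of long directional selection are
  enriched ~2-fold for high mutational input, so their raw median rate
  overstates what typical populations sustain. The adjusted rate is a
  weighted median of survivor trait rates with weights
  `p(sigma_m2/sigma_e2)` from the Gamma input density, normalized over the
  survivor sample.

## Ensemble design and problem sizes

The full design is 15,000 populations per cell of
{100, 500, 1000, 5000} loci × {3, 5} recombination rates (120,000 runs of
up to 250,000 generations) — cluster-scale, exposed as
`ensemble.FULL_DESIGN` behind an explicit flag, with reference outcomes in
`ensemble.LONG_RUN_TARGETS`. Because loci count and recombination rate
make very little quantitative difference to the medians, the package's
default scaled design (`ensemble.SCALED_DESIGN`) uses one cell
(k = 100, mu_r = 3), 500 populations, a reduced 2,000-generation burn-in
and a 2,000-generation directional cap; it runs in minutes on one core and
reproduces the all-population medians (extinction time, trait-scaled
rates, 50%-mortality cutoff statistics) to Monte-Carlo tolerance.

**Reduced burn-in sensitivity.** Equilibrium genetic variance approaches
its drift–mutation–selection balance on a ~`2 n` generation timescale, so
a 2,000-generation burn-in at n = 1000 leaves `sigma_g2` somewhat below
its 10,000-generation value. The all-population medians are dominated by
`omega` and `delta_env` (which jointly set how fast lag-driven mortality
escalates) and are insensitive to this; survivor-tail quantities (the
5.1% survivor fraction, adjusted rate, k_c distribution) are not
desk-reproducible at this scale and remain long-run targets.

Per-population RNG streams are `SeedSequence(master_seed,
spawn_key=(cell, index, {0: config, 1: run}))`, so ensembles are
byte-identical for a master seed regardless of execution order or worker
count; populations are embarrassingly parallel and merged by key.

## Numerical choices

- Alleles are stored as float32 in a row-major `(n, 2k)` matrix (both
  haplotypes of an individual adjacent); all means, variances and genotype
  sums are accumulated in float64. Gamete assembly is a compiled kernel;
  crossover and mutation totals are generated by Poisson splitting (one
  Poisson total across all gametes, events assigned uniformly), which is
  distributionally identical to the per-gamete Poisson draws implemented
  literally in `make_gamete`.
- Within-gamete duplicate mutation targets are redrawn (loci mutate
  without replacement).
- Census statistics (phenotypic/genotypic mean and variance) are recorded
  *before* selection each generation; survivor means are recorded at
  selection time, giving realized selection differentials.
- Records are thinned for very long runs (full detail for the last 1,000
  stabilising generations and the first 10,000 directional ones, every
  100th generation elsewhere); every summary statistic is an exact
  accumulator unaffected by thinning.
- Extinction = fewer than two survivors (a lone survivor cannot form a
  non-self pair). The extinction check runs after selection, before
  reproduction. Pre-directional extinctions are retained in ensemble
  tables, flagged, and excluded from directional-phase summaries.
- Weighted quantiles invert the cumulative weight at mid-point (Hazen)
  plotting positions; with uniform weights they reduce bit-exactly to
  numpy's default estimator. Equal-count binning ranks with a stable sort
  so ties are broken by original order.

## Synthetic phenology generator

`generate_synthetic_phenology` emulates longitudinal field panels of
advancing phenologies (annual population mean and within-population sd,
~25 series of ~29 years, median advance 0.022 sd/yr, ~2-year generation
times): linear standardized trends, sampling noise of the annual mean
scaled by `trait_sd / sqrt(n_obs)`, and an optional variance decline split
between linear and sqrt-time components (fast-early decline). It does
*not* emulate phenotypic plasticity, shared climate forcing across series,
autocorrelated year effects, or observation-effort changes — so recovery
tests validate the estimators (standardized rates, power-law decay of rate
with study length, variance-trend fits), not inference about real field
data. Real data enter through a thin CSV reader with a documented column
map.

## Limitations

No dominance, epistasis, linkage-map heterogeneity, per-locus mutation
rate variation, migration, phenotypic plasticity, or stochastic noise
around the moving optimum; a single trait free of genetic correlations;
constant `n = 1000` carrying capacity. These match the scope of the model
the estimators derive from; the moving-optimum machinery is agnostic to
them but conclusions about real populations inherit these assumptions.
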