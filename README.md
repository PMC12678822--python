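# optimtrack

How fast can a population evolve to keep up with a directionally changing
environment — and for how long? `optimtrack` is an individual-based,
multi-locus quantitative-genetic Monte Carlo simulator for populations
tracking a moving environmental optimum, together with the estimators
needed to turn ensembles of such simulations into a *maximum sustainable
rate of phenotypic change*. It is aimed at evolutionary ecologists and
quantitative geneticists assessing species' vulnerability to sustained
directional change (e.g. climate-driven phenological shifts).

## The model

A population of `n` diploid individuals carries a trait determined by `k`
additive loci (continuum-of-alleles): genotype = sum of `2k` allelic
effects, phenotype `z` = genotype + `N(0, σ_e²)`. Each generation,
individuals survive an independent coin toss with Gaussian fitness

    w(z) = exp(−(z − θ)² / (2ω²)),

then survivors mate at random with replacement (no selfing) back to
carrying capacity; gametes recombine (Poisson(μ_r) crossovers) and mutate
(Poisson(kμ_m) mutations of additive effect `N(0, m²)`, with
`2kμ_m·m² = σ_m²` the new genetic variance per generation). After a
stabilising burn-in at θ = 0, the optimum moves by Δ_env per generation
until the population goes extinct or a generation cap is reached.

Starting conditions are drawn from meta-analytic distributions of natural
populations — σ_T² ~ truncated Exponential(0.018), h² ~ truncated
Weibull(1.6, 0.4), σ_m²/σ_e² ~ Gamma(1.1, 0.004), ω ~ U(0, 10),
Δ_env ~ U(0, 0.3) — so an ensemble of runs numerically integrates over the
space of phenotypes and selection regimes seen in the wild.

Per population, the package computes trait-scaled (haldane-like) rates of
environmental and phenotypic change, the lag behind the optimum, times to
extinction and to the first >50%-mortality generation, and the theoretical
critical rate of environmental change

    k_c = σ_g²/(σ_g² + V_s) · sqrt((V_s + σ_g²) · ln(N_o·ω / sqrt(V_s + σ_g²))),
    V_s = ω² + σ_e²,

scaled by the equilibrium trait sd. Ensemble-level summaries include
equal-count binned medians, survivor classification, a log-log quadratic
regression of extinction time on lag, and the mutation-adjusted weighted
median rate of the survivors. A phenology module estimates standardized
rates of change from longitudinal field series (year, mean, sd) and ships
a synthetic panel generator so every analysis step is testable offline.

## Worked example

```python
import optimtrack as ot

cfg, der = ot.make_config(seed=7, k_loci=100, mu_r=3.0)
print(f"omega={cfg.omega:.3f}  delta_env={cfg.delta_env:.4f}  "
      f"sigma_T2={cfg.sigma_T2:.4f}  h2={cfg.h2:.3f}  "
      f"mut_scalar={cfg.mut_scalar:.5f}")

traj = ot.run(cfg, der, stab_gens=2000, max_dir_gens=2000)
m = ot.compute_metrics(traj)
print(f"equilibrium trait sd: {traj.eq_trait_sd:.4f}")
print(f"scaled environmental rate: {m.rate_env:.3f} sd/gen")
print(f"scaled phenotypic rate:    {m.rate_trait:.3f} sd/gen")
print(f"lag rate:                  {m.lag_rate:.3f} sd/gen")
print(f"generations to extinction: {m.gens_to_extinction}")
print(f"generations to >50% mortality: {m.gens_to_50pct}")
print(f"critical rate k_c:         {m.kc:.4f} sd/gen")
```

prints

```
omega=2.150  delta_env=0.2015  sigma_T2=0.0127  h2=0.301  mut_scalar=0.00741
equilibrium trait sd: 0.2502
scaled environmental rate: 0.805 sd/gen
scaled phenotypic rate:    0.151 sd/gen
lag rate:                  0.655 sd/gen
generations to extinction: 46
generations to >50% mortality: 14
critical rate k_c:         0.1062 sd/gen
```

This population's environment moves at 0.805 trait sd per generation —
far above its critical rate of ~0.11 — so its phenotype responds at only
0.151 sd/gen, the gap to the optimum grows by 0.655 sd every generation
(rate_env − rate_trait = lag rate, by construction), mortality passes 50%
at directional generation 14, and the population is extinct by
generation 46.

Ensembles and field-data rates are also available from the shell:

```sh
optimtrack ensemble --seed 1 --out-dir results/      # scaled default design
optimtrack pheno synth --n 25 --years 29 --seed 0 --out panel.csv
optimtrack pheno rates --in panel.csv --out rates.csv
```

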