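"""Individual-based simulation of one population tracking a moving optimum.

The model: ``n_pop`` diploid individuals carry ``k`` additive loci
(continuum-of-alleles; a genotypic value is the sum of all ``2k`` allelic
effects). Each generation

1. phenotypes = genotypes + fresh N(0, sigma_e2) environmental deviations;
2. Gaussian viability selection around the current optimum ``theta``:
   each individual survives an independent coin toss with probability
   ``exp(-(z - theta)^2 / (2 omega^2))`` (fitness 1 at the optimum);
3. survivors mate at random with replacement (no selfing) until the
   population is returned to exactly ``n_pop`` offspring; every parent
   contributes one recombined gamete per offspring (Poisson(mu_r)
   crossovers at uniform inter-locus boundaries) with Poisson(k*mu_m)
   mutations, each adding a N(0, m2) increment to an allele, so mutation
   injects 2*k*mu_m*m2 = sigma_m2 of genetic variance per generation.

A run is 10,000 generations of stabilising selection (optimum fixed at 0,
bringing the population to mutation-selection balance) followed by
directional selection: the optimum moves by ``delta_env`` every generation,
independently of the population's response, until extinction (fewer than
two survivors, since selfing is prohibited) or a generation cap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._kernels import assemble_gametes
from .params import PopulationConfig, DerivedVariances, derive_variances

__all__ = [
    "ExtinctionError",
    "PopulationState",
    "Trajectory",
    "init_population",
    "phenotypes",
    "fitness",
    "select_survivors",
    "make_gamete",
    "reproduce",
    "run",
]

RECORD_STRIDE = 100          # thinning stride outside the full-record windows
STAB_TAIL_FULL = 1000        # last stabilising generations recorded in full
DIR_FULL = 10_000            # directional generations recorded in full


class ExtinctionError(RuntimeError):
    """Raised when fewer than two distinct survivors remain to mate."""


@dataclass
class PopulationState:
    """Allelic state of a living population.

    ``alleles`` has shape ``(n_current, 2, k)``: individuals x haplotypes x
    loci, in trait units. The genotypic value of individual ``i`` is
    ``alleles[i].sum()``.
    """

    alleles: np.ndarray
    optimum: float = 0.0
    generation: int = 0
    phase: str = "stabilising"

    @property
    def n_current(self) -> int:
        return self.alleles.shape[0]

    @property
    def k_loci(self) -> int:
        return self.alleles.shape[2]

    @property
    def genotypes(self) -> np.ndarray:
        return self.alleles.sum(axis=(1, 2), dtype=np.float64)


@dataclass
class Trajectory:
    """Outcome of one full simulation run.

    ``records`` is a per-generation table (possibly thinned for very long
    runs; all summary fields below are exact accumulators unaffected by
    thinning). Directional-phase generations are counted from 1; a
    population that never reached the directional phase has
    ``pre_directional_extinct=True`` and ``extinct_at=0``.
    """

    config: PopulationConfig
    derived: DerivedVariances
    stab_gens: int
    max_dir_gens: int
    records: Optional[pd.DataFrame]
    extinct_at: Optional[int]            # directional generation of extinction
    pre_directional_extinct: bool
    survived_cap: bool
    directional_gens: int                # directional generations survived
    eq_geno_var: float                   # mean geno var, stabilising tail
    eq_trait_sd: float                   # mean pheno sd, stabilising tail
    mean_survivors_directional: float
    mean_survivors_stab_tail: float
    onset_pheno_mean: float              # census mean at directional onset
    final_pheno_mean: float              # census mean, last directional gen
    final_optimum: float
    lag_sum: float                       # sum of (optimum - census mean)
    first_mort50_gen: Optional[int]      # first directional gen, mortality > 0.5
    pheno_mean_at_mort50: float = math.nan

    def __post_init__(self) -> None:
        assert self.survived_cap != (self.extinct_at is not None)


def init_population(
    config: PopulationConfig,
    derived: DerivedVariances | None = None,
    rng: np.random.Generator | None = None,
) -> PopulationState:
    """Found a population of ``n_pop`` individuals at the optimum.

    Each of the 2k allelic values is drawn i.i.d. N(0, sigma_g2_init / 2k),
    so the expected initial genetic variance equals h2 * sigma_T2. The
    stabilising burn-in then takes the population to its own
    mutation-selection-drift equilibrium.
    """
    derived = derived or derive_variances(config)
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n, k = config.n_pop, config.k_loci
    sd0 = math.sqrt(derived.sigma_g2_init / (2 * k))
    alleles = rng.normal(0.0, sd0, size=(n, 2, k)) if sd0 > 0 else np.zeros((n, 2, k))
    return PopulationState(alleles=alleles)


def phenotypes(
    state: PopulationState,
    derived: DerivedVariances,
    rng: np.random.Generator,
) -> np.ndarray:
    """Phenotypes = genotypes + fresh N(0, sigma_e2) deviations."""
    noise_sd = math.sqrt(derived.sigma_e2)
    return state.genotypes + rng.normal(0.0, noise_sd, size=state.n_current)


def fitness(phenotype, optimum: float, omega: float):
    """Gaussian survival probability, scaled to 1 at the optimum.

    ``omega = 0`` is the degenerate strongest-selection limit: fitness is
    the indicator of an exact match with the optimum (so populations drawn
    with tiny omega can die out during the burn-in, as a handful do).
    """
    z = np.asarray(phenotype, dtype=float)
    if omega == 0:
        w = (z == optimum).astype(float)
    elif math.isinf(omega):
        w = np.ones_like(z)
    else:
        d = z - optimum
        w = np.exp(-(d * d) / (2.0 * omega * omega))
    return float(w) if np.isscalar(phenotype) else w


def select_survivors(
    pheno: np.ndarray,
    optimum: float,
    omega: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Viability selection: independent coin toss per individual.

    Returns the indices of survivors; expected count is the sum of
    individual fitnesses.
    """
    w = fitness(pheno, optimum, omega)
    return np.nonzero(rng.random(pheno.shape[0]) < w)[0]


def make_gamete(
    parent_alleles: np.ndarray,
    mu_r: float,
    mu_m: float,
    m2: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One recombined, mutated haploid gamete from a (2, k) parent.

    Crossover count ~ Poisson(mu_r), positions uniform over the k-1
    inter-locus boundaries (two crossovers in the same boundary cancel);
    the copy starts from either haplotype with probability 1/2. Mutation
    count ~ Poisson(k * mu_m); mutated loci are chosen uniformly without
    replacement and each receives an additive N(0, m2) increment
    (continuum-of-alleles).
    """
    k = parent_alleles.shape[1]
    n_xo = rng.poisson(mu_r)
    pos = rng.integers(0, k - 1, size=n_xo) if (k > 1 and n_xo > 0) else np.empty(0, int)
    start = int(rng.integers(0, 2))
    flips = np.bincount(pos, minlength=k - 1) if k > 1 else np.empty(0, int)
    src = np.empty(k, dtype=np.int64)
    src[0] = start
    if k > 1:
        src[1:] = (start + np.cumsum(flips)) & 1
    gamete = parent_alleles[src, np.arange(k)].astype(float)
    n_mut = min(int(rng.poisson(k * mu_m)), k)
    if n_mut:
        loci = rng.choice(k, size=n_mut, replace=False)
        gamete[loci] += rng.normal(0.0, math.sqrt(m2), size=n_mut)
    return gamete


def reproduce(
    alleles: np.ndarray,
    survivors: np.ndarray,
    n_pop: int,
    mu_r: float,
    mu_m: float,
    m2: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Random mating with replacement back to carrying capacity.

    For each of ``n_pop`` offspring: draw two *distinct* parents uniformly
    with replacement from the survivors (selfing prohibited); each
    contributes one gamete via :func:`make_gamete`.

    Raises
    ------
    ExtinctionError
        With fewer than two survivors no non-self pair can form.
    """
    survivors = np.asarray(survivors)
    ns = survivors.size
    if ns < 2:
        raise ExtinctionError(f"{ns} survivor(s): population is extinct")
    k = alleles.shape[2]
    offspring = np.empty((n_pop, 2, k))
    for i in range(n_pop):
        pa = int(rng.integers(0, ns))
        pb = int(rng.integers(0, ns))
        while pb == pa:
            pb = int(rng.integers(0, ns))
        offspring[i, 0] = make_gamete(alleles[survivors[pa]], mu_r, mu_m, m2, rng)
        offspring[i, 1] = make_gamete(alleles[survivors[pb]], mu_r, mu_m, m2, rng)
    return offspring


# ---------------------------------------------------------------------------
# Fast generation step used by run(): identical model, batched RNG.
# Crossover and mutation counts are generated by Poisson splitting (one
# Poisson total over all 2*n_pop gametes, events assigned to gametes and
# positions uniformly), which is distributionally identical to the
# per-gamete Poisson draws in make_gamete.
# ---------------------------------------------------------------------------


def _reproduce_batch(A, surv_idx, n_pop, k, mu_r, mu_m, m_sd, rng, out):
    """Fill ``out`` (n_pop, 2k) with the next generation; return offspring genotypes."""
    ns = surv_idx.size
    G = 2 * n_pop
    pair = rng.integers(0, ns, size=G)
    pa, pb = pair[:n_pop], pair[n_pop:]
    bad = pa == pb
    while bad.any():
        pb[bad] = rng.integers(0, ns, size=int(bad.sum()))
        bad = pa == pb
    parents = surv_idx[pair]

    # A single uniform draw on [0, G*(k-1)) decomposes into independent
    # uniform (gamete, boundary) coordinates.
    if k > 1 and mu_r > 0:
        t_xo = int(rng.poisson(mu_r * G))
        u = rng.integers(0, G * (k - 1), size=t_xo)
        gid = u // (k - 1)
        key = np.sort((gid * k + u % (k - 1)).astype(np.int32))
        xo_pos = (key % k).astype(np.int64)
        counts = np.bincount(gid, minlength=G)
    else:
        xo_pos = np.empty(0, dtype=np.int64)
        counts = np.zeros(G, dtype=np.int64)
    xo_off = np.zeros(G + 1, dtype=np.int64)
    np.cumsum(counts, out=xo_off[1:])
    start = rng.integers(0, 2, size=G)

    gsum = np.empty(G, dtype=np.float64)
    assemble_gametes(A, parents, start, xo_off, xo_pos, out, gsum)

    # Mutations: uniform (gamete, locus) targets; within-gamete duplicate
    # loci are redrawn so loci mutate without replacement.
    t_mut = int(rng.poisson(k * mu_m * G))
    if t_mut:
        keys = rng.integers(0, G * k, size=t_mut)
        if t_mut > 1:
            ks = np.sort(keys)
            while np.any(ks[1:] == ks[:-1]):
                uniq, first = np.unique(keys, return_index=True)
                dup = np.ones(keys.size, dtype=bool)
                dup[first] = False
                mg_dup = keys[dup] // k
                keys[dup] = mg_dup * k + rng.integers(0, k, size=int(dup.sum()))
                ks = np.sort(keys)
        mg = keys // k
        ml = keys % k
        vals = rng.normal(0.0, m_sd, size=t_mut)
        row = np.where(mg < n_pop, mg, mg - n_pop)
        col = np.where(mg < n_pop, ml, ml + k)
        np.add.at(out.reshape(-1), row * (2 * k) + col, vals.astype(out.dtype))
        np.add.at(gsum, mg, vals)
    return gsum[:n_pop] + gsum[n_pop:]


def _should_record(phase: str, g: int, phase_len: int) -> bool:
    if phase == "stabilising":
        return g > phase_len - STAB_TAIL_FULL or g % RECORD_STRIDE == 0
    return g <= DIR_FULL or g % RECORD_STRIDE == 0


_REC_COLS = (
    "generation", "phase", "optimum", "pheno_mean", "pheno_var", "geno_mean",
    "geno_var", "n_survivors", "mortality", "survivor_pheno_mean",
)


def run(
    config: PopulationConfig,
    derived: DerivedVariances | None = None,
    stab_gens: int = 10_000,
    max_dir_gens: int = 240_000,
    rng: np.random.Generator | None = None,
    eq_window: int = STAB_TAIL_FULL,
    keep_records: bool = True,
    dtype=np.float32,
) -> Trajectory:
    """Simulate one population: stabilising burn-in, then directional selection.

    The optimum stays at 0 for ``stab_gens`` generations, then moves by
    ``config.delta_env`` per generation for up to ``max_dir_gens``
    generations or until extinction. Equilibrium summaries (``eq_geno_var``,
    ``eq_trait_sd``) are means over the final ``eq_window`` stabilising
    generations. Per-generation records are thinned beyond the full-record
    windows; every summary field of the returned :class:`Trajectory` is an
    exact accumulator.

    Alleles are held in ``dtype`` (float32 by default); all variance and
    mean accumulators are double precision.
    """
    derived = derived or derive_variances(config)
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n, k = config.n_pop, config.k_loci
    delta, omega = config.delta_env, config.omega
    eq_window = min(eq_window, stab_gens)
    noise_sd = math.sqrt(derived.sigma_e2)
    m_sd = math.sqrt(derived.m2)

    state0 = init_population(config, derived, rng)
    A = np.ascontiguousarray(state0.alleles.reshape(n, 2 * k), dtype=dtype)
    B = np.empty_like(A)
    geno = A.sum(axis=1, dtype=np.float64)

    recs: list[tuple] = []
    eq_gv_sum = eq_sd_sum = 0.0
    eq_count = 0
    stab_tail_surv_sum = 0.0
    dir_surv_sum = 0.0
    lag_sum = 0.0
    onset_mean = math.nan
    last_mean = math.nan
    last_opt = 0.0
    first_mort50: Optional[int] = None
    mean_at_mort50 = math.nan
    extinct_at: Optional[int] = None
    pre_dir_extinct = False
    dir_gens = 0

    for phase, phase_len in (("stabilising", stab_gens), ("directional", max_dir_gens)):
        extinct_here = False
        for g in range(1, phase_len + 1):
            opt = 0.0 if phase == "stabilising" else delta * g
            pheno = geno + rng.normal(0.0, noise_sd, size=n)
            # one-pass moments via dot products (means stay small relative to
            # double precision even at the largest optimum displacements)
            p_mean = float(pheno.sum()) / n
            p_var = float(pheno.dot(pheno)) / n - p_mean * p_mean
            g_mean = float(geno.sum()) / n
            g_var = float(geno.dot(geno)) / n - g_mean * g_mean

            if omega == 0:
                w = (pheno == opt).astype(float)
            else:
                d = pheno - opt
                w = np.exp(-(d * d) / (2.0 * omega * omega))
            surv = rng.random(n) < w
            ns = int(surv.sum())
            mortality = 1.0 - ns / n
            s_mean = float(pheno[surv].mean()) if ns else math.nan

            if phase == "stabilising":
                if g > stab_gens - eq_window:
                    eq_gv_sum += g_var
                    eq_sd_sum += math.sqrt(p_var)
                    eq_count += 1
                    stab_tail_surv_sum += ns
            else:
                if g == 1:
                    onset_mean = p_mean
                lag_sum += opt - p_mean
                dir_surv_sum += ns
                last_mean = p_mean
                last_opt = opt
                dir_gens = g
                if first_mort50 is None and mortality > 0.5:
                    first_mort50 = g
                    mean_at_mort50 = p_mean

            extinct_here = ns < 2
            if keep_records and (_should_record(phase, g, phase_len) or extinct_here):
                recs.append(
                    (g, phase, opt, p_mean, p_var, g_mean, g_var, ns, mortality, s_mean)
                )
            if extinct_here:
                if phase == "stabilising":
                    pre_dir_extinct = True
                    extinct_at = 0
                else:
                    extinct_at = g
                break

            surv_idx = np.nonzero(surv)[0]
            geno = _reproduce_batch(
                A, surv_idx, n, k, config.mu_r, config.mu_m, m_sd, rng, B
            )
            A, B = B, A
        if extinct_here:
            break

    records = None
    if keep_records:
        records = pd.DataFrame.from_records(recs, columns=_REC_COLS)

    return Trajectory(
        config=config,
        derived=derived,
        stab_gens=stab_gens,
        max_dir_gens=max_dir_gens,
        records=records,
        extinct_at=extinct_at,
        pre_directional_extinct=pre_dir_extinct,
        survived_cap=extinct_at is None,
        directional_gens=0 if pre_dir_extinct else dir_gens,
        eq_geno_var=eq_gv_sum / eq_count if eq_count else math.nan,
        eq_trait_sd=eq_sd_sum / eq_count if eq_count else math.nan,
        mean_survivors_directional=(
            dir_surv_sum / dir_gens if dir_gens else math.nan
        ),
        mean_survivors_stab_tail=(
            stab_tail_surv_sum / eq_count if eq_count else math.nan
        ),
        onset_pheno_mean=onset_mean,
        final_pheno_mean=last_mean,
        final_optimum=last_opt,
        lag_sum=lag_sum,
        first_mort50_gen=first_mort50,
        pheno_mean_at_mort50=mean_at_mort50,
    )
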