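"""Simulator building blocks and full-run behaviour."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from optimtrack import (
    DerivedVariances,
    ExtinctionError,
    derive_variances,
    fitness,
    init_population,
    make_gamete,
    phenotypes,
    reproduce,
    run,
    select_survivors,
)
from optimtrack.simulate import PopulationState

from conftest import small_config


class TestInitPopulation:
    def test_initial_genetic_variance(self):
        cfg, der = small_config(sigma_T2=0.04, h2=0.5, n_pop=20_000, k_loci=50)
        state = init_population(cfg, der, np.random.default_rng(0))
        gv = state.genotypes.var()
        assert gv == pytest.approx(der.sigma_g2_init, rel=0.05)

    def test_zero_variance_gives_zero_genotypes(self):
        cfg, der = small_config()
        d0 = DerivedVariances(0.0, der.sigma_e2, der.sigma_m2, der.m2)
        state = init_population(cfg, d0, np.random.default_rng(0))
        assert np.all(state.alleles == 0)
        assert np.all(state.genotypes == 0)

    def test_deterministic_from_seed(self):
        cfg, der = small_config()
        a = init_population(cfg, der, np.random.default_rng(3)).alleles
        b = init_population(cfg, der, np.random.default_rng(3)).alleles
        np.testing.assert_array_equal(a, b)


class TestPhenotypes:
    def test_no_environmental_variance(self, rng):
        cfg, der = small_config()
        state = init_population(cfg, der, rng)
        d0 = DerivedVariances(der.sigma_g2_init, 0.0, der.sigma_m2, der.m2)
        np.testing.assert_allclose(phenotypes(state, d0, rng), state.genotypes)

    def test_mean_and_variance_additivity(self, rng):
        cfg, der = small_config(n_pop=50_000, sigma_T2=0.04, h2=0.5)
        state = init_population(cfg, der, rng)
        ph = phenotypes(state, der, rng)
        gv = state.genotypes.var()
        assert ph.mean() == pytest.approx(state.genotypes.mean(), abs=4 * math.sqrt(der.sigma_e2 / cfg.n_pop))
        assert ph.var() == pytest.approx(gv + der.sigma_e2, rel=0.05)


class TestFitness:
    @pytest.mark.parametrize(
        "pheno,opt,omega,expected",
        [
            (0.3, 0.3, 1.0, 1.0),                      # at the optimum
            (1.0, 0.0, 1.0, math.exp(-0.5)),           # one fitness sd away
            (5.0, 0.0, math.inf, 1.0),                 # neutral limit
            (0.0, 0.0, 0.0, 1.0),                      # omega=0: exact match
            (1e-9, 0.0, 0.0, 0.0),                     # omega=0: any mismatch
        ],
    )
    def test_pointwise(self, pheno, opt, omega, expected):
        assert fitness(pheno, opt, omega) == pytest.approx(expected)

    def test_vectorized_in_unit_interval(self, rng):
        z = rng.normal(0, 1, 1000)
        w = fitness(z, 0.2, 0.7)
        assert np.all((w > 0) & (w <= 1))


class TestSelection:
    def test_all_at_optimum_survive(self, rng):
        idx = select_survivors(np.zeros(500), 0.0, 1.0, rng)
        assert idx.size == 500

    def test_expected_survivor_count(self, rng):
        z = rng.normal(0.0, 0.2, 300)
        w = fitness(z, 0.1, 0.25)
        counts = [select_survivors(z, 0.1, 0.25, rng).size for _ in range(3000)]
        expected = w.sum()
        se = math.sqrt((w * (1 - w)).sum() / 3000)
        assert np.mean(counts) == pytest.approx(expected, abs=4 * se)

    def test_tiny_omega_kills_everyone(self, rng):
        z = rng.normal(0.0, 0.2, 1000)
        assert select_survivors(z, 0.0, 1e-6, rng).size == 0


class TestMakeGamete:
    def test_no_crossover_no_mutation_copies_a_haplotype(self, rng):
        parent = rng.normal(0, 1, size=(2, 30))
        gam = make_gamete(parent, mu_r=0.0, mu_m=0.0, m2=1e-4, rng=rng)
        assert np.array_equal(gam, parent[0]) or np.array_equal(gam, parent[1])

    def test_expected_mutation_count(self, rng):
        k, mu_m = 100, 1e-2
        parent = np.zeros((2, k))
        n_rep = 20_000
        total = sum(
            np.count_nonzero(make_gamete(parent, 3.0, mu_m, 1e-4, rng))
            for _ in range(n_rep)
        )
        lam = k * mu_m  # Poisson mean per haploid gamete
        se = math.sqrt(lam / n_rep)
        assert total / n_rep == pytest.approx(lam, abs=4 * se)

    def test_mutational_variance_injection(self, rng):
        # offspring of zero-valued parents carry only mutational variance:
        # Var(genotype) = 2 k mu_m m2 = sigma_m2
        k, mu_m = 100, 1e-3
        sigma_m2 = 1e-4
        m2 = sigma_m2 / (2 * k * mu_m)
        parent = np.zeros((2, k))
        n_rep = 20_000
        geno = np.array([
            make_gamete(parent, 3.0, mu_m, m2, rng).sum()
            + make_gamete(parent, 3.0, mu_m, m2, rng).sum()
            for _ in range(n_rep)
        ])
        assert geno.var() == pytest.approx(sigma_m2, rel=0.12)

    def test_recombination_mixes_haplotypes(self, rng):
        parent = np.stack([np.zeros(50), np.ones(50)])
        gams = np.array([
            make_gamete(parent, 3.0, 0.0, 1e-4, rng) for _ in range(500)
        ])
        # with mu_r=3 most gametes mix the two haplotypes
        mixed = np.mean([0 < g.sum() < 50 for g in gams])
        assert mixed > 0.7
        # and every allele is copied, never invented
        assert np.all((gams == 0) | (gams == 1))


class TestReproduce:
    def test_population_returned_to_carrying_capacity(self, rng):
        cfg, der = small_config(n_pop=120)
        state = init_population(cfg, der, rng)
        off = reproduce(state.alleles, np.arange(40), 120, 3.0, 1e-4, der.m2, rng)
        assert off.shape == (120, 2, cfg.k_loci)

    def test_two_survivors_parent_everyone(self, rng):
        # distinguishable parents: constant allele values 1 and 2
        k = 10
        alleles = np.zeros((5, 2, k))
        alleles[3] = 1.0
        alleles[4] = 2.0
        off = reproduce(alleles, np.array([3, 4]), 50, 0.0, 0.0, 1e-4, rng)
        sums = off.sum(axis=(1, 2))
        assert np.all(sums == 10 + 20)  # one gamete from each parent, always

    def test_no_directional_bias(self, rng):
        cfg, der = small_config(n_pop=400, k_loci=10)
        state = init_population(cfg, der, rng)
        surv = np.arange(100)
        parent_mean = state.genotypes[surv].mean()
        means = [
            reproduce(state.alleles, surv, 400, 3.0, 0.0, der.m2, rng)
            .sum(axis=(1, 2))
            .mean()
            for _ in range(60)
        ]
        se = np.std(means) / math.sqrt(len(means))
        assert np.mean(means) == pytest.approx(parent_mean, abs=4 * se + 1e-9)

    @pytest.mark.parametrize("n_survivors", [0, 1])
    def test_extinction_signalled(self, rng, n_survivors):
        cfg, der = small_config()
        state = init_population(cfg, der, rng)
        with pytest.raises(ExtinctionError):
            reproduce(
                state.alleles, np.arange(n_survivors), cfg.n_pop,
                3.0, 1e-4, der.m2, rng,
            )


class TestRun:
    def test_neutral_stabilising_survives_near_zero(self):
        cfg, der = small_config(omega=10.0, delta_env=0.0, n_pop=300, seed=5)
        traj = run(cfg, der, stab_gens=400, max_dir_gens=100)
        assert traj.survived_cap and traj.extinct_at is None
        # bounded random walk near the optimum
        assert abs(traj.final_pheno_mean) < 5 * traj.eq_trait_sd

    def test_fast_environmental_change_goes_extinct(self):
        cfg, der = small_config(
            omega=0.5, delta_env=0.3, sigma_T2=0.02, n_pop=300, seed=6
        )
        traj = run(cfg, der, stab_gens=200, max_dir_gens=5000)
        assert not traj.survived_cap
        assert traj.extinct_at is not None and traj.extinct_at < 1000
        assert traj.directional_gens == traj.extinct_at

    def test_variance_accounting(self):
        cfg, der = small_config(omega=5.0, delta_env=0.0, n_pop=1000, seed=7)
        traj = run(cfg, der, stab_gens=500, max_dir_gens=0)
        rec = traj.records
        resid = rec["pheno_var"] - rec["geno_var"] - der.sigma_e2
        # per-generation noise-variance estimates scatter ~ sqrt(2/n)
        assert abs(resid.mean()) < 3 * der.sigma_e2 * math.sqrt(2 / cfg.n_pop)

    def test_heritability_calibration_at_start(self):
        cfg, der = small_config(h2=0.6, sigma_T2=0.05, n_pop=2000, seed=8)
        traj = run(cfg, der, stab_gens=1, max_dir_gens=0)
        first = traj.records.iloc[0]
        assert first["geno_var"] / first["pheno_var"] == pytest.approx(0.6, abs=0.06)

    def test_mutational_variance_input_under_near_neutrality(self):
        # omega = 10 with a tiny trait variance is effectively neutral;
        # genetic variance should grow ~ sigma_m2 per generation at first.
        # mu_m is raised so the input comes from many small mutations (the
        # default rare-large-effect regime makes a 60-generation regression
        # hopelessly skewed even though its expectation is exact).
        cfg, der = small_config(
            omega=10.0, delta_env=0.0, sigma_T2=0.09, h2=0.01,
            mut_scalar=0.1, n_pop=500, k_loci=50, mu_m=1e-2, seed=9,
        )
        traj = run(cfg, der, stab_gens=60, max_dir_gens=0)
        rec = traj.records
        slope = np.polyfit(rec["generation"], rec["geno_var"], 1)[0]
        assert slope == pytest.approx(der.sigma_m2, rel=0.2)

    def test_variance_burst_at_directional_onset(self):
        # moving the optimum initially inflates genetic variance over its
        # stabilising-selection equilibrium value
        cfg, der = small_config(
            omega=1.0, delta_env=0.05, sigma_T2=0.04, h2=0.5,
            mut_scalar=0.01, n_pop=500, k_loci=50, seed=10,
        )
        traj = run(cfg, der, stab_gens=1500, max_dir_gens=400)
        rec = traj.records
        dir_var = rec.loc[rec["phase"] == "directional", "geno_var"]
        assert dir_var.iloc[100:].mean() > traj.eq_geno_var

    def test_deterministic_trajectories(self):
        cfg, der = small_config(seed=11)
        a = run(cfg, der, stab_gens=120, max_dir_gens=80)
        b = run(cfg, der, stab_gens=120, max_dir_gens=80)
        pd.testing.assert_frame_equal(a.records, b.records)
        assert a.eq_geno_var == b.eq_geno_var
        assert a.final_pheno_mean == b.final_pheno_mean

    def test_pre_directional_extinction_flagged(self):
        cfg, der = small_config(omega=0.001, sigma_T2=0.04, n_pop=100, seed=12)
        traj = run(cfg, der, stab_gens=200, max_dir_gens=100)
        assert traj.pre_directional_extinct
        assert traj.extinct_at == 0 and not traj.survived_cap
        assert traj.directional_gens == 0


@settings(max_examples=15, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 2**20),
    h2=st.floats(0.05, 0.95),
    omega=st.floats(0.5, 10.0),
    delta=st.floats(0.0, 0.3),
)
def test_run_invariants_property(seed, h2, omega, delta):
    """Any short run keeps its bookkeeping invariants."""
    cfg, der = small_config(
        h2=h2, omega=omega, delta_env=delta, n_pop=60, k_loci=8, seed=seed
    )
    traj = run(cfg, der, stab_gens=40, max_dir_gens=40)
    assert traj.survived_cap != (traj.extinct_at is not None)
    rec = traj.records
    assert (rec["pheno_var"] >= 0).all() and (rec["geno_var"] >= 0).all()
    np.testing.assert_allclose(
        rec["mortality"], 1 - rec["n_survivors"] / cfg.n_pop
    )
    assert rec["n_survivors"].between(0, cfg.n_pop).all()
    if traj.extinct_at:
        assert rec["n_survivors"].iloc[-1] < 2
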