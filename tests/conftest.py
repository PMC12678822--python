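import numpy as np
import pytest

from optimtrack import PopulationConfig, derive_variances


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def small_config(
    sigma_T2=0.04,
    h2=0.5,
    omega=2.0,
    delta_env=0.05,
    mut_scalar=0.005,
    k_loci=20,
    mu_r=3.0,
    n_pop=200,
    mu_m=1e-4,
    seed=99,
):
    """A cheap, hand-set population for unit tests."""
    cfg = PopulationConfig(
        sigma_T2=sigma_T2,
        h2=h2,
        omega=omega,
        delta_env=delta_env,
        mut_scalar=mut_scalar,
        k_loci=k_loci,
        mu_r=mu_r,
        n_pop=n_pop,
        mu_m=mu_m,
        seed=seed,
    )
    return cfg, derive_variances(cfg)
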