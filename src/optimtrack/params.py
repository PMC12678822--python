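"""Empirically calibrated parameter space for the simulated populations.

A simulated population is defined by five randomly drawn quantities —
phenotypic variance :math:`\\sigma_T^2`, broad-sense heritability
:math:`h^2`, width of the Gaussian fitness function :math:`\\omega`,
per-generation optimum shift :math:`\\Delta_{env}`, and the mutational
heritability :math:`\\sigma_m^2/\\sigma_e^2` ("mutation scalar") — plus a
fixed genetic architecture (``k_loci`` equivalent diploid loci, mean
recombination rate ``mu_r``, per-allele mutation probability ``mu_m`` and
carrying capacity ``n_pop``).

The sampling densities are meta-analytic fits from field studies of
natural populations:

* :math:`\\sigma_T^2` ~ Exponential(mean 0.018) truncated to [0.01, 0.09]
  (log-scale trait variance, so results are scale-free),
* :math:`h^2` ~ Weibull(shape 1.6, scale 0.4) truncated to [0.01, 0.99],
* :math:`\\sigma_m^2/\\sigma_e^2` ~ Gamma(shape 1.1, scale 0.004),
* :math:`\\omega` ~ U(0, 10) and :math:`\\Delta_{env}` ~ U(0, 0.3),
  calibrated so realized directional-selection intensities resemble the
  log-normal(-2.56, 1.19) distribution observed in selection meta-analyses.

Truncation is performed by rejection (redraw), never clipping, so no point
mass accumulates at the bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, fields

import numpy as np
from scipy import stats

__all__ = [
    "PopulationConfig",
    "DerivedVariances",
    "sample_phenotypic_variance",
    "sample_heritability",
    "sample_mut_scalar",
    "sample_selection_widths",
    "mut_scalar_pdf",
    "make_config",
    "derive_variances",
    "truncated_exponential_median",
    "directional_selection_reference",
    "read_config",
    "write_config",
]

# Meta-analytic density parameters (see module docstring).
SIGMA_T2_MEAN = 0.018
SIGMA_T2_BOUNDS = (0.01, 0.09)
H2_SHAPE, H2_SCALE = 1.6, 0.4
H2_BOUNDS = (0.01, 0.99)
MUT_SCALAR_SHAPE, MUT_SCALAR_SCALE = 1.1, 0.004
OMEGA_RANGE = (0.0, 10.0)
DELTA_ENV_RANGE = (0.0, 0.3)
K_LOCI_CHOICES = (100, 500, 1000, 5000)
MU_R_CHOICES = (3.0, 5.0)
DEFAULT_N_POP = 1000
DEFAULT_MU_M = 1e-4

#: Log-normal fit to standardized directional-selection gradients from field
#: meta-analyses. Not a sampled input: used only to sanity-check realized
#: selection intensities produced by the uniform (omega, delta_env) scheme.
directional_selection_reference = stats.lognorm(s=1.19, scale=math.exp(-2.56))


@dataclass(frozen=True)
class PopulationConfig:
    """Fixed starting conditions of one simulated population.

    Attributes
    ----------
    sigma_T2 : float
        Phenotypic variance of the trait (log-scale trait units squared).
    h2 : float
        Broad-sense heritability, sigma_g2 / sigma_T2.
    omega : float
        Standard deviation of the Gaussian fitness function (trait units);
        smaller means stronger stabilising selection.
    delta_env : float
        Per-generation shift of the environmental optimum during the
        directional phase (trait units).
    mut_scalar : float
        Mutational heritability sigma_m2 / sigma_e2.
    k_loci : int
        Number of equivalent diploid loci underlying the trait.
    mu_r : float
        Mean recombination (crossover) events per haploid genome per meiosis.
    n_pop : int
        Carrying capacity; the population is returned to this size every
        generation.
    mu_m : float
        Per-allele mutation probability per generation.
    seed : int
        RNG seed that makes a run of this population reproducible.
    """

    sigma_T2: float
    h2: float
    omega: float
    delta_env: float
    mut_scalar: float
    k_loci: int
    mu_r: float
    n_pop: int = DEFAULT_N_POP
    mu_m: float = DEFAULT_MU_M
    seed: int = 0

    def __post_init__(self) -> None:
        if not (SIGMA_T2_BOUNDS[0] <= self.sigma_T2 <= SIGMA_T2_BOUNDS[1]):
            raise ValueError(f"sigma_T2={self.sigma_T2} outside {SIGMA_T2_BOUNDS}")
        if not (H2_BOUNDS[0] <= self.h2 <= H2_BOUNDS[1]):
            raise ValueError(f"h2={self.h2} outside {H2_BOUNDS}")
        if not (0.0 <= self.omega <= OMEGA_RANGE[1]):
            raise ValueError(f"omega={self.omega} outside [0, {OMEGA_RANGE[1]}]")
        if not (0.0 <= self.delta_env <= DELTA_ENV_RANGE[1]):
            raise ValueError(f"delta_env={self.delta_env} outside [0, {DELTA_ENV_RANGE[1]}]")
        if self.mut_scalar <= 0:
            raise ValueError("mut_scalar must be > 0")
        if self.k_loci < 1:
            raise ValueError("k_loci must be >= 1")
        if self.mu_r < 0 or self.mu_m < 0:
            raise ValueError("mu_r and mu_m must be >= 0")
        if self.n_pop < 1:
            raise ValueError("n_pop must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationConfig":
        names = {f.name for f in fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in names})


@dataclass(frozen=True)
class DerivedVariances:
    """Variance components derived from a :class:`PopulationConfig`.

    sigma_g2_init = h2 * sigma_T2 (initial genetic variance),
    sigma_e2 = (1 - h2) * sigma_T2 (environmental variance, held fixed),
    sigma_m2 = mut_scalar * sigma_e2 (new mutational variance per generation),
    m2 = sigma_m2 / (2 * k_loci * mu_m) (per-mutation effect variance, so
    that the genomic mutation rate 2*k*mu_m injects exactly sigma_m2).
    """

    sigma_g2_init: float
    sigma_e2: float
    sigma_m2: float
    m2: float

    def to_dict(self) -> dict:
        return asdict(self)


def derive_variances(config: PopulationConfig) -> DerivedVariances:
    """Compute the internal variance components implied by a config."""
    sigma_g2_init = config.h2 * config.sigma_T2
    sigma_e2 = (1.0 - config.h2) * config.sigma_T2
    sigma_m2 = config.mut_scalar * sigma_e2
    m2 = sigma_m2 / (2.0 * config.k_loci * config.mu_m)
    return DerivedVariances(sigma_g2_init, sigma_e2, sigma_m2, m2)


def _truncated(rng: np.random.Generator, draw, lo: float, hi: float, size):
    """Rejection-sample `draw(rng, m)` into [lo, hi]."""
    if lo == hi:
        # Degenerate interval: the distribution collapses to a point mass.
        return lo if size is None else np.full(size, lo)
    n = 1 if size is None else int(np.prod(size))
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = max(n - filled, 16)
        x = draw(rng, 2 * m)
        x = x[(x >= lo) & (x <= hi)]
        take = min(x.size, n - filled)
        out[filled:filled + take] = x[:take]
        filled += take
    if size is None:
        return float(out[0])
    return out.reshape(size)


def sample_phenotypic_variance(rng: np.random.Generator, size=None, bounds=SIGMA_T2_BOUNDS):
    """Draw sigma_T2 ~ Exponential(mean 0.018) truncated to ``bounds``.

    The exponential parameter is the *mean* (the meta-analytic sample means
    are 0.017-0.022, i.e. on the scale of the mean, not the rate). Equal
    bounds collapse the draw to that point.
    """
    lo, hi = bounds
    return _truncated(
        rng, lambda r, m: r.exponential(SIGMA_T2_MEAN, m), lo, hi, size
    )


def sample_heritability(rng: np.random.Generator, size=None, bounds=H2_BOUNDS):
    """Draw h2 ~ Weibull(shape 1.6, scale 0.4) truncated to ``bounds``."""
    lo, hi = bounds
    return _truncated(
        rng, lambda r, m: H2_SCALE * r.weibull(H2_SHAPE, m), lo, hi, size
    )


def sample_mut_scalar(rng: np.random.Generator, size=None):
    """Draw sigma_m2/sigma_e2 ~ Gamma(shape 1.1, scale 0.004); mean 0.0044."""
    x = rng.gamma(MUT_SCALAR_SHAPE, MUT_SCALAR_SCALE, size=size)
    return float(x) if size is None else x


def sample_selection_widths(rng: np.random.Generator, size=None):
    """Draw (omega, delta_env) ~ U(0,10) x U(0,0.3), independent."""
    omega = rng.uniform(*OMEGA_RANGE, size=size)
    delta = rng.uniform(*DELTA_ENV_RANGE, size=size)
    if size is None:
        return float(omega), float(delta)
    return omega, delta


def mut_scalar_pdf(x):
    """Gamma(1.1, 0.004) density of the mutation scalar, p(sigma_m2/sigma_e2).

    Used as the importance weight when adjusting survivor rates to the
    mutational-heritability distribution of natural populations.

    Raises
    ------
    ValueError
        If any ``x`` is <= 0 (outside the support).
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("mut_scalar_pdf is defined for x > 0 only")
    p = stats.gamma.pdf(arr, a=MUT_SCALAR_SHAPE, scale=MUT_SCALAR_SCALE)
    return float(p) if np.isscalar(x) else p


def truncated_exponential_median(
    mean: float = SIGMA_T2_MEAN, bounds=SIGMA_T2_BOUNDS
) -> float:
    """Closed-form median of an exponential truncated to ``bounds``.

    Solves S(m) = (S(lo) + S(hi)) / 2 with S(x) = exp(-x/mean).
    """
    lo, hi = bounds
    s = 0.5 * (math.exp(-lo / mean) + math.exp(-hi / mean))
    return -mean * math.log(s)


def make_config(
    seed,
    k_loci: int,
    mu_r: float,
    n_pop: int = DEFAULT_N_POP,
    mu_m: float = DEFAULT_MU_M,
) -> tuple[PopulationConfig, DerivedVariances]:
    """Sample a fully specified population from the five input densities.

    A pure function of ``(seed, k_loci, mu_r, n_pop, mu_m)``: the same seed
    always yields the same configuration. ``seed`` may be an int or a
    :class:`numpy.random.SeedSequence`.
    """
    if isinstance(seed, np.random.SeedSequence):
        seq = seed
        seed_int = int(seq.generate_state(1)[0] % (2**31))
    else:
        seed_int = int(seed)
        seq = np.random.SeedSequence(seed_int)
    rng = np.random.default_rng(seq)
    sigma_T2 = sample_phenotypic_variance(rng)
    h2 = sample_heritability(rng)
    mut_scalar = sample_mut_scalar(rng)
    omega, delta_env = sample_selection_widths(rng)
    config = PopulationConfig(
        sigma_T2=sigma_T2,
        h2=h2,
        omega=omega,
        delta_env=delta_env,
        mut_scalar=mut_scalar,
        k_loci=int(k_loci),
        mu_r=float(mu_r),
        n_pop=int(n_pop),
        mu_m=float(mu_m),
        seed=seed_int,
    )
    return config, derive_variances(config)


def write_config(config: PopulationConfig, path) -> None:
    """Write a config as a flat key = value TOML file."""
    with open(path, "w") as fh:
        for key, val in config.to_dict().items():
            fh.write(f"{key} = {val!r}\n" if isinstance(val, str) else f"{key} = {val}\n")


def read_config(path) -> PopulationConfig:
    """Read a flat TOML config file written by :func:`write_config`."""
    import tomllib

    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return PopulationConfig.from_dict(data)
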