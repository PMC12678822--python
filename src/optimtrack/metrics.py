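"""Per-population derived statistics.

All rates are expressed in units of the population's *realized* equilibrium
phenotypic standard deviation (``eq_trait_sd``, the mean phenotypic sd over
the final stabilising window), i.e. approximately haldanes. Using the
realized sd rather than the drawn input sigma_T keeps the rates and the
critical-rate estimator internally consistent: both are measured on the
population the burn-in actually produced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from .simulate import Trajectory

__all__ = [
    "PopulationMetrics",
    "trait_rate",
    "lag_per_generation",
    "time_to_50pct",
    "trait_rate_50pct",
    "kc_estimate",
    "offspring_per_parent",
    "realized_selection_intensity",
    "compute_metrics",
]


@dataclass(frozen=True)
class PopulationMetrics:
    """Summary statistics of one simulated population.

    Rates are in trait-sd units per generation. ``lag_mean`` is the mean
    scaled gap between optimum and phenotypic mean; ``lag_rate`` is the
    per-generation growth of that gap (the quantity compared 1:1 against
    ``rate_env``). ``kc`` is the theoretical critical rate of environmental
    change; ``No`` the offspring per surviving parent entering it.
    """

    rate_trait: float
    rate_env: float
    lag_mean: float
    lag_rate: float
    gens_to_extinction: int
    gens_to_50pct: Optional[int]
    rate_trait_50pct: float
    survived_cap: bool
    kc: float
    No: float
    eq_geno_var: float
    eq_trait_sd: float
    pre_directional_extinct: bool

    def to_dict(self) -> dict:
        return asdict(self)


def _require_directional(traj: Trajectory) -> None:
    if traj.directional_gens < 1:
        raise ValueError("trajectory has no directional-phase generations")


def trait_rate(traj: Trajectory) -> float:
    """Trait-scaled rate of phenotypic change over the directional phase.

    (final census mean - onset census mean) / generations survived,
    divided by the equilibrium trait sd.
    """
    _require_directional(traj)
    return (
        (traj.final_pheno_mean - traj.onset_pheno_mean)
        / traj.directional_gens
        / traj.eq_trait_sd
    )


def lag_per_generation(traj: Trajectory) -> tuple[float, float]:
    """Scaled lag behind the optimum: ``(lag_mean, lag_rate)``.

    ``lag_mean`` averages the per-generation scaled gap
    (optimum - phenotypic mean) / eq_trait_sd over the directional phase.
    ``lag_rate`` is the net growth of the gap per generation; by
    construction ``lag_rate = rate_env - rate_trait``, so a population with
    no response at all falls on the 1:1 line against the scaled rate of
    environmental change, and a perfect tracker sits at 0.
    """
    _require_directional(traj)
    sd = traj.eq_trait_sd
    g = traj.directional_gens
    lag_mean = traj.lag_sum / g / sd
    gap_final = traj.final_optimum - traj.final_pheno_mean
    gap_onset = 0.0 - traj.onset_pheno_mean
    lag_rate = (gap_final - gap_onset) / g / sd
    return lag_mean, lag_rate


def time_to_50pct(traj: Trajectory) -> Optional[int]:
    """First directional generation with post-selection mortality > 50%.

    Few natural populations recover from losing half their number in one
    generation, so this is used as an alternative extinction cutoff.
    Returns ``None`` if mortality never exceeds 50%.
    """
    return traj.first_mort50_gen


def trait_rate_50pct(traj: Trajectory) -> float:
    """Trait-scaled rate with lifetime truncated at the >50%-mortality cutoff.

    Falls back to the full-lifetime rate for populations that never cross
    the cutoff.
    """
    _require_directional(traj)
    g50 = traj.first_mort50_gen
    if g50 is None:
        return trait_rate(traj)
    return (
        (traj.pheno_mean_at_mort50 - traj.onset_pheno_mean) / g50 / traj.eq_trait_sd
    )


def kc_estimate(
    eq_geno_var: float,
    sigma_e2: float,
    omega: float,
    No: float,
    eq_trait_sd: float,
) -> float:
    """Critical (maximum sustainable) rate of environmental change, in sd/gen.

    From quasi-deterministic quantitative-genetic theory of a population
    tracking a moving optimum:

        k_c = sigma_g2 / (sigma_g2 + V_s)
              * sqrt((V_s + sigma_g2) * ln(No * omega / sqrt(V_s + sigma_g2)))

    with ``V_s = omega**2 + sigma_e2`` and ``sigma_g2`` the genetic variance
    observed at mutation-selection balance. The raw trait-unit value is
    scaled by ``eq_trait_sd``. The derivation assumes effective population
    size stays constant while the environment moves (offspring per
    surviving parent ``No``).

    Returns 0 when ``sigma_g2`` is 0 and ``nan`` when the log argument is
    not positive (no sustainable rate of change exists) or ``omega <= 0``.
    """
    if eq_geno_var == 0:
        return 0.0
    if omega <= 0:
        return math.nan
    vs = omega * omega + sigma_e2
    tot = vs + eq_geno_var
    log_arg = No * omega / math.sqrt(tot)
    if log_arg <= 1.0:
        return math.nan
    kc = eq_geno_var / tot * math.sqrt(tot * math.log(log_arg))
    return kc / eq_trait_sd


def offspring_per_parent(traj: Trajectory, window: str = "directional") -> float:
    """Expected offspring per surviving parent, No.

    Under random mating with replacement back to carrying capacity,
    ``No = n_pop / (mean survivor count per generation)``. The averaging
    window is the directional phase (matching the constant-effective-size
    assumption of the critical-rate derivation); it falls back to the
    stabilising tail when no directional generations exist, or when
    ``window="stabilising"`` is requested for sensitivity checks.
    """
    if window == "directional" and traj.directional_gens >= 1:
        mean_surv = traj.mean_survivors_directional
    else:
        mean_surv = traj.mean_survivors_stab_tail
    return traj.config.n_pop / mean_surv


def realized_selection_intensity(traj: Trajectory) -> np.ndarray:
    """Standardized selection differentials per recorded directional generation.

    (survivor phenotypic mean - census phenotypic mean) / phenotypic sd.
    For Gaussian selection on a Gaussian trait the expected differential is
    sigma_T2 * (theta - mean) / (sigma_T2 + omega^2), scaled by sigma_T.
    The resulting distribution can be compared against the log-normal
    reference density of field-observed selection gradients
    (:data:`optimtrack.params.directional_selection_reference`).
    """
    if traj.records is None:
        raise ValueError("trajectory was run with keep_records=False")
    rec = traj.records
    d = rec[rec["phase"] == "directional"]
    return (
        (d["survivor_pheno_mean"] - d["pheno_mean"])
        / np.sqrt(d["pheno_var"])
    ).to_numpy()


def compute_metrics(traj: Trajectory) -> PopulationMetrics:
    """Assemble the full metric set for one trajectory.

    Populations extinct before the directional phase get ``nan`` rates and
    lag (they never experienced environmental change).
    """
    cfg, der = traj.config, traj.derived
    rate_env = cfg.delta_env / traj.eq_trait_sd if traj.eq_trait_sd else math.nan
    if traj.directional_gens >= 1:
        r_trait = trait_rate(traj)
        lag_mean, lag_rate = lag_per_generation(traj)
        r50 = trait_rate_50pct(traj)
        no = offspring_per_parent(traj)
        gens_ext = traj.extinct_at if traj.extinct_at is not None else traj.max_dir_gens
    else:
        r_trait = lag_mean = lag_rate = r50 = math.nan
        no = math.nan
        gens_ext = 0
    kc = (
        kc_estimate(traj.eq_geno_var, der.sigma_e2, cfg.omega, no, traj.eq_trait_sd)
        if not math.isnan(no)
        else math.nan
    )
    return PopulationMetrics(
        rate_trait=r_trait,
        rate_env=rate_env,
        lag_mean=lag_mean,
        lag_rate=lag_rate,
        gens_to_extinction=gens_ext,
        gens_to_50pct=traj.first_mort50_gen,
        rate_trait_50pct=r50,
        survived_cap=traj.survived_cap,
        kc=kc,
        No=no,
        eq_geno_var=traj.eq_geno_var,
        eq_trait_sd=traj.eq_trait_sd,
        pre_directional_extinct=traj.pre_directional_extinct,
    )
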