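"""Species trait generation and scenario-dependent demography.

Each of the ``n_species`` annual plant species carries two fundamental
traits: a thermal optimum T_opt (the temperature of maximal growth) and a
seed mass SM (mg).  Thermal optima are evenly spaced over the landscape's
baseline temperature range extended by ``extension_C`` on both sides, so
that warmer-adapted species than any resident exist in the downslope pool.

Seed mass drives demography according to the dispersal scenario:

* ``uniform``   — every species has the same seed mass (the distribution
  mean); all vital rates identical.
* ``variable``  — seed masses are lognormal draws; SM affects only the
  dispersal scale (mean distance ~ SM^-0.13), all other vital rates are
  computed from the distribution median and shared.
* ``tradeoff``  — seed masses are lognormal draws and additionally set the
  vital rates: fecundity falls with SM (a strict seed-mass/seed-number
  trade-off at fixed reproductive investment), while germination
  probability and seedling biomass rise with SM (tolerance-fecundity
  trade-off after Jakobsson & Eriksson's grassland data).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .dispersal import KernelSpec, beta_from_sm, mean_distance
from .errors import ConfigurationError, InvalidTraitError

__all__ = [
    "SeedMassDistribution",
    "ScenarioSpec",
    "SpeciesTraits",
    "SCENARIOS",
    "assign_thermal_optima",
    "lognormal_params",
    "sample_seed_masses",
    "derive_demography",
    "build_traits",
]

SCENARIOS = ("uniform", "variable", "tradeoff")


@dataclass(frozen=True)
class SeedMassDistribution:
    """Arithmetic mean and SD (both mg) of the community seed-mass spread."""

    mean_mg: float = 1.5
    sd_mg: float = 3.0

    def __post_init__(self) -> None:
        if self.mean_mg <= 0:
            raise ConfigurationError("seed-mass mean must be positive")
        if self.sd_mg < 0:
            raise ConfigurationError("seed-mass SD must be non-negative")


@dataclass(frozen=True)
class ScenarioSpec:
    """Dispersal scenario plus the demographic scaling constants.

    ``phi`` is the reproductive investment per unit biomass (mg of seed
    output), so trade-off fecundity is phi / SM seeds per unit biomass.
    Germination probability saturates from ``g_min`` to ``g_max`` with
    half-saturation ``sm_half_mg``; seedling biomass is the allometric
    ``kappa * SM^seedling_exponent``.
    """

    kind: str = "uniform"
    sm_dist: SeedMassDistribution = SeedMassDistribution()
    phi: float = 16.0
    g_min: float = 0.2
    g_max: float = 0.8
    sm_half_mg: float = 1.0
    kappa: float = 1.0
    seedling_exponent: float = 0.65

    def __post_init__(self) -> None:
        if self.kind not in SCENARIOS:
            raise ConfigurationError(f"unknown scenario {self.kind!r}; pick one of {SCENARIOS}")
        if not (0 <= self.g_min <= self.g_max <= 1):
            raise ConfigurationError("need 0 <= g_min <= g_max <= 1")
        if self.phi <= 0 or self.kappa <= 0 or self.sm_half_mg <= 0:
            raise ConfigurationError("phi, kappa, sm_half_mg must be positive")


@dataclass(frozen=True)
class SpeciesTraits:
    """Per-species trait arrays, all of length n_species."""

    t_opt_C: np.ndarray
    sm_mg: np.ndarray
    beta_m: np.ndarray
    delta_m: np.ndarray
    fecundity: np.ndarray
    germ_p: np.ndarray
    seedling_b: np.ndarray

    @property
    def n_species(self) -> int:
        return self.t_opt_C.size

    @property
    def species_id(self) -> np.ndarray:
        return np.arange(self.n_species)


def assign_thermal_optima(n_species: int, landscape, extension_C: float = 2.0) -> np.ndarray:
    """Evenly spaced thermal optima covering the gradient plus a margin.

    The optima span [min T_base - extension_C, max T_base + extension_C],
    sorted ascending.  Even spacing guarantees full niche coverage; with
    the default 2 degC margin the covered range is broader than any
    temperature experienced in the landscape.
    """
    if n_species < 2:
        raise ConfigurationError("n_species must be >= 2")
    if extension_C < 0:
        raise ConfigurationError("extension_C must be non-negative")
    t = landscape.t_base_C
    return np.linspace(t.min() - extension_C, t.max() + extension_C, n_species)


def lognormal_params(mean_mg: float, sd_mg: float) -> Tuple[float, float]:
    """Moment-matched (mu, sigma) of the normal underlying a lognormal.

    sigma^2 = ln(1 + sd^2/mean^2) and mu = ln(mean) - sigma^2/2, so that
    the lognormal has arithmetic mean ``mean_mg`` and SD ``sd_mg``.
    """
    if mean_mg <= 0:
        raise ConfigurationError("mean_mg must be positive")
    if sd_mg <= 0:
        raise ConfigurationError("sd_mg must be positive (use the uniform scenario for SD = 0)")
    sigma2 = math.log(1.0 + (sd_mg / mean_mg) ** 2)
    mu = math.log(mean_mg) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def sample_seed_masses(spec: ScenarioSpec, n_species: int, rng: np.random.Generator) -> np.ndarray:
    """Draw the per-species seed masses (mg) for a replicate.

    Uniform scenario (or SD = 0): every species gets the distribution
    mean.  Otherwise i.i.d. lognormal draws moment-matched to the
    requested arithmetic mean and SD.
    """
    d = spec.sm_dist
    if spec.kind == "uniform" or d.sd_mg == 0:
        return np.full(n_species, d.mean_mg)
    mu, sigma = lognormal_params(d.mean_mg, d.sd_mg)
    return rng.lognormal(mean=mu, sigma=sigma, size=n_species)


def derive_demography(
    sm_mg: np.ndarray, spec: ScenarioSpec, kernel: KernelSpec
) -> SpeciesTraits:
    """Compute vital rates and dispersal scales from seed masses.

    The kernel scale beta (and hence mean distance delta) always follows
    each species' own seed mass.  In the uniform and variable scenarios
    fecundity, germination probability and seedling biomass are computed
    once from a reference seed mass (the common SM, respectively the
    distribution median exp(mu)) and shared by all species; in the
    trade-off scenario they follow each species' own SM.

    Returns a :class:`SpeciesTraits` with ``t_opt_C`` left as NaN (set by
    :func:`build_traits`).
    """
    sm = np.asarray(sm_mg, dtype=float)
    if np.any(sm <= 0):
        raise InvalidTraitError("all seed masses must be positive")
    beta = beta_from_sm(sm, kernel)
    delta = mean_distance(beta, kernel.c)

    if spec.kind == "tradeoff":
        sm_ref = sm
    elif spec.kind == "uniform":
        sm_ref = np.full_like(sm, spec.sm_dist.mean_mg)
    else:  # variable: rates from the distribution median, replicate-independent
        d = spec.sm_dist
        if d.sd_mg == 0:
            median = d.mean_mg
        else:
            mu, _ = lognormal_params(d.mean_mg, d.sd_mg)
            median = math.exp(mu)
        sm_ref = np.full_like(sm, median)

    fecundity = spec.phi / sm_ref
    germ_p = spec.g_min + (spec.g_max - spec.g_min) * sm_ref / (sm_ref + spec.sm_half_mg)
    seedling_b = spec.kappa * sm_ref**spec.seedling_exponent
    return SpeciesTraits(
        t_opt_C=np.full_like(sm, np.nan),
        sm_mg=sm,
        beta_m=beta,
        delta_m=delta,
        fecundity=fecundity,
        germ_p=germ_p,
        seedling_b=seedling_b,
    )


def build_traits(
    n_species: int,
    landscape,
    spec: ScenarioSpec,
    kernel: KernelSpec,
    rng: np.random.Generator,
    extension_C: float = 2.0,
) -> SpeciesTraits:
    """Full trait set for one replicate: optima, seed masses, demography."""
    t_opt = assign_thermal_optima(n_species, landscape, extension_C)
    sm = sample_seed_masses(spec, n_species, rng)
    tr = derive_demography(sm, spec, kernel)
    return SpeciesTraits(
        t_opt_C=t_opt,
        sm_mg=tr.sm_mg,
        beta_m=tr.beta_m,
        delta_m=tr.delta_m,
        fecundity=tr.fecundity,
        germ_p=tr.germ_p,
        seedling_b=tr.seedling_b,
    )
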