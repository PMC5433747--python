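"""Within-year biomass dynamics: thermal growth and Lotka-Volterra competition.

Growth rate follows a Gaussian thermal performance curve

    r_i(T) = r_max * exp(-(T - T_opt_i)^2 / (2 sigma_opt^2)),

with a niche width sigma_opt common to all species.  Carrying capacity is
proportional to the growth rate, K_i = K_max * r_i / r_max, floored at
K_floor to keep the density-dependence term finite off-niche.  Daily
biomass updates over the 120-day growing season follow the discrete
Lotka-Volterra difference equation

    B_i(t+1) = B_i + r_i (1 - B_i/K_i - sum_{j!=i} alpha_ij B_j/K_j) B_i - m B_i,

with intraspecific coefficient alpha_ii = 1, a single interspecific
coefficient alpha_ij = alpha < 1 (allowing coexistence), and a constant
background loss m (herbivory, pathogens).  With one common alpha the
interaction sum collapses to alpha * (sum_j B_j/K_j - B_i/K_i), making the
daily update O(S) per patch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "GrowthParams",
    "growth_rate",
    "carrying_capacity",
    "lv_day_step",
    "run_growing_season",
]


@dataclass(frozen=True)
class GrowthParams:
    r_max: float = 0.05          # max per-day growth rate at T = T_opt
    sigma_opt: float = 2.75      # thermal niche width (degC)
    m: float = 0.001             # background loss rate (day^-1)
    K_max: float = 100.0         # carrying capacity at the optimum
    K_floor_frac: float = 1e-4   # K floor as a fraction of K_max
    alpha_inter: float = 0.5     # interspecific competition alpha_ij
    alpha_intra: float = 1.0     # alpha_ii, fixed at 1
    season_days: int = 120
    extinction_threshold: float = 0.01

    def __post_init__(self) -> None:
        if self.r_max <= 0 or self.sigma_opt <= 0 or self.K_max <= 0:
            raise ConfigurationError("r_max, sigma_opt, K_max must be positive")
        if not (0 <= self.m < self.r_max):
            raise ConfigurationError("need 0 <= m < r_max")
        if not (0 <= self.alpha_inter < self.alpha_intra):
            raise ConfigurationError("need 0 <= alpha_inter < alpha_intra")
        if self.K_floor_frac <= 0:
            raise ConfigurationError("K_floor_frac must be positive")

    @property
    def K_floor(self) -> float:
        return self.K_floor_frac * self.K_max


def growth_rate(T, t_opt, params: GrowthParams):
    """Gaussian thermal performance: r_max at T = T_opt, symmetric decay."""
    dT = np.asarray(T, dtype=float) - np.asarray(t_opt, dtype=float)
    return params.r_max * np.exp(-(dT**2) / (2.0 * params.sigma_opt**2))


def carrying_capacity(T, t_opt, params: GrowthParams):
    """Temperature-dependent K, proportional to r and floored at K_floor."""
    r = growth_rate(T, t_opt, params)
    return np.maximum(params.K_max * r / params.r_max, params.K_floor)


def lv_day_step(B, r, K, params: GrowthParams):
    """One synchronous daily Lotka-Volterra update; negatives clamped to 0.

    ``B``, ``r``, ``K`` may be 1-D (one patch) or 2-D (patch x species);
    competition acts within the trailing species axis.
    """
    B = np.asarray(B, dtype=float)
    r = np.asarray(r, dtype=float)
    K = np.asarray(K, dtype=float)
    if B.shape != r.shape or B.shape != K.shape:
        raise ValueError("B, r, K must share a shape")
    X = B / K
    tot = X.sum(axis=-1, keepdims=True)
    interaction = 1.0 - X - params.alpha_inter * (tot - X)
    B_new = B + r * interaction * B - params.m * B
    return np.maximum(B_new, 0.0)


def run_growing_season(B0, r, K, params: GrowthParams):
    """Iterate the daily update for the full growing season at constant T.

    Species ending the season below the extinction threshold are zeroed
    (local extinction; defines presence/absence for event counting).  The
    inner loop is buffered to avoid per-day allocations: with a common
    interspecific alpha the update needs only the per-patch sum of B/K.
    """
    B = np.array(B0, dtype=float, copy=True)
    r = np.asarray(r, dtype=float)
    K = np.asarray(K, dtype=float)
    alpha = params.alpha_inter
    one_minus_alpha = 1.0 - alpha
    m = params.m
    X = np.empty_like(B)
    growth = np.empty_like(B)
    for _ in range(params.season_days):
        np.divide(B, K, out=X)
        tot = X.sum(axis=-1, keepdims=True)
        # interaction = 1 - (1 - alpha) X - alpha tot
        np.multiply(X, -one_minus_alpha, out=growth)
        growth -= alpha * tot
        growth += 1.0
        growth *= r
        growth -= m
        growth *= B
        B += growth
        np.maximum(B, 0.0, out=B)
    B[B < params.extinction_threshold] = 0.0
    return B
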