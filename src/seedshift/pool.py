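"""Dynamic downslope species pool: warm-edge immigration source.

The landscape's warm (downslope) boundary is open; to keep the competitive
environment at the warm end realistic, a regional pool of warmer-adapted
species supplies immigrants.  The pool sits half a mean nearest-neighbour
interpatch distance beyond the warm edge (x < 0).  Each year its
community-weighted mean (CWM) thermal optimum is extrapolated by ordinary
least squares from the patch CWM T_opt values regressed on gradient
position, and its T_opt abundance profile is a normal density centred on
that extrapolated CWM with variance equal to the mean within-patch T_opt
variance, rescaled to the mean total biomass of occupied patches.  A
virtual donor community with this composition sits directly downslope of
every patch, and its seed rain reaches the patch through the common
dispersal kernel evaluated at the offset distance.

Species sustained only by the pool are not "native" (not present at
equilibrium) and are excluded from every response variable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dispersal import DispersalMatrix

__all__ = [
    "PoolState",
    "mean_nn_distance_m",
    "extrapolate_pool_cwm",
    "mean_topt_variance",
    "pool_community",
    "pool_immigration",
    "update_pool",
]

logger = logging.getLogger(__name__)


@dataclass
class PoolState:
    cwm_topt: float              # extrapolated CWM T_opt at the pool (degC)
    var_topt: float              # pool T_opt variance (degC^2)
    abundances: np.ndarray       # per-species biomass profile
    location_offset_m: float     # half mean nearest-neighbour distance


def mean_nn_distance_m(landscape) -> float:
    """Mean nearest-neighbour distance between patches (m)."""
    d = landscape.distance_matrix_m().copy()
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).mean())


def extrapolate_pool_cwm(
    B: np.ndarray, t_opt: np.ndarray, x_km: np.ndarray, x_pool_km: float
) -> float:
    """OLS-extrapolated community-weighted mean T_opt at the pool position.

    Per-patch CWM T_opt values (biomass-weighted) are regressed on
    gradient position x; the fit is evaluated at ``x_pool_km`` beyond the
    warm edge.  Empty patches are excluded.  With fewer than two occupied
    patches the warmest-edge patch CWM is returned as a fallback (logged).
    """
    totals = B.sum(axis=1)
    occ = totals > 0
    if occ.sum() < 2:
        logger.warning("fewer than 2 occupied patches; pool CWM falls back to warm edge")
        if occ.sum() == 0:
            return float(np.nan)
        return float((B[occ] @ t_opt) / totals[occ])
    cwm = (B[occ] @ t_opt) / totals[occ]
    slope, intercept = np.polyfit(x_km[occ], cwm, 1)
    return float(slope * x_pool_km + intercept)


def mean_topt_variance(B: np.ndarray, t_opt: np.ndarray) -> float:
    """Mean over occupied patches of the abundance-weighted T_opt variance."""
    totals = B.sum(axis=1)
    occ = totals > 0
    if not occ.any():
        return float(np.nan)
    w = B[occ] / totals[occ, None]
    mean = w @ t_opt
    var = (w * (t_opt[None, :] - mean[:, None]) ** 2).sum(axis=1)
    return float(var.mean())


def pool_community(
    cwm_topt: float, var_topt: float, t_opt: np.ndarray, scale: float
) -> np.ndarray:
    """Normal-profile pool abundances over the species' thermal optima.

    Abundance of species s is proportional to the normal density at
    T_opt_s (mean ``cwm_topt``, variance ``var_topt``), rescaled so the
    total pool biomass equals ``scale``.
    """
    if var_topt <= 0:
        raise ValueError("pool T_opt variance must be positive")
    dens = np.exp(-((t_opt - cwm_topt) ** 2) / (2.0 * var_topt))
    total = dens.sum()
    if total < 1e-300 or scale == 0:
        return np.zeros_like(dens)
    return dens * (scale / total)


def update_pool(
    B: np.ndarray,
    t_opt: np.ndarray,
    x_km: np.ndarray,
    offset_m: float,
    scale_factor: float = 1.0,
) -> PoolState:
    """Recompute the pool state from this year's end-of-season communities.

    ``scale_factor`` multiplies the pool's total biomass (default: the mean
    total biomass of occupied patches), setting immigrant propagule
    pressure relative to a resident community.
    """
    x_pool_km = -offset_m / 1000.0
    cwm = extrapolate_pool_cwm(B, t_opt, x_km, x_pool_km)
    var = mean_topt_variance(B, t_opt)
    totals = B.sum(axis=1)
    occ = totals > 0
    scale = float(totals[occ].mean()) * scale_factor if occ.any() else 0.0
    if not np.isfinite(cwm) or not np.isfinite(var) or var <= 0:
        ab = np.zeros_like(t_opt)
    else:
        ab = pool_community(cwm, var, t_opt, scale)
    return PoolState(
        cwm_topt=float(cwm), var_topt=float(var), abundances=ab, location_offset_m=offset_m
    )


def pool_immigration(pool: PoolState, dm: DispersalMatrix, traits) -> np.ndarray:
    """Seed input per patch per species from the virtual downslope donors.

    Each patch has its own donor community (composition = the pool
    profile) one offset downslope, so the immigrant seed rain
    fecundity * abundance * P(offset, beta) * capture-area is identical
    across patches; returns a (n_patches, n_species) array.
    """
    seeds = traits.fecundity * pool.abundances * dm.pool_row
    return np.broadcast_to(seeds, (dm.n_patches, dm.n_species)).copy()
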