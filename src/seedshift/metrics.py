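"""Response variables: diversity partitioning, events, seed-mass and lag stats.

Diversity uses the inverse Simpson index 1 / sum(p^2) (the effective
number of equally abundant species).  Alpha is its mean over occupied
patches, gamma is the index of the pooled regional abundances, and beta is
the multiplicative remainder gamma / alpha.  All response variables are
computed over native species only (species present at equilibrium after
the stable-climate run-up).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .errors import UndefinedChangeError

__all__ = [
    "ResponseSummary",
    "inverse_simpson",
    "diversity_partition",
    "jaccard_mean",
    "weighted_geomean_sm",
    "climate_lag",
    "count_events",
    "percent_change",
]


@dataclass
class ResponseSummary:
    """One row of response variables for a phase of one replicate."""

    local_richness_mean: float
    regional_richness: int
    alpha_div: float
    beta_div: float
    gamma_div: float
    jaccard_mean: float
    colonisations_per_patch: float = np.nan
    exclusions_per_patch: float = np.nan
    cwm_geomean_sm: float = np.nan
    lag_mean_C: float = np.nan
    lag_sm_corr: float = np.nan
    pct_change_richness: float = np.nan
    pct_change_gamma_div: float = np.nan


def inverse_simpson(abundances: np.ndarray) -> float:
    """Inverse Simpson diversity 1 / sum p^2; 0 for an empty community.

    Equals n for n equally abundant species and 1 for a monoculture.
    """
    a = np.asarray(abundances, dtype=float)
    total = a.sum()
    if total <= 0:
        return 0.0
    p = a / total
    return float(1.0 / (p**2).sum())


def diversity_partition(B: np.ndarray) -> Tuple[float, float, float]:
    """(alpha, beta, gamma) inverse-Simpson partition of a patch x species matrix.

    alpha averages the patch-level index over occupied patches; gamma is
    the index of the regional (column-sum) abundances; beta = gamma/alpha.
    An empty metacommunity returns (0, 0, 0).
    """
    B = np.asarray(B, dtype=float)
    occ = B.sum(axis=1) > 0
    if not occ.any():
        return 0.0, 0.0, 0.0
    alpha = float(np.mean([inverse_simpson(row) for row in B[occ]]))
    gamma = inverse_simpson(B.sum(axis=0))
    beta = gamma / alpha if alpha > 0 else 0.0
    return alpha, beta, gamma


def jaccard_mean(presence: np.ndarray) -> float:
    """Mean pairwise Jaccard dissimilarity 1 - |A&B|/|A|B| between patches.

    Pairs of mutually empty patches contribute 0 (identical communities).
    """
    P = np.asarray(presence, dtype=bool)
    n = P.shape[0]
    if n < 2:
        raise ValueError("need at least 2 patches")
    inter = (P.astype(float) @ P.T.astype(float))
    sizes = P.sum(axis=1).astype(float)
    union = sizes[:, None] + sizes[None, :] - inter
    iu = np.triu_indices(n, k=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dis = 1.0 - inter[iu] / union[iu]
    dis[union[iu] == 0] = 0.0
    return float(dis.mean())


def weighted_geomean_sm(regional_abundance: np.ndarray, sm_mg: np.ndarray) -> float:
    """Geometric mean seed mass weighted by regional abundance shares."""
    a = np.asarray(regional_abundance, dtype=float)
    sm = np.asarray(sm_mg, dtype=float)
    total = a.sum()
    if total <= 0:
        raise ValueError("total regional abundance must be positive")
    if np.any(sm <= 0):
        raise ValueError("seed masses must be positive")
    w = a / total
    return float(np.exp(w @ np.log(sm)))


def climate_lag(
    B: np.ndarray,
    patch_temps: np.ndarray,
    t_opt: np.ndarray,
    sm_mg: np.ndarray,
    natives: np.ndarray,
    n_focal: int = 40,
) -> Tuple[np.ndarray, float, float]:
    """Climate-tracking lag of the ``n_focal`` warmest-adapted natives.

    The lag of a species is its abundance-weighted mean experienced
    temperature minus its thermal optimum (positive = occupying sites
    warmer than the optimum, i.e. trailing the shifting niche).  Focal
    species are the natives with the highest T_opt; regionally extinct
    focal species are dropped.  Returns (per-species lags, mean absolute
    lag, Pearson correlation of |lag| with seed mass).
    """
    B = np.asarray(B, dtype=float)
    native_idx = np.flatnonzero(np.asarray(natives, dtype=bool))
    if native_idx.size == 0:
        return np.array([]), np.nan, np.nan
    order = native_idx[np.argsort(t_opt[native_idx])]
    focal = order[-min(n_focal, order.size):]
    regional = B[:, focal].sum(axis=0)
    alive = regional > 0
    focal = focal[alive]
    if focal.size == 0:
        return np.array([]), np.nan, np.nan
    w = B[:, focal]
    exp_T = (w * patch_temps[:, None]).sum(axis=0) / w.sum(axis=0)
    lags = exp_T - t_opt[focal]
    abs_lag = np.abs(lags)
    if focal.size < 2 or np.std(abs_lag) == 0 or np.std(sm_mg[focal]) == 0:
        corr = np.nan
    else:
        corr = float(np.corrcoef(abs_lag, sm_mg[focal])[0, 1])
    return lags, float(abs_lag.mean()), corr


def count_events(log, year_min: int, year_max: int, n_patches: int) -> Tuple[float, float]:
    """Mean (colonisations, exclusions) per patch over a window of years.

    ``log`` is any object exposing parallel lists ``years``,
    ``colonisations`` and ``exclusions`` (per-year, per-patch count
    vectors, already restricted to native species).  Counts are summed
    over years in [year_min, year_max] and divided by the patch count.
    """
    col = np.zeros(n_patches)
    exc = np.zeros(n_patches)
    for y, c, e in zip(log.years, log.colonisations, log.exclusions):
        if year_min <= y <= year_max:
            col += c
            exc += e
    return float(col.mean()), float(exc.mean())


def percent_change(before: float, after: float) -> float:
    """100 * (after - before) / before."""
    if before == 0:
        raise UndefinedChangeError("percent change undefined for a zero baseline")
    return 100.0 * (after - before) / before
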