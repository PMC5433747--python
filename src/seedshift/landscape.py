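"""Patch landscapes on a linear temperature gradient and sigmoidal warming.

The landscape is a rectangle of ``extent_km`` (gradient axis, x) by
``width_km`` (cross-gradient axis, y) holding randomly placed patches.
Baseline temperature declines linearly with x from a warm edge at x = 0,
spanning ``gradient_span_C`` over the full extent; elevation rises linearly
in step (6 degC over 50 km corresponds to roughly a 900 m elevational
gradient).  Climate change adds a spatially uniform, sigmoidally increasing
temperature increment to every patch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "Patch",
    "Landscape",
    "ClimateForcing",
    "build_landscape",
    "temperature_at",
    "landscape_temperatures",
]


@dataclass(frozen=True)
class Patch:
    """A single habitat patch (positions in km, elevation in m)."""

    id: int
    x_km: float
    y_km: float
    elevation_m: float
    t_base_C: float


@dataclass(frozen=True)
class Landscape:
    """Random patch positions plus the linear maps x -> T_base, elevation.

    Positions are stored as arrays (kilometres); :meth:`positions_m` returns
    them in metres, the unit used by the dispersal kernel.
    """

    x_km: np.ndarray
    y_km: np.ndarray
    extent_km: float
    width_km: float
    gradient_span_C: float
    elevation_span_m: float = 900.0
    t_warm_C: float = 14.0

    @property
    def n_patches(self) -> int:
        return self.x_km.size

    @property
    def t_base_C(self) -> np.ndarray:
        """Baseline temperature of every patch (warmest at x = 0)."""
        return self.t_warm_C - self.gradient_span_C * (self.x_km / self.extent_km)

    @property
    def elevation_m(self) -> np.ndarray:
        return self.elevation_span_m * (self.x_km / self.extent_km)

    @property
    def patches(self) -> List[Patch]:
        t = self.t_base_C
        e = self.elevation_m
        return [
            Patch(i, float(self.x_km[i]), float(self.y_km[i]), float(e[i]), float(t[i]))
            for i in range(self.n_patches)
        ]

    def positions_m(self) -> np.ndarray:
        """(n_patches, 2) array of patch coordinates in metres."""
        return np.column_stack([self.x_km, self.y_km]) * 1000.0

    def distance_matrix_m(self) -> np.ndarray:
        pos = self.positions_m()
        diff = pos[:, None, :] - pos[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))


def build_landscape(
    n_patches: int,
    extent_km: float,
    width_km: float,
    gradient_span_C: float,
    rng: np.random.Generator,
    *,
    elevation_span_m: float = 900.0,
    t_warm_C: float = 14.0,
) -> Landscape:
    """Draw ``n_patches`` uniformly random patches in the gradient rectangle.

    Deterministic for a fixed ``rng`` state.  The baseline temperature at the
    extremes of x differs by exactly ``gradient_span_C``.
    """
    if n_patches < 2:
        raise ConfigurationError(f"n_patches must be >= 2, got {n_patches}")
    if extent_km <= 0 or width_km <= 0:
        raise ConfigurationError("landscape dimensions must be positive")
    if gradient_span_C <= 0:
        raise ConfigurationError("gradient_span_C must be positive")
    x = rng.uniform(0.0, extent_km, size=n_patches)
    y = rng.uniform(0.0, width_km, size=n_patches)
    return Landscape(
        x_km=x,
        y_km=y,
        extent_km=float(extent_km),
        width_km=float(width_km),
        gradient_span_C=float(gradient_span_C),
        elevation_span_m=float(elevation_span_m),
        t_warm_C=float(t_warm_C),
    )


@dataclass(frozen=True)
class ClimateForcing:
    """Sigmoidal warming trajectory, renormalised to exact endpoints.

    The raw logistic s(t) = 1 / (1 + exp(-k (t - t_mid))) never reaches 0
    or 1 on a finite window, so the forcing is the affinely rescaled

        f(t) = delta_total_C * (s(t) - s(0)) / (s(duration_y) - s(0)),

    which satisfies f(0) = 0 and f(duration_y) = delta_total_C exactly and
    is symmetric about ``t_mid`` for the default t_mid = duration_y / 2.
    Outside the warming window the forcing is clamped: 0 before onset, the
    full increment afterwards.
    """

    delta_total_C: float = 3.0
    duration_y: float = 150.0
    k: float = 0.08
    t_mid: float = field(default=math.nan)

    def __post_init__(self) -> None:
        if self.duration_y <= 0:
            raise ConfigurationError("duration_y must be positive")
        if self.k <= 0:
            raise ConfigurationError("sigmoid steepness k must be positive")
        if math.isnan(self.t_mid):
            object.__setattr__(self, "t_mid", self.duration_y / 2.0)

    def _s(self, t):
        return 1.0 / (1.0 + np.exp(-self.k * (np.asarray(t, dtype=float) - self.t_mid)))

    def __call__(self, t):
        """Warming increment (degC) at time ``t`` years after onset."""
        s0 = self._s(0.0)
        sD = self._s(self.duration_y)
        raw = self.delta_total_C * (self._s(t) - s0) / (sD - s0)
        out = np.clip(raw, 0.0, self.delta_total_C)
        out = np.where(np.asarray(t, dtype=float) <= 0.0, 0.0, out)
        out = np.where(np.asarray(t, dtype=float) >= self.duration_y, self.delta_total_C, out)
        if np.isscalar(t) or np.ndim(t) == 0:
            return float(out)
        return out


def temperature_at(patch: Patch, t: float, forcing: ClimateForcing) -> float:
    """Temperature experienced in ``patch`` at ``t`` years after warming onset.

    Negative ``t`` denotes the stable run-up phase (no increment).  The
    increment is spatially uniform: identical for every patch at a given t.
    """
    return patch.t_base_C + forcing(t)


def landscape_temperatures(landscape: Landscape, t: float, forcing: ClimateForcing) -> np.ndarray:
    """Vector of experienced temperatures over all patches at time ``t``."""
    return landscape.t_base_C + forcing(t)
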