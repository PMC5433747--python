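"""Run configuration: validated defaults, YAML/JSON loading, serialisation.

Every tunable of the simulator lives in :class:`RunConfig`.  Defaults
reproduce the baseline study design: 200 species on a 6 degC / 50 km
gradient of 50 random patches, seed-mass distribution mean 1.5 mg / SD
3 mg, interspecific competition alpha = 0.5, 3 degC of sigmoidal warming
over 150 years, 30 replicates.  Demographic and growth constants that are
not fixed by the design are calibration knobs with documented defaults
(see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Mapping, Optional

import yaml

from .dispersal import KernelSpec
from .errors import ConfigurationError
from .growth import GrowthParams
from .landscape import ClimateForcing
from .traits import SCENARIOS, ScenarioSpec, SeedMassDistribution

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    # landscape & gradient
    n_patches: int = 50
    extent_km: float = 50.0
    width_km: float = 5.0
    gradient_span_C: float = 6.0
    elevation_span_m: float = 900.0
    t_warm_C: float = 14.0
    # climate forcing
    warming_C: float = 3.0
    warming_years: int = 150
    sigmoid_k: float = 0.08
    # species & scenario
    n_species: int = 200
    scenario: str = "uniform"
    sm_mean_mg: float = 1.5
    sm_sd_mg: float = 3.0
    topt_extension_C: float = 2.0
    # demography (trade-off scaling constants)
    phi: float = 16.0
    g_min: float = 0.2
    g_max: float = 0.8
    sm_half: float = 1.0
    kappa: float = 1.0
    seedling_exponent: float = 0.65
    # growth & competition
    r_max: float = 0.05
    sigma_opt: float = 2.75
    m: float = 0.001
    K_max: float = 100.0
    K_floor_frac: float = 1e-4
    alpha_inter: float = 0.5
    season_days: int = 120
    extinction_threshold: float = 0.01
    # dispersal kernel
    kernel_c: float = 0.5
    kernel_a: float = 600.0
    sm_exponent: float = -0.13
    r_capture_m: float = 100.0
    # regional pool
    pool_enabled: bool = True
    pool_scale_mode: str = "mean_patch_biomass"
    pool_scale_factor: float = 1.0
    # run control
    max_stable_years: int = 400
    stable_tol: float = 1e-4
    stable_window: int = 10
    settle_years: int = 50
    n_replicates: int = 30
    seed: int = 42

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ConfigurationError(
                f"scenario must be one of {SCENARIOS}, got {self.scenario!r}"
            )
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if self.n_species < 2:
            raise ConfigurationError("n_species must be >= 2")
        if self.warming_years < 1 or self.settle_years < 0:
            raise ConfigurationError("warming_years >= 1 and settle_years >= 0 required")
        # component dataclasses validate the rest eagerly
        self.scenario_spec()
        self.kernel_spec()
        self.growth_params()
        self.forcing()

    # ------------------------------------------------------------------
    # component views
    def scenario_spec(self) -> ScenarioSpec:
        return ScenarioSpec(
            kind=self.scenario,
            sm_dist=SeedMassDistribution(self.sm_mean_mg, self.sm_sd_mg),
            phi=self.phi,
            g_min=self.g_min,
            g_max=self.g_max,
            sm_half_mg=self.sm_half,
            kappa=self.kappa,
            seedling_exponent=self.seedling_exponent,
        )

    def kernel_spec(self) -> KernelSpec:
        return KernelSpec(
            c=self.kernel_c,
            a=self.kernel_a,
            sm_exponent=self.sm_exponent,
            r_capture_m=self.r_capture_m,
        )

    def growth_params(self) -> GrowthParams:
        return GrowthParams(
            r_max=self.r_max,
            sigma_opt=self.sigma_opt,
            m=self.m,
            K_max=self.K_max,
            K_floor_frac=self.K_floor_frac,
            alpha_inter=self.alpha_inter,
            season_days=self.season_days,
            extinction_threshold=self.extinction_threshold,
        )

    def forcing(self) -> ClimateForcing:
        return ClimateForcing(
            delta_total_C=self.warming_C,
            duration_y=float(self.warming_years),
            k=self.sigmoid_k,
        )

    # ------------------------------------------------------------------
    # serialisation
    def to_dict(self) -> Dict[str, Any]:
        return dataclasses.asdict(self)

    def replace(self, **kwargs: Any) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def dump(self, path: Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)


_FIELD_TYPES = {f.name: f.type for f in dataclasses.fields(RunConfig)}


def _coerce(key: str, value: Any) -> Any:
    """Coerce a raw config value to its field type, rejecting mismatches."""
    target = _FIELD_TYPES[key]
    try:
        if target in ("int", int):
            if isinstance(value, bool) or (isinstance(value, float) and value != int(value)):
                raise ConfigurationError(f"key {key!r} expects an integer, got {value!r}")
            return int(value)
        if target in ("float", float):
            if isinstance(value, bool):
                raise ConfigurationError(f"key {key!r} expects a number, got {value!r}")
            return float(value)
        if target in ("bool", bool):
            if not isinstance(value, bool):
                raise ConfigurationError(f"key {key!r} expects a boolean, got {value!r}")
            return value
        if target in ("str", str):
            if not isinstance(value, str):
                raise ConfigurationError(f"key {key!r} expects a string, got {value!r}")
            return value
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"key {key!r}: cannot coerce {value!r}") from exc
    return value


def load_config(
    path: Optional[Path] = None, overrides: Optional[Mapping[str, Any]] = None
) -> RunConfig:
    """Build a fully resolved :class:`RunConfig` from a file plus overrides.

    ``path`` may be absent (defaults-only mode) or a YAML/JSON file.
    Unknown keys are rejected with the offending key named.  Overrides are
    applied after the file.
    """
    data: Dict[str, Any] = {}
    if path is not None:
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config file {path} must hold a mapping")
        data.update(raw)
    if overrides:
        data.update(overrides)
    unknown = set(data) - set(_FIELD_TYPES)
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
    coerced = {k: _coerce(k, v) for k, v in data.items()}
    return RunConfig(**coerced)
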