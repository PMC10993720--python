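"""Residual whole-tree canopy transpiration after full stomatal closure.

Even with stomata fully closed a canopy keeps losing water through the
cuticle at a rate g_min * VPD / P per unit leaf area.  Integrating that flux
over a day's 5-minute climate record and scaling by R — the ratio of canopy
projected leaf area to stem basal area (m2 m-2) — gives the daily residual
canopy transpiration standardized by tree size:

    E_min_canop = sum_i  g_min(T_i) * VPD_i / P * dT * R      [mmol m-2 basal]

converted to litres via the molar mass of water (18.015 g mol-1) and unit
density.  P is the site air pressure, 94.9 kPa by default.  Leaf temperature
is taken equal to air temperature and boundary-layer conductance is neglected.

Heat scenarios shift the whole diurnal temperature curve upward in 0.1 degC
steps while holding the vapor-pressure (absolute humidity) curve fixed, so
VPD rises with temperature exactly as it would if the same air mass were
simply hotter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .drydown import WATER_MOLAR_MASS
from .psychro import (
    SITE_PRESSURE_KPA,
    rh_from_vapor_pressure,
    saturation_vapor_pressure,
)
from .temperature import ExpFit

__all__ = [
    "DiurnalClimate",
    "CanopySpec",
    "EminResult",
    "instantaneous_flux",
    "integrate_emin_day",
    "elevate_climate",
    "scenario_sweep",
    "leaf_area_sweep",
]

#: litres of liquid water per mmol (18.015 mg at density 1.0 g mL-1).
LITRES_PER_MMOL = WATER_MOLAR_MASS * 1e-6


@dataclass(frozen=True)
class DiurnalClimate:
    """Uniformly sampled one-day canopy climate record.

    ``times`` are seconds from the start of the record (default 08:00), on a
    uniform step; ``vapor_pressure`` is the actual vapor pressure series
    derived once from (T, RH) and carried alongside so that temperature
    elevation can conserve it exactly.
    """

    times: np.ndarray  # s from start, uniform step
    temperature: np.ndarray  # degC
    rh: np.ndarray  # percent
    vapor_pressure: np.ndarray  # kPa
    pressure: float = SITE_PRESSURE_KPA
    rh_capped: np.ndarray | None = None  # samples where RH hit 100%

    def __post_init__(self) -> None:
        n = self.times.size
        if not (self.temperature.size == self.rh.size == self.vapor_pressure.size == n):
            raise ValueError("climate series must have equal length")
        steps = np.diff(self.times)
        if n > 1 and not np.allclose(steps, steps[0]):
            raise ValueError("climate record must be uniformly sampled")
        if np.any(self.rh < 0) or np.any(self.rh > 100):
            raise ValueError("RH must lie in [0, 100]%")

    @classmethod
    def from_temperature_rh(
        cls, times, temperature, rh, pressure: float = SITE_PRESSURE_KPA
    ) -> "DiurnalClimate":
        times = np.asarray(times, dtype=float)
        temperature = np.asarray(temperature, dtype=float)
        rh = np.asarray(rh, dtype=float)
        e = saturation_vapor_pressure(temperature) * rh / 100.0
        return cls(
            times=times,
            temperature=temperature,
            rh=rh,
            vapor_pressure=e,
            pressure=pressure,
        )

    @property
    def step(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def vpd(self) -> np.ndarray:
        return saturation_vapor_pressure(self.temperature) * (1.0 - self.rh / 100.0)

    @property
    def max_temperature(self) -> float:
        return float(self.temperature.max())

    @property
    def max_vpd(self) -> float:
        return float(self.vpd.max())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "temperature_C": self.temperature,
                "rh_pct": self.rh,
                "vapor_pressure_kPa": self.vapor_pressure,
                "vpd_kPa": self.vpd,
            }
        )


@dataclass(frozen=True)
class CanopySpec:
    """Scaling description of one species' canopy.

    ``r_ratio`` is R, canopy projected leaf area per stem basal area
    (m2 m-2); ``area_basis_factor`` converts between the leaf-area basis of
    g_min (two-sided) and of R (projected) and defaults to 1, i.e. the scaling
    relation is applied literally as printed in the source field protocol.
    """

    species: str
    r_ratio: float
    basal_area: float | None = None  # m2 per tree
    canopy_leaf_area: float | None = None  # m2 per tree
    area_basis_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.r_ratio <= 0:
            raise ValueError("R must be positive")


@dataclass(frozen=True)
class EminResult:
    """Daily residual canopy transpiration for one species and scenario."""

    species: str
    delta: float  # degC added to the base day
    e_std: float  # L per m2 basal area per day
    e_tree: float | None  # L per tree per day
    e_canopy: float | None  # L per canopy per day
    max_temperature: float
    max_vpd: float


def instantaneous_flux(gmin: float, vpd: float, pressure: float = SITE_PRESSURE_KPA):
    """Cuticular water flux g_min*VPD/P, mmol per m2 leaf per s."""
    return gmin * vpd / pressure


def _gmin_series(model, temperature: np.ndarray) -> np.ndarray:
    if isinstance(model, ExpFit):
        return model.predict(temperature)
    return np.full_like(temperature, float(model))


def integrate_emin_day(
    model,
    climate: DiurnalClimate,
    spec: CanopySpec,
    delta: float = 0.0,
    extrapolation_margin: float = 5.0,
) -> EminResult:
    """Left-Riemann integration of the residual flux over one day.

    ``model`` is either an :class:`ExpFit` (g_min as a function of air
    temperature) or a fixed conductance in mmol m-2 s-1.  The sum runs over
    the record's intervals (samples except the last), at the native step.
    Extrapolating an ExpFit more than ``extrapolation_margin`` degC beyond its
    calibration range emits a warning, not an error.
    """
    if isinstance(model, ExpFit):
        hi = climate.temperature.max()
        if hi > model.t_range[1] + extrapolation_margin:
            import warnings

            warnings.warn(
                f"extrapolating g_min(T) {hi - model.t_range[1]:.1f} degC beyond "
                "its calibration range",
                stacklevel=2,
            )
    t = climate.temperature[:-1]
    vpd = climate.vpd[:-1]
    dt = climate.step
    g = _gmin_series(model, t)
    # mmol per m2 of g_min's leaf-area basis, integrated over the day
    per_leaf_mmol = float(np.sum(g * vpd) / climate.pressure * dt)
    per_leaf_l = per_leaf_mmol * LITRES_PER_MMOL
    e_std = per_leaf_l * spec.r_ratio * spec.area_basis_factor
    e_tree = e_std * spec.basal_area if spec.basal_area is not None else None
    e_canopy = (
        per_leaf_l * spec.canopy_leaf_area * spec.area_basis_factor
        if spec.canopy_leaf_area is not None
        else None
    )
    return EminResult(
        species=spec.species,
        delta=delta,
        e_std=e_std,
        e_tree=e_tree,
        e_canopy=e_canopy,
        max_temperature=climate.max_temperature,
        max_vpd=climate.max_vpd,
    )


def elevate_climate(climate: DiurnalClimate, delta: float) -> DiurnalClimate:
    """Shift the day's temperature curve by ``delta`` degC at fixed vapor pressure.

    The vapor-pressure series is carried over bit-identically; RH is
    recomputed from it at the new temperatures (capped at 100% with the cap
    positions recorded in ``rh_capped``), so VPD covaries with the warming.
    """
    new_t = climate.temperature + delta
    rh, capped = rh_from_vapor_pressure(climate.vapor_pressure, new_t)
    return DiurnalClimate(
        times=climate.times,
        temperature=new_t,
        rh=rh,
        vapor_pressure=climate.vapor_pressure,
        pressure=climate.pressure,
        rh_capped=capped,
    )


def scenario_sweep(
    model,
    climate: DiurnalClimate,
    spec: CanopySpec,
    step: float = 0.1,
    t_cap: float = 50.0,
) -> list[EminResult]:
    """Daily totals for elevation scenarios 0, step, ... until max T hits t_cap."""
    base_max = climate.max_temperature
    if base_max > t_cap:
        raise ValueError("base climate already exceeds the temperature cap")
    n_steps = int(round((t_cap - base_max) / step))
    deltas = np.round(np.arange(n_steps + 1) * step, 10)
    return [
        integrate_emin_day(model, elevate_climate(climate, d), spec, delta=float(d))
        for d in deltas
    ]


def leaf_area_sweep(
    model,
    climate: DiurnalClimate,
    areas,
    species: str = "",
    area_basis_factor: float = 1.0,
) -> pd.DataFrame:
    """Daily canopy water loss (L) as a function of canopy leaf area (m2).

    Linear in area with zero intercept: the per-area daily loss is computed
    once and scaled.
    """
    areas = np.asarray(areas, dtype=float)
    if np.any(areas < 0):
        raise ValueError("leaf areas must be nonnegative")
    unit = integrate_emin_day(
        model,
        climate,
        CanopySpec(species=species, r_ratio=1.0, area_basis_factor=area_basis_factor),
    ).e_std  # L per m2 of leaf area per day
    return pd.DataFrame(
        {"species": species, "canopy_leaf_area_m2": areas, "water_loss_L": unit * areas}
    )


def sweep_to_frame(results: list[EminResult]) -> pd.DataFrame:
    """Tidy table of a scenario sweep (one row per species x delta)."""
    return pd.DataFrame(
        {
            "species": [r.species for r in results],
            "delta_C": [r.delta for r in results],
            "max_T_C": [r.max_temperature for r in results],
            "max_vpd_kPa": [r.max_vpd for r in results],
            "e_std_L_per_m2": [r.e_std for r in results],
            "e_tree_L": [r.e_tree for r in results],
        }
    )
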