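"""Psychrometric helpers: saturation vapor pressure, VPD and humidity conversions.

All vapor-pressure arithmetic used by both the drydown-estimation and the
canopy-simulation stages lives here.  Pressures are in kPa, temperatures in
degrees Celsius, relative humidity in percent (0-100).

The saturation formula is the Magnus approximation over liquid water,

    es(T) = 0.6108 * exp(17.27 * T / (T + 237.3))   [kPa]

which is the standard micrometeorological choice (FAO-56 coefficients) and is
accurate to well under 1% between -20 and 60 degC.  The formula is a single
module-level function so an alternative (Buck, Tetens ice-phase, ...) can be
swapped in one place.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AirState",
    "CHAMBER_PRESSURE_KPA",
    "SITE_PRESSURE_KPA",
    "MAGNUS_A_KPA",
    "MAGNUS_B",
    "MAGNUS_C",
    "saturation_vapor_pressure",
    "vpd",
    "actual_vapor_pressure",
    "rh_from_vapor_pressure",
]

#: Atmospheric pressure assumed inside the growth chamber (kPa).
CHAMBER_PRESSURE_KPA = 98.0
#: Mean air pressure at the forest research site (kPa).
SITE_PRESSURE_KPA = 94.9

# Magnus coefficients over liquid water.
MAGNUS_A_KPA = 0.6108
MAGNUS_B = 17.27
MAGNUS_C = 237.3

# Validity range of the Magnus fit (degC).
_T_MIN, _T_MAX = -20.0, 60.0


@dataclass(frozen=True)
class AirState:
    """Bulk state of moist air: temperature (degC), RH (%), pressure (kPa)."""

    temperature: float
    relative_humidity: float
    pressure: float = CHAMBER_PRESSURE_KPA

    def __post_init__(self) -> None:
        if not (0.0 <= self.relative_humidity <= 100.0):
            raise ValueError(
                f"relative_humidity must be in [0, 100]%, got {self.relative_humidity}"
            )
        if self.pressure <= 0:
            raise ValueError(f"pressure must be positive, got {self.pressure}")
        _check_temperature(self.temperature)

    @property
    def vpd(self) -> float:
        return vpd(self)

    @property
    def vapor_pressure(self) -> float:
        return actual_vapor_pressure(self)


def _check_temperature(temperature) -> None:
    t = np.asarray(temperature, dtype=float)
    if np.any(t < _T_MIN) or np.any(t > _T_MAX):
        raise ValueError(
            f"temperature outside the validated range [{_T_MIN}, {_T_MAX}] degC"
        )


def saturation_vapor_pressure(temperature):
    """Saturation vapor pressure over water, kPa (Magnus form).

    Accepts scalars or arrays; strictly positive and strictly increasing in
    temperature over the validated -20..60 degC range.
    """
    _check_temperature(temperature)
    t = np.asarray(temperature, dtype=float)
    es = MAGNUS_A_KPA * np.exp(MAGNUS_B * t / (t + MAGNUS_C))
    if np.isscalar(temperature) or np.ndim(temperature) == 0:
        return float(es)
    return es


def vpd(state: AirState) -> float:
    """Vapor pressure deficit es(T) - e, kPa. Nonnegative by construction."""
    return saturation_vapor_pressure(state.temperature) * (
        1.0 - state.relative_humidity / 100.0
    )


def actual_vapor_pressure(state: AirState) -> float:
    """Actual (partial) vapor pressure e = es(T) * RH/100, kPa."""
    return saturation_vapor_pressure(state.temperature) * state.relative_humidity / 100.0


def rh_from_vapor_pressure(e, temperature):
    """Relative humidity (%) implied by vapor pressure ``e`` at ``temperature``.

    Returns ``(rh, capped)``: supersaturated inputs are capped at 100% and the
    boolean flag (scalar or array) reports where capping occurred.  Inverse of
    :func:`actual_vapor_pressure` whenever no capping takes place.
    """
    e_arr = np.asarray(e, dtype=float)
    if np.any(e_arr < 0):
        raise ValueError("vapor pressure must be nonnegative")
    es = np.asarray(saturation_vapor_pressure(temperature), dtype=float)
    rh = 100.0 * e_arr / es
    capped = rh > 100.0
    rh = np.minimum(rh, 100.0)
    if np.ndim(e) == 0 and np.ndim(temperature) == 0:
        return float(rh), bool(capped)
    return rh, capped


def absolute_humidity(state: AirState) -> float:
    """Mass-based absolute humidity, g water per m3 of air (ideal gas).

    Provided because 'constant absolute humidity' during a temperature
    elevation can be read either as constant vapor pressure (the default
    elsewhere in this package) or as constant water mass per volume; the two
    differ only through the ideal-gas temperature factor.
    """
    e_pa = actual_vapor_pressure(state) * 1000.0
    t_k = state.temperature + 273.15
    # Rv = 461.5 J kg-1 K-1; result kg m-3 -> g m-3
    return e_pa / (461.5 * t_k) * 1000.0


def vapor_pressure_from_absolute_humidity(ah_g_m3: float, temperature: float) -> float:
    """Inverse of :func:`absolute_humidity`: vapor pressure (kPa) from g m-3."""
    t_k = temperature + 273.15
    return ah_g_m3 / 1000.0 * 461.5 * t_k / 1000.0
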