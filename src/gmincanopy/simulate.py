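"""Seeded generators for drydown experiments, diurnal climates and trait tables.

These generators encode the study conditions the estimation stages assume, so
every downstream stage is testable without measured data:

* ``simulate_drydown`` integrates the forward water-loss model of a detached
  leaf — conductance starts at a stomatal value, decays exponentially with
  falling relative water content, and settles on the cuticular floor
  ``true_gmin`` below the closure RWC — and samples the mass trajectory at the
  weighing interval with additive balance noise.  The true conductance is
  carried on the returned record so recovery tests have their oracle.
* ``simulate_diurnal_climate`` builds a sinusoid-shaped 08:00-20:00
  temperature day with a constant vapor-pressure (absolute-humidity) curve,
  the structure of a hot anticyclonic summer day.
* ``simulate_trait_table`` draws a species panel whose minimum conductance is
  generated from maximum stomatal conductance (positive effect), total
  cuticle thickness (positive) and stomatal size (negative), plus lognormal
  noise.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .drydown import WATER_MOLAR_MASS, DrydownRecord
from .psychro import AirState, rh_from_vapor_pressure, saturation_vapor_pressure, vpd
from .canopy import DiurnalClimate

__all__ = [
    "DrydownSimParams",
    "ClimateSimParams",
    "TraitSimParams",
    "simulate_drydown",
    "simulate_diurnal_climate",
    "simulate_trait_table",
    "climate_from_extremes",
]

#: Chamber conditions of the growth-chamber drydown protocol (20 degC, 69% RH).
DEFAULT_CHAMBER = AirState(temperature=20.0, relative_humidity=69.0, pressure=98.0)


@dataclass(frozen=True)
class DrydownSimParams:
    """Forward-model parameters for one synthetic drydown.

    Defaults mirror the growth-chamber protocol: a broadleaf with ~0.8 g of
    mobile water weighed every 2.5 h for 30 h at 20 degC / 69% RH on a
    0.2 mg-precision balance.  ``stomatal_g0`` is the conductance at full
    saturation (dark, detached: a modest fraction of g_max) and decays to
    ``true_gmin`` as RWC approaches ``closure_rwc``.
    """

    true_gmin: float = 2.0  # mmol m-2 s-1, cuticular floor
    stomatal_g0: float = 12.0  # mmol m-2 s-1 at RWC = 1
    closure_rwc: float = 0.80  # full stomatal closure below this RWC
    leaf_area_two_sided: float = 0.0075  # m2 (SLA 15 m2 kg-1, 0.25 g dry, x2)
    w_sat: float = 1.05  # g
    w_dry: float = 0.25  # g
    chamber: AirState = DEFAULT_CHAMBER
    weighing_interval: float = 9000.0  # s (2.5 h)
    duration: float = 108000.0  # s (30 h)
    balance_sd: float = 0.0002  # g (0.2 mg balance)
    seed: int = 0
    decay_rate: float = 5.0  # e-foldings of stomatal closure across 1 -> closure_rwc

    def __post_init__(self) -> None:
        if not self.w_sat > self.w_dry > 0:
            raise ValueError("need w_sat > w_dry > 0")
        if not self.true_gmin < self.stomatal_g0:
            raise ValueError("true_gmin must be below stomatal_g0")
        if not (0.5 < self.closure_rwc <= 1.0):
            raise ValueError("closure_rwc must lie in (0.5, 1.0]")
        if self.leaf_area_two_sided <= 0 or self.weighing_interval <= 0:
            raise ValueError("area and weighing interval must be positive")


def _conductance_of_rwc(rwc: float, p: DrydownSimParams) -> float:
    """Exponential stomatal closure onto the cuticular floor."""
    if p.closure_rwc >= 1.0 or rwc <= p.closure_rwc:
        return p.true_gmin
    frac = (1.0 - rwc) / (1.0 - p.closure_rwc)  # 0 at saturation, 1 at closure
    return p.true_gmin + (p.stomatal_g0 - p.true_gmin) * np.exp(-p.decay_rate * frac)


def simulate_drydown(
    params: DrydownSimParams,
    sample_id: str = "sim",
    species: str = "",
    tree_id: str = "",
    integration_step: float = 60.0,
) -> DrydownRecord:
    """Integrate the forward drydown model and sample noisy weighings.

    Mass loss per internal step is g(RWC)*VPD/P*A*dt converted to grams via
    the molar mass of water; the noiseless trajectory starts at ``w_sat`` and
    is nonincreasing.  Balance noise is i.i.d. Gaussian per weighing,
    truncated at +-3 sd so a weighing never reports an impossible mass gain.
    The first weighing (the saturated reference measurement) is taken
    noiseless, as it defines the record's ``w_sat``.
    """
    p = params
    chamber_vpd = vpd(p.chamber)
    water = p.w_sat - p.w_dry
    n_weigh = int(np.floor(p.duration / p.weighing_interval)) + 1
    weigh_times = np.arange(n_weigh) * p.weighing_interval

    flux_scale = (
        p.leaf_area_two_sided * chamber_vpd / p.chamber.pressure * WATER_MOLAR_MASS / 1000.0
    )  # g s-1 per (mmol m-2 s-1) of conductance

    masses = np.empty(n_weigh)
    masses[0] = p.w_sat
    mass = p.w_sat
    t = 0.0
    k = 1
    while k < n_weigh:
        t_next = weigh_times[k]
        while t < t_next:
            dt = min(integration_step, t_next - t)
            rwc = (mass - p.w_dry) / water
            g = _conductance_of_rwc(rwc, p)
            mass = max(mass - g * flux_scale * dt, p.w_dry)
            t += dt
        masses[k] = mass
        k += 1

    rng = np.random.default_rng(p.seed)
    if p.balance_sd > 0:
        noise = rng.normal(0.0, p.balance_sd, size=n_weigh)
        noise = np.clip(noise, -3 * p.balance_sd, 3 * p.balance_sd)
        noise[0] = 0.0
        noisy = masses + noise
    else:
        noisy = masses.copy()
    noisy = np.maximum(noisy, p.w_dry + 1e-12)

    return DrydownRecord(
        sample_id=sample_id,
        times=weigh_times,
        masses=noisy,
        w_sat=p.w_sat,
        w_dry=p.w_dry,
        area_two_sided=p.leaf_area_two_sided,
        chamber=p.chamber,
        species=species,
        tree_id=tree_id,
        true_gmin=p.true_gmin,
    )


@dataclass(frozen=True)
class ClimateSimParams:
    """Shape of a synthetic hot-day diurnal climate record.

    Temperature follows a half-sinusoid from ``t_min`` at the start of the
    record up to ``t_max`` at ``peak_s`` and back down; the vapor pressure is
    held constant all day (the observed structure of hot anticyclonic days,
    where absolute humidity barely moves while RH swings).  Defaults: a
    12-hour 08:00-20:00 record at 5-min resolution peaking at 14:00.
    """

    t_min: float = 17.0
    t_max: float = 32.2
    vapor_pressure: float = 1.41  # kPa; ~29-30% RH at the default t_max
    start_s: float = 0.0  # s; 0 = 08:00
    duration: float = 43200.0  # s (12 h)
    step: float = 300.0  # s
    peak_s: float = 21600.0  # s after start (14:00)
    pressure: float = 94.9

    def __post_init__(self) -> None:
        if self.t_max < self.t_min:
            raise ValueError("t_max must not be below t_min")
        if self.duration % self.step != 0:
            raise ValueError("step must divide the record duration")
        if not (0 < self.peak_s < self.duration):
            raise ValueError("peak must fall inside the record")


def simulate_diurnal_climate(params: ClimateSimParams) -> DiurnalClimate:
    """Sinusoid-shaped temperature day with a constant vapor-pressure curve."""
    p = params
    times = np.arange(0.0, p.duration + p.step / 2, p.step)
    amp = p.t_max - p.t_min
    temp = np.where(
        times <= p.peak_s,
        p.t_min + amp * np.sin(0.5 * np.pi * times / p.peak_s),
        p.t_min + amp * np.cos(0.5 * np.pi * (times - p.peak_s) / (p.duration - p.peak_s)),
    )
    e = np.full_like(times, p.vapor_pressure)
    rh, capped = rh_from_vapor_pressure(e, temp)
    return DiurnalClimate(
        times=times,
        temperature=temp,
        rh=rh,
        vapor_pressure=e,
        pressure=p.pressure,
        rh_capped=capped,
    )


def climate_from_extremes(
    t_max: float = 32.2,
    rh_min: float = 29.4,
    t_min: float = 17.0,
    pressure: float = 94.9,
    step: float = 300.0,
) -> DiurnalClimate:
    """Synthetic day hitting a given maximum temperature and minimum RH.

    The constant vapor pressure is chosen so that RH bottoms out at ``rh_min``
    exactly when temperature peaks at ``t_max`` — hence the day's maximum VPD
    is es(t_max)*(1 - rh_min/100).
    """
    e = saturation_vapor_pressure(t_max) * rh_min / 100.0
    return simulate_diurnal_climate(
        ClimateSimParams(
            t_min=t_min, t_max=t_max, vapor_pressure=e, pressure=pressure, step=step
        )
    )


@dataclass(frozen=True)
class TraitSimParams:
    """Generative cross-species trait panel with configurable effect signs.

    Minimum conductance (on the log scale) is built from standardised log
    g_max, log stomatal size and cuticle thickness with the given effect
    sizes, plus Gaussian noise — the correlation structure expected if leaky
    stomata and cuticular investment co-determine residual water loss.
    """

    n_species: int = 9
    effect_gmax: float = 0.16  # positive: leakier high-conductance canopies
    effect_ct: float = 0.12  # positive: thick-cuticle species still leak more
    effect_ss: float = -0.16  # negative: large stomata seal better
    noise_scale: float = 0.08  # sd of log10 g_min noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 3:
            raise ValueError("need at least 3 species")


def simulate_trait_table(params: TraitSimParams) -> pd.DataFrame:
    """Species panel of g_min, g_max, stomatal and cuticular traits."""
    p = params
    rng = np.random.default_rng(p.seed)
    n = p.n_species

    log_gmax = rng.normal(np.log10(200.0), 0.18, n)
    length = rng.uniform(15.0, 40.0, n)  # guard-cell length, um
    width = rng.uniform(10.0, 30.0, n)  # guard-cell pair width, um
    ss = length * width
    log_ss = np.log10(ss)
    sd = rng.uniform(80.0, 400.0, n)  # stomata mm-2
    ct_ad = rng.uniform(2.0, 7.0, n)  # um
    ct_ab = ct_ad / rng.uniform(1.6, 2.4, n)  # adaxial ~2x abaxial
    ct_total = 0.5 * (ct_ad + ct_ab)
    sla = rng.uniform(8.0, 25.0, n)

    def z(x):
        s = np.std(x)
        return (x - np.mean(x)) / s if s > 0 else np.zeros_like(x)

    # effect sizes are log10(g_min) units per SD of the (possibly logged) trait
    log_gmin = (
        np.log10(2.0)
        + p.effect_gmax * z(log_gmax)
        + p.effect_ct * z(ct_total)
        + p.effect_ss * z(log_ss)
        + rng.normal(0.0, p.noise_scale, n)
    )
    return pd.DataFrame(
        {
            "species": [f"sp{i+1:02d}" for i in range(n)],
            "gmin_25C": 10.0 ** log_gmin,
            "g_max": 10.0 ** log_gmax,
            "stomatal_density": sd,
            "guard_cell_length": length,
            "guard_cell_width": width,
            "stomatal_size": ss,
            "ct_adaxial": ct_ad,
            "ct_abaxial": ct_ab,
            "ct_total": ct_total,
            "sla": sla,
        }
    )
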