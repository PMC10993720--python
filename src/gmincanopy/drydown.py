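"""Minimum leaf conductance (g_min) from detached-leaf drydown mass series.

A drydown experiment weighs a detached, rehydrated leaf repeatedly while it
desiccates in a climate-controlled chamber.  Between two weighings the water
conductance of the leaf surface is

    J = W_loss / (dT * A * VPD) * P          [mmol m-2 s-1]

with W_loss the mass loss converted to mmol of water (molar mass
18.015 g mol-1), dT the interval length (s), A the total two-sided leaf area
(m2), VPD the chamber vapor pressure deficit (kPa) and P the chamber air
pressure (kPa, default 98.0).  Plotting J against the leaf relative water
content

    RWC = (W_fre - W_dry) / (W_sat - W_dry)

shows an initial stomatal decline followed by a near-horizontal cuticular
plateau; g_min is the mean of J over the plateau, taken between 80% and 50%
RWC (full stomatal closure above artifact territory).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .psychro import AirState, vpd

__all__ = [
    "WATER_MOLAR_MASS",
    "DrydownRecord",
    "ConductanceCurve",
    "GminEstimate",
    "GminEstimationError",
    "compute_rwc",
    "leaf_area_from_sla",
    "conductance_curve",
    "estimate_gmin",
    "aggregate_gmin",
]

#: Molar mass of water, g mol-1 (equivalently mg mmol-1).
WATER_MOLAR_MASS = 18.015

#: Default RWC window for the cuticular plateau (fractions, inclusive).
DEFAULT_RWC_WINDOW = (0.50, 0.80)


class GminEstimationError(ValueError):
    """Raised when a conductance curve cannot support a g_min estimate."""


@dataclass
class DrydownRecord:
    """One leaf/twig desiccation experiment.

    ``times`` are seconds since the first weighing; ``masses`` the fresh
    weights (g) at those times.  ``w_sat`` and ``w_dry`` are the saturated and
    oven-dry reference masses; ``area_two_sided`` the total (two-sided) leaf
    area in m2.
    """

    sample_id: str
    times: np.ndarray
    masses: np.ndarray
    w_sat: float
    w_dry: float
    area_two_sided: float
    chamber: AirState
    species: str = ""
    tree_id: str = ""
    leaf_age_class: str = "n/a"
    true_gmin: float | None = None  # populated by the simulator for oracle tests

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.times.shape != self.masses.shape:
            raise ValueError("times and masses must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.w_sat <= self.w_dry:
            raise ValueError("w_sat must exceed w_dry")
        if np.any(self.masses <= self.w_dry):
            raise ValueError("fresh masses must stay above the dry mass")
        if self.area_two_sided <= 0:
            raise ValueError("leaf area must be positive")


@dataclass
class ConductanceCurve:
    """Per-interval conductance J paired with the interval's mean RWC."""

    sample_id: str
    midpoint_times: np.ndarray
    water_loss: np.ndarray  # g per interval
    mean_rwc: np.ndarray  # fraction
    conductance: np.ndarray  # mmol m-2 s-1
    excluded: np.ndarray  # bool, negative-loss intervals flagged out

    def __len__(self) -> int:
        return self.midpoint_times.size


@dataclass
class GminEstimate:
    """g_min (mmol m-2 s-1) with window occupancy and plateau diagnostics."""

    sample_id: str
    gmin: float
    n_intervals_used: int
    rwc_window: tuple[float, float]
    plateau_slope: float
    qc_flags: list[str] = field(default_factory=list)
    species: str = ""
    tree_id: str = ""


def compute_rwc(w_fre, w_sat: float, w_dry: float):
    """Relative water content (W_fre - W_dry)/(W_sat - W_dry), clamped to [0, 1].

    Returns ``(rwc, flagged)`` where ``flagged`` marks values that fell outside
    [0, 1] before clamping (weighing noise can push the first point above the
    saturated reference).
    """
    if w_sat <= w_dry:
        raise ValueError("w_sat must exceed w_dry")
    rwc = (np.asarray(w_fre, dtype=float) - w_dry) / (w_sat - w_dry)
    flagged = (rwc < 0.0) | (rwc > 1.0)
    rwc = np.clip(rwc, 0.0, 1.0)
    if np.ndim(w_fre) == 0:
        return float(rwc), bool(flagged)
    return rwc, flagged


def leaf_area_from_sla(sla: float, dry_mass: float, sidedness_factor: float = 2.0) -> float:
    """Leaf area (m2) from specific leaf area (m2 kg-1, projected) and dry mass (kg).

    The drydown conductance formula wants the *total* evaporating area.  For
    flat broadleaves the two-sided area is twice the projected area (default
    factor 2).  For conifer needles the projected-to-total conversion depends
    on needle geometry and is left configurable; 2 is kept as the default and
    documented as a bias knob.
    """
    if sla <= 0 or dry_mass <= 0:
        raise ValueError("sla and dry_mass must be positive")
    return sidedness_factor * sla * dry_mass


def conductance_curve(
    record: DrydownRecord,
    pressure: float | None = None,
    noise_tolerance: float = 0.0,
) -> ConductanceCurve:
    """Per-interval leaf water conductance from a drydown mass series.

    Intervals with a mass *gain* beyond ``noise_tolerance`` (g) are flagged and
    excluded from downstream estimation rather than producing negative J.
    """
    if record.times.size < 2:
        raise ValueError("need at least two weighings")
    chamber_vpd = vpd(record.chamber)
    if chamber_vpd <= 0:
        raise ValueError("chamber VPD must be positive (air saturated?)")
    p = record.chamber.pressure if pressure is None else pressure

    dt = np.diff(record.times)
    w_loss = -np.diff(record.masses)  # positive when the leaf loses water
    w_loss_mmol = w_loss * 1000.0 / WATER_MOLAR_MASS
    j = w_loss_mmol / (dt * record.area_two_sided * chamber_vpd) * p

    rwc, _ = compute_rwc(record.masses, record.w_sat, record.w_dry)
    mean_rwc = 0.5 * (rwc[:-1] + rwc[1:])
    excluded = w_loss < -noise_tolerance
    return ConductanceCurve(
        sample_id=record.sample_id,
        midpoint_times=0.5 * (record.times[:-1] + record.times[1:]),
        water_loss=w_loss,
        mean_rwc=mean_rwc,
        conductance=j,
        excluded=excluded,
    )


def estimate_gmin(
    curve: ConductanceCurve,
    window: tuple[float, float] = DEFAULT_RWC_WINDOW,
    min_intervals: int = 3,
    slope_threshold: float = 5.0,
    species: str = "",
    tree_id: str = "",
) -> GminEstimate:
    """g_min as the mean conductance over the RWC plateau window (inclusive).

    The plateau slope (OLS slope of J against RWC inside the window,
    mmol m-2 s-1 per unit RWC) is reported as a diagnostic; estimates with
    |slope| above ``slope_threshold`` are flagged, not rejected.
    """
    if len(curve) == 0:
        raise GminEstimationError("empty conductance curve")
    lo, hi = min(window), max(window)
    in_window = (curve.mean_rwc >= lo) & (curve.mean_rwc <= hi) & ~curve.excluded
    n_used = int(in_window.sum())
    if n_used < min_intervals:
        raise GminEstimationError(
            f"only {n_used} interval(s) fall in the RWC window [{lo}, {hi}] "
            f"(minimum {min_intervals}); curve spans RWC "
            f"{curve.mean_rwc.min():.2f}-{curve.mean_rwc.max():.2f}"
        )
    j = curve.conductance[in_window]
    rwc = curve.mean_rwc[in_window]
    gmin = float(np.mean(j))
    if np.ptp(rwc) > 0:
        slope = float(np.polyfit(rwc, j, 1)[0])
    else:
        slope = float("nan")
    flags = []
    if np.isfinite(slope) and abs(slope) > slope_threshold:
        flags.append("plateau-not-horizontal")
    if gmin < 0:
        flags.append("negative-gmin")
    return GminEstimate(
        sample_id=curve.sample_id,
        gmin=gmin,
        n_intervals_used=n_used,
        rwc_window=(lo, hi),
        plateau_slope=slope,
        qc_flags=flags,
        species=species,
        tree_id=tree_id,
    )


def _mean_se(values: pd.Series) -> pd.Series:
    n = values.count()
    return pd.Series(
        {
            "mean": values.mean(),
            "se": values.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
            "n": n,
        }
    )


def aggregate_gmin(
    estimates: pd.DataFrame,
    value_col: str = "gmin",
    functional_groups: dict[str, str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Hierarchical leaf -> tree -> species -> functional-group aggregation.

    ``estimates`` needs columns ``species``, ``tree_id`` and ``value_col``.
    Leaves are averaged within a tree, tree means within a species, species
    means within a functional group; the SE at each level comes from the
    entities one level below (so a single-member group has an undefined SE,
    reported as NaN).  Returns a dict with ``tree``, ``species`` and (when
    ``functional_groups`` maps species -> group) ``group`` tables.
    """
    required = {"species", "tree_id", value_col}
    missing = required - set(estimates.columns)
    if missing:
        raise ValueError(f"estimates table missing columns: {sorted(missing)}")

    tree = (
        estimates.groupby(["species", "tree_id"])[value_col]
        .apply(_mean_se)
        .unstack()
        .reset_index()
    )
    species = (
        tree.groupby("species")["mean"].apply(_mean_se).unstack().reset_index()
    )
    out = {"tree": tree, "species": species}
    if functional_groups is not None:
        sp = species.copy()
        sp["group"] = sp["species"].map(functional_groups)
        group = sp.groupby("group")["mean"].apply(_mean_se).unstack().reset_index()
        out["group"] = group
    return out
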