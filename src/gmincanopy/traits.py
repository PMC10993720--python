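"""Stomatal/cuticular trait metrics and their cross-species correlations.

Stomatal size is the guard-cell length times the width of the guard-cell
pair (SS = L*W, um2); the fraction of the epidermis allocated to stomata is

    f_gc = (pi/2) * W * L * SD

with L and W in mm and stomatal density SD in mm-2 (an elliptical footprint
per stomate).  Cross-species relationships between minimum conductance and
these traits are quantified with Pearson correlations, with an optional
per-trait log10 transform (defaults: SD, SS and g_max are logged, which
follows the usual right-skew of those traits).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StomatalTraits",
    "CuticleTraits",
    "stomatal_size",
    "guard_cell_fraction",
    "cuticle_total",
    "correlate_traits",
    "DEFAULT_LOG10_TRAITS",
]

#: Traits log10-transformed by default before correlating against g_min.
DEFAULT_LOG10_TRAITS = frozenset({"stomatal_density", "stomatal_size", "g_max"})


@dataclass(frozen=True)
class StomatalTraits:
    """Stomatal morphometrics for one species (areal units as noted)."""

    stomatal_density: float  # count mm-2
    guard_cell_length: float  # um
    guard_cell_width: float  # um, width of the guard-cell pair

    @property
    def stomatal_size(self) -> float:
        return stomatal_size(self.guard_cell_length, self.guard_cell_width)

    @property
    def f_gc(self) -> float:
        return guard_cell_fraction(
            self.guard_cell_length, self.guard_cell_width, self.stomatal_density
        )


@dataclass(frozen=True)
class CuticleTraits:
    """Adaxial/abaxial cuticle thickness (um); total is their mean."""

    ct_adaxial: float
    ct_abaxial: float

    @property
    def ct_total(self) -> float:
        return cuticle_total(self.ct_adaxial, self.ct_abaxial)


def stomatal_size(length_um: float, width_um: float) -> float:
    """Stomatal size SS = L * W, um2."""
    if length_um < 0 or width_um < 0:
        raise ValueError("guard-cell dimensions must be nonnegative")
    return length_um * width_um


def guard_cell_fraction(length_um: float, width_um: float, density_mm2: float) -> float:
    """Fraction of epidermis occupied by guard-cell pairs, dimensionless.

    f_gc = (pi/2)*W*L*SD with L, W converted um -> mm.  Values above 1 signal
    inconsistent units; they are returned as-is but a warning flag accompanies
    them via :class:`StomatalTraits` consumers (check explicitly if needed).
    """
    if density_mm2 < 0:
        raise ValueError("stomatal density must be nonnegative")
    l_mm = length_um / 1000.0
    w_mm = width_um / 1000.0
    return (math.pi / 2.0) * w_mm * l_mm * density_mm2


def cuticle_total(ct_adaxial: float, ct_abaxial: float) -> float:
    """Total cuticular thickness as the mean of the two leaf sides, um."""
    return 0.5 * (ct_adaxial + ct_abaxial)


def correlate_traits(
    table: pd.DataFrame,
    gmin_col: str = "gmin_25C",
    trait_cols: list[str] | None = None,
    log10_traits: frozenset[str] | set[str] = DEFAULT_LOG10_TRAITS,
    log10_gmin: bool = False,
) -> pd.DataFrame:
    """Pearson correlations of each trait against minimum conductance.

    One row per trait with columns ``r``, ``p``, ``n`` and ``transform``.
    Missing species are dropped pairwise.  A trait with zero variance (or
    fewer than 3 complete pairs) yields NaN r/p and a ``note`` explaining why.
    No multiple-testing correction is applied by default (raw per-trait
    p-values, matching common practice for small cross-species panels).
    """
    if trait_cols is None:
        trait_cols = [c for c in table.columns if c not in (gmin_col, "species", "group")]
    rows = []
    y_all = table[gmin_col].astype(float)
    for trait in trait_cols:
        x_all = table[trait].astype(float)
        ok = x_all.notna() & y_all.notna()
        x, y = x_all[ok].to_numpy(), y_all[ok].to_numpy()
        transform = "log10" if trait in log10_traits else "identity"
        note = ""
        r = p = np.nan
        if x.size < 3:
            note = "fewer than 3 complete species pairs"
        else:
            if transform == "log10":
                if np.any(x <= 0):
                    note = "nonpositive values; log10 skipped"
                    transform = "identity"
                else:
                    x = np.log10(x)
            yv = np.log10(y) if log10_gmin else y
            if np.ptp(x) == 0 or np.ptp(yv) == 0:
                note = "zero variance; correlation undefined"
            else:
                r, p = stats.pearsonr(x, yv)
        rows.append(
            {
                "trait": trait,
                "r": float(r) if np.isfinite(r) else np.nan,
                "p": float(p) if np.isfinite(p) else np.nan,
                "n": int(x.size),
                "transform": transform,
                "note": note,
            }
        )
    return pd.DataFrame(rows)
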