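"""Report-table formatting: group summaries and scenario grids at 1 d.p.

Published ecophysiology tables round half away from zero (a group mean of
3.15 prints as 3.2), so formatting goes through a decimal half-up helper
rather than Python's banker's rounding.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = ["round_half_up", "group_summary", "conductance_report", "emin_report"]


def round_half_up(x, ndigits: int = 1):
    """Decimal round-half-away-from-zero (vectorised over arrays/Series)."""
    q = Decimal(1).scaleb(-ndigits)

    def _one(v):
        if v is None or (isinstance(v, float) and not np.isfinite(v)):
            return np.nan
        return float(Decimal(repr(float(v))).quantize(q, rounding=ROUND_HALF_UP))

    if isinstance(x, pd.Series):
        return x.map(_one)
    if np.ndim(x) > 0:
        return np.array([_one(v) for v in np.asarray(x, dtype=float)])
    return _one(x)


def group_summary(
    species_table: pd.DataFrame,
    value_col: str,
    group_col: str = "group",
) -> pd.DataFrame:
    """Functional-group mean +- SE over species means (n = species per group)."""
    def _agg(s: pd.Series) -> pd.Series:
        vals = s.dropna()
        n = vals.size
        return pd.Series(
            {
                "mean": vals.mean() if n else np.nan,
                "se": vals.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
                "n": n,
            }
        )

    return (
        species_table.groupby(group_col)[value_col].apply(_agg).unstack().reset_index()
    )


def conductance_report(species_table: pd.DataFrame, ndigits: int = 1) -> pd.DataFrame:
    """Species x {g_min, g_max} grid with functional-group rows appended.

    ``species_table`` needs columns species, group, gmin, gmax (SE columns
    optional).  Group rows carry the mean over species means and the SE over
    species (undefined SE left blank); everything rounds half-up at
    ``ndigits``.
    """
    rows = []
    for _, r in species_table.iterrows():
        rows.append(
            {
                "name": r["species"],
                "level": "species",
                "gmin": round_half_up(r["gmin"], ndigits),
                "gmin_se": round_half_up(r.get("gmin_se"), ndigits),
                "gmax": round_half_up(r["gmax"], ndigits),
                "gmax_se": round_half_up(r.get("gmax_se"), ndigits),
            }
        )
    for grp, sub in species_table.groupby("group"):
        row = {"name": grp, "level": "group"}
        for col in ("gmin", "gmax"):
            vals = sub[col].dropna()
            row[col] = round_half_up(vals.mean(), ndigits)
            row[f"{col}_se"] = (
                round_half_up(vals.std(ddof=1) / np.sqrt(vals.size), ndigits)
                if vals.size > 1
                else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows, columns=["name", "level", "gmin", "gmin_se", "gmax", "gmax_se"])


def emin_report(
    sweep_table: pd.DataFrame,
    scenario_max_temperatures=(32.2, 35.0, 40.0),
    ndigits: int = 1,
) -> pd.DataFrame:
    """Wide species x scenario-maximum grid from a tidy scenario sweep.

    ``sweep_table`` is the tidy output of the canopy sweep (columns species,
    max_T_C, e_std_L_per_m2, optionally e_tree_L).  For each requested
    scenario maximum the closest swept scenario is used (they coincide on the
    0.1 degC grid whenever the target is reachable).
    """
    if sweep_table.empty:
        return pd.DataFrame(columns=["species"])
    out = []
    for sp, sub in sweep_table.groupby("species", sort=False):
        row = {"species": sp}
        for t_target in scenario_max_temperatures:
            i = (sub["max_T_C"] - t_target).abs().idxmin()
            row[f"e_std_{t_target:g}C"] = round_half_up(
                sub.loc[i, "e_std_L_per_m2"], ndigits
            )
            if "e_tree_L" in sub and pd.notna(sub.loc[i, "e_tree_L"]):
                row[f"e_tree_{t_target:g}C"] = round_half_up(sub.loc[i, "e_tree_L"], ndigits)
        out.append(row)
    return pd.DataFrame(out)
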