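"""Published species-level measurements from the nine-species study site.

Season-mean minimum conductance and maximum stomatal conductance (both
mmol m-2 s-1, per tree replicates), the canopy-to-basal-area scaling ratio R
(m2 projected leaf area per m2 stem basal area), and the standardized daily
residual canopy transpiration (L per m2 basal area) under the measured hot
day (max 32.2 degC) and two elevated scenarios.  These serve as inputs for
aggregation, fold-change and cross-species-spread calculations; six species
are deciduous angiosperms and three are evergreen gymnosperm conifers.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "FUNCTIONAL_GROUPS",
    "species_conductance_table",
    "canopy_scaling_table",
    "emin_standardized_table",
    "temperature_response_endpoints",
    "HOT_DAY_T_MAX_C",
    "HOT_DAY_RH_MIN_PCT",
]

#: Extremes of the measured hot drought day used for the canopy simulations.
HOT_DAY_T_MAX_C = 32.2
HOT_DAY_RH_MIN_PCT = 29.4

FUNCTIONAL_GROUPS: dict[str, str] = {
    "Acer": "Angiosperm",
    "Carpinus": "Angiosperm",
    "Fagus": "Angiosperm",
    "Fraxinus": "Angiosperm",
    "Quercus": "Angiosperm",
    "Sorbus": "Angiosperm",
    "Abies": "Gymnosperm",
    "Picea": "Gymnosperm",
    "Pinus": "Gymnosperm",
}

# species, season-mean g_min (mmol m-2 s-1), SE, n trees, g_max, SE, n trees
_CONDUCTANCE = [
    ("Acer", 4.8, 0.4, 5, 275.7, 20.4, 4),
    ("Carpinus", 1.2, 0.1, 5, 149.6, 11.9, 4),
    ("Fagus", 2.5, 0.2, 5, 178.7, 28.7, 4),
    ("Fraxinus", 2.9, 0.4, 3, 225.2, 6.5, 3),
    ("Quercus", 2.7, 0.1, 5, 373.4, 58.0, 4),
    ("Sorbus", 4.8, None, 2, 369.7, None, 2),
    ("Abies", 1.5, 0.2, 4, 114.6, 7.2, 4),
    ("Picea", 1.5, 0.1, 5, 146.7, 30.3, 4),
    ("Pinus", 0.8, 0.1, 5, 158.1, 18.4, 4),
]

# species, R (m2 m-2), standardized E_min_canop (L m-2 day-1) at scenario
# maximum temperatures 32.2 / 35 / 40 degC
_EMIN = [
    ("Acer", 611.0, 33.3, 49.8, 97.8),
    ("Carpinus", 1046.6, 24.6, 34.9, 62.1),
    ("Fagus", 1161.3, 36.7, 50.5, 85.6),
    ("Fraxinus", 379.5, 23.1, 33.6, 62.8),
    ("Quercus", 401.9, 21.1, 30.7, 57.5),
    ("Sorbus", 406.3, 30.9, 45.0, 84.2),
    ("Abies", 274.2, 6.9, 10.6, 21.9),
    ("Picea", 836.8, 13.8, 19.0, 32.3),
    ("Pinus", 96.1, 2.0, 2.7, 4.3),
]

# species with published 25 -> 50 degC conductance endpoints (mmol m-2 s-1)
_ENDPOINTS = {
    "Acer": (2.8, 9.7),
    "Abies": (0.8, 3.0),
}


def species_conductance_table() -> pd.DataFrame:
    """Season-mean g_min and g_max per species with SE and tree replication."""
    df = pd.DataFrame(
        _CONDUCTANCE,
        columns=["species", "gmin", "gmin_se", "gmin_n", "gmax", "gmax_se", "gmax_n"],
    )
    df["group"] = df["species"].map(FUNCTIONAL_GROUPS)
    return df


def canopy_scaling_table() -> pd.DataFrame:
    """Canopy projected-leaf-area-to-basal-area ratio R per species."""
    return pd.DataFrame(
        [(s, r) for s, r, *_ in _EMIN], columns=["species", "r_ratio"]
    )


def emin_standardized_table() -> pd.DataFrame:
    """Standardized daily residual canopy transpiration per scenario maximum."""
    return pd.DataFrame(
        _EMIN,
        columns=["species", "r_ratio", "emin_32.2C", "emin_35C", "emin_40C"],
    )


def temperature_response_endpoints() -> dict[str, tuple[float, float]]:
    """Published (g_min at 25 degC, g_min at 50 degC) endpoints per species."""
    return dict(_ENDPOINTS)
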