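#!/usr/bin/env python
"""Cross-species trait correlations against minimum conductance.

Draws a nine-species panel from the trait generator (g_min positively tied
to g_max and cuticle thickness, negatively to stomatal size) and computes
Pearson correlations with the default log10 policy, mirroring how field
panels are analysed.
"""

from pathlib import Path

import pandas as pd

from gmincanopy.simulate import TraitSimParams, simulate_trait_table
from gmincanopy.traits import correlate_traits

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 0


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    table = simulate_trait_table(TraitSimParams(n_species=9, seed=SEED))
    table.to_csv(RESULTS / "trait_table.csv", index=False)
    corr = correlate_traits(
        table,
        trait_cols=[
            "stomatal_density",
            "stomatal_size",
            "g_max",
            "ct_total",
            "sla",
        ],
    )
    corr.to_csv(RESULTS / "trait_correlations.csv", index=False)
    print(corr.to_string(index=False))
    print(
        "signs: SS "
        + ("negative" if corr.set_index("trait").loc["stomatal_size", "r"] < 0 else "positive")
        + ", g_max "
        + ("positive" if corr.set_index("trait").loc["g_max", "r"] > 0 else "negative")
        + ", CT_total "
        + ("positive" if corr.set_index("trait").loc["ct_total", "r"] > 0 else "negative")
    )


if __name__ == "__main__":
    main()
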