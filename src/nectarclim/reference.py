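"""Published reference inputs for the climate-comparison reproduction.

Previously reported optimum temperatures (°C, 24-h means) for six
Mediterranean species flowering January-June, used as inputs to reproduce
the paired-t comparison against the default climate scenario.  The values
are inputs, not outputs: every statistic below is recomputed at call time
from these numbers by the package's own operations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .climate import BASELINE, ClimateScenario, paired_t_optima, scenario_temperature
from .simulate import compute_24h_mean

_SPECIES = ("sp_jan", "sp_mar", "sp_apr", "sp_may", "sp_jun_a", "sp_jun_b")
_MONTHS = (1, 3, 4, 5, 6, 6)

_OPTIMA = {
    "mean_volume": (15.7, 12.4, 16.4, 23.1, 25.9, 30.9),
    "sugar_per_flower": (16.0, 12.5, np.nan, 20.8, 25.7, 28.7),
    "sugar_per_plant": (17.7, 14.7, 15.3, 20.8, 25.4, 22.5),
    "n_flowers": (19.7, 15.9, 18.9, 18.7, 24.7, 20.2),
}


def published_optima() -> pd.DataFrame:
    """Long-format table of the published per-species trait optima."""
    rows = []
    for trait, values in _OPTIMA.items():
        for sp, month, val in zip(_SPECIES, _MONTHS, values):
            rows.append(
                {"species": sp, "flowering_month": month, "trait": trait,
                 "t_opt": val}
            )
    return pd.DataFrame(rows)


# target id -> (trait, flowering group, scenario level)
_TARGETS = {
    "t1": ("mean_volume", "early", BASELINE),
    "t2": ("mean_volume", "late", BASELINE),
    "t3": ("mean_volume", "early", "max"),
    "t4": ("sugar_per_plant", "late", BASELINE),
    "t5": ("n_flowers", "late", "max"),
    "t6": ("sugar_per_flower", "early", BASELINE),
    "t7": ("sugar_per_flower", "late", "max"),
    "t8": ("n_flowers", "early", BASELINE),
    "t9": ("n_flowers", "late", "p75"),
    "t10": ("sugar_per_plant", "late", "max"),
}


def target_statistics() -> dict:
    """Recompute the reference comparison statistics from scratch.

    Returns ``{target_id: {"value": t statistic, "n": pairs}}`` for the ten
    paired t-tests plus the 24-h mean temperature check (t11).
    """
    scenario = ClimateScenario()
    table = published_optima()
    early = [m <= 4 for m in table["flowering_month"]]
    table["flowering_group"] = np.where(early, "early", "late")
    out = {}
    for tid, (trait, group, level) in _TARGETS.items():
        sub = table[(table["trait"] == trait) & (table["flowering_group"] == group)]
        refs = [
            scenario_temperature(int(m), level, scenario)
            for m in sub["flowering_month"]
        ]
        cmp = paired_t_optima(
            sub["t_opt"].to_numpy(), refs, flowering_group=group,
            trait=trait, level=level,
        )
        out[tid] = {"value": round(cmp.t, 3), "n": cmp.n}
    out["t11"] = {"value": compute_24h_mean(7.0, 14.0), "n": 1}
    return out
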