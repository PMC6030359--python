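"""Baseline and projected flowering-month temperatures, paired-t comparisons.

Compares per-species trait optima against the long-term monthly mean
temperature of each species' flowering month and against that mean plus
seasonal warming increments for the end of the century.  The 75th-percentile
and maximal increments ship as defaults; the median ("p50") increments are
not published and must be supplied explicitly — requesting them without
configuration fails loudly rather than inventing numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .optima import significance_band

BASELINE = "baseline"
LEVELS = (BASELINE, "p50", "p75", "max")

SEASONS = {
    "winter": (12, 1, 2),
    "spring": (3, 4, 5),
    "summer": (6, 7, 8),
    "autumn": (9, 10, 11),
}

#: long-term (1958-2001) monthly mean temperatures, °C, for the flowering
#: months of the default study layout
DEFAULT_BASELINES = {1: 9.2, 3: 11.9, 4: 15.9, 5: 21.3, 6: 26.2}

#: end-of-century seasonal warming increments, °C (stabilization scenarios;
#: p50 deliberately absent — see module docstring)
DEFAULT_INCREMENTS = {
    "p75": {"winter": 2.4, "spring": 2.7, "summer": 3.3},
    "max": {"winter": 3.0, "spring": 3.7, "summer": 5.5},
}

COMPARED_TRAITS = (
    "mean_volume",
    "sugar_per_flower",
    "sugar_per_plant",
    "n_flowers",
)


class ScenarioError(KeyError):
    """Missing baseline or increment in a climate scenario."""


class GroupAssignmentError(ValueError):
    """Flowering month outside the early/late study design."""


class PairingError(ValueError):
    """Not enough valid pairs for a paired t-test."""


def season_of(month: int) -> str:
    for name, months in SEASONS.items():
        if month in months:
            return name
    raise ValueError(f"month must be in 1..12, got {month}")


@dataclass
class ClimateScenario:
    """Monthly baselines plus per-season warming increments by level."""

    baselines: dict = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    increments: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_INCREMENTS.items()}
    )
    label: str = "default"

    def __post_init__(self):
        for level, seasonal in self.increments.items():
            for season, inc in seasonal.items():
                if inc < 0:
                    raise ValueError(f"increment {level}/{season} must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "ClimateScenario":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(
            baselines={int(k): float(v) for k, v in raw["baselines"].items()},
            increments={
                lvl: {s: float(x) for s, x in seasonal.items()}
                for lvl, seasonal in raw.get("increments", {}).items()
            },
            label=raw.get("label", "custom"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                {
                    "label": self.label,
                    "baselines": self.baselines,
                    "increments": self.increments,
                },
                fh, sort_keys=False,
            )


def scenario_temperature(month: int, level: str, scenario: ClimateScenario) -> float:
    """Baseline (or baseline + seasonal increment) for a flowering month."""
    if month not in scenario.baselines:
        raise ScenarioError(f"no baseline temperature configured for month {month}")
    base = scenario.baselines[month]
    if level == BASELINE:
        return float(base)
    if level not in scenario.increments:
        raise ScenarioError(
            f"warming increments for level {level!r} are not configured; "
            "supply them explicitly (no silent default)"
        )
    season = season_of(month)
    seasonal = scenario.increments[level]
    if season not in seasonal:
        raise ScenarioError(f"level {level!r} has no increment for season {season!r}")
    return float(base + seasonal[season])


def assign_flowering_group(species: str, flowering_month: int) -> str:
    """Months 1-4 -> 'early', 5-6 -> 'late'; anything else is out of design."""
    if flowering_month in (1, 2, 3, 4):
        return "early"
    if flowering_month in (5, 6):
        return "late"
    raise GroupAssignmentError(
        f"{species}: flowering month {flowering_month} is outside the "
        "early (Jan-Apr) / late (May-Jun) design"
    )


@dataclass
class PairedComparison:
    flowering_group: str
    trait: str
    level: str
    n: int
    df: int
    t: float
    p: float
    annotation: str


def paired_t_optima(
    optima, references, flowering_group: str = "", trait: str = "", level: str = ""
) -> PairedComparison:
    """Two-sided paired t-test of optima against reference temperatures.

    Pairs with an undefined optimum are dropped pairwise.  Uses the sample
    SD (n-1) of the differences; df = n-1.
    """
    opt = np.asarray(optima, dtype=float)
    ref = np.asarray(references, dtype=float)
    if opt.shape != ref.shape:
        raise PairingError("optima and references must pair one-to-one")
    keep = ~(np.isnan(opt) | np.isnan(ref))
    d = opt[keep] - ref[keep]
    n = int(d.size)
    if n < 2:
        raise PairingError(f"need >= 2 pairs, have {n}")
    sd = d.std(ddof=1)
    if sd == 0:
        raise PairingError("zero variance of pair differences: t undefined")
    t = float(d.mean() / (sd / np.sqrt(n)))
    df = n - 1
    p = float(2 * stats.t.sf(abs(t), df))
    return PairedComparison(
        flowering_group=flowering_group, trait=trait, level=level,
        n=n, df=df, t=t, p=p, annotation=significance_band(p),
    )


def build_comparison_table(
    optima_table: pd.DataFrame,
    scenario: ClimateScenario | None = None,
    levels=(BASELINE, "p75", "max"),
) -> pd.DataFrame:
    """Paired t-tests for every trait x flowering group x scenario level.

    ``optima_table`` needs columns species, flowering_month, trait, t_opt
    (NaN where no optimum exists).  Sugar concentration is excluded: its
    response is linear in several species, so no optimum is defined.
    Failed cells (too few pairs, degenerate differences) are emitted with
    NaN statistics and the failure reason in ``note``.
    """
    scenario = scenario or ClimateScenario()
    rows = []
    table = optima_table.copy()
    table["flowering_group"] = [
        assign_flowering_group(s, m)
        for s, m in zip(table["species"], table["flowering_month"])
    ]
    for trait in COMPARED_TRAITS:
        sub_t = table[table["trait"] == trait]
        for group in ("early", "late"):
            sub = sub_t[sub_t["flowering_group"] == group]
            for level in levels:
                base = {
                    "trait": trait, "flowering_group": group, "level": level,
                }
                try:
                    refs = [
                        scenario_temperature(int(m), level, scenario)
                        for m in sub["flowering_month"]
                    ]
                    cmp = paired_t_optima(
                        sub["t_opt"].to_numpy(), refs,
                        flowering_group=group, trait=trait, level=level,
                    )
                    rows.append(
                        {**base, "n": cmp.n, "df": cmp.df, "t": cmp.t,
                         "p": cmp.p, "annotation": cmp.annotation, "note": ""}
                    )
                except (PairingError, ScenarioError) as err:
                    rows.append(
                        {**base, "n": np.nan, "df": np.nan, "t": np.nan,
                         "p": np.nan, "annotation": "", "note": str(err)}
                    )
    return pd.DataFrame(rows)
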