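"""Input validation for flower-record and count tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

FLOWER_COLUMNS = [
    "plant_id", "species", "group", "step", "time_index",
    "day_temp", "mean24_temp", "flower_index", "volume",
    "concentration", "is_empty",
]
COUNT_COLUMNS = [
    "plant_id", "species", "group", "step", "time_index",
    "day_temp", "mean24_temp", "n_flowers",
]

ERROR = "error"
WARNING = "warning"


def _issue(rule, severity, message, row=None, column=None):
    return {
        "rule": rule, "severity": severity, "message": message,
        "row": row, "column": column,
    }


def _check_columns(df, required, issues):
    missing = [c for c in required if c not in df.columns]
    for col in missing:
        issues.append(_issue("missing_column", ERROR, f"column {col!r} absent", column=col))
    return not missing


def _check_range(df, col, mask, rule, message, issues, severity=ERROR):
    bad = np.flatnonzero(mask.to_numpy())
    for i in bad[:50]:  # cap the report, not the detection
        issues.append(_issue(rule, severity, message, row=int(df.index[i]), column=col))
    if len(bad) > 50:
        issues.append(_issue(rule, severity, f"... {len(bad) - 50} more rows", column=col))


def validate_flowers(df: pd.DataFrame) -> list[dict]:
    """Machine-readable issue list for a per-flower record table."""
    issues: list[dict] = []
    if not _check_columns(df, FLOWER_COLUMNS, issues):
        return issues
    vol = pd.to_numeric(df["volume"], errors="coerce")
    conc = pd.to_numeric(df["concentration"], errors="coerce")
    _check_range(df, "volume", vol.isna() | (vol < 0), "volume_range",
                 "volume must be a number >= 0", issues)
    conc_given = df["concentration"].notna()
    _check_range(df, "concentration", conc_given & (conc.isna() | (conc < 0) | (conc > 100)),
                 "concentration_range", "concentration must be in [0, 100] % w/w or empty",
                 issues)
    empty = df["is_empty"].astype(bool)
    _check_range(df, "is_empty", empty & (vol > 0), "empty_with_volume",
                 "empty flowers must have volume 0", issues)
    _check_range(df, "group", ~df["group"].isin(["experimental", "control"]),
                 "group_label", "group must be 'experimental' or 'control'", issues)
    step = pd.to_numeric(df["step"], errors="coerce")
    _check_range(df, "step", step.isna() | (step < 0) | (step != np.floor(step)),
                 "step_index", "step must be a non-negative integer", issues)
    _check_range(df, "species", df["species"].isna() | (df["species"].astype(str) == ""),
                 "species_label", "species must be non-empty", issues)
    dup = df.duplicated(subset=["plant_id", "step", "flower_index"], keep=False)
    if dup.any():
        issues.append(
            _issue("duplicate_flower", ERROR,
                   f"{int(dup.sum())} duplicated (plant, step, flower_index) rows")
        )
    # one species per plant
    per_plant = df.groupby("plant_id")["species"].nunique()
    for pid in per_plant[per_plant > 1].index:
        issues.append(
            _issue("plant_species_conflict", ERROR,
                   f"plant {pid!r} is assigned to multiple species")
        )
    return issues


def validate_counts(df: pd.DataFrame) -> list[dict]:
    """Issue list for a per-plant-day flower-count table."""
    issues: list[dict] = []
    if not _check_columns(df, COUNT_COLUMNS, issues):
        return issues
    n = pd.to_numeric(df["n_flowers"], errors="coerce")
    _check_range(df, "n_flowers", n.isna() | (n < 0), "count_range",
                 "n_flowers must be a number >= 0", issues)
    # deterministic (noiseless) simulations carry fractional expected counts
    _check_range(df, "n_flowers", n.notna() & (n >= 0) & (n != np.round(n)),
                 "count_integral", "n_flowers is not an integer", issues,
                 severity=WARNING)
    dup = df.duplicated(subset=["plant_id", "step"], keep=False)
    if dup.any():
        issues.append(
            _issue("duplicate_count", ERROR,
                   f"{int(dup.sum())} duplicated (plant, step) rows")
        )
    return issues


def has_errors(issues: list[dict]) -> bool:
    return any(i["severity"] == ERROR for i in issues)
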