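"""Trait derivation, imputation, transformation and standardization.

Turns per-flower records plus per-plant flower counts into the five
plant-day analysis traits:

1. nectar volume per flower (µl, mean of sampled flowers, empties count as 0)
2. sugar concentration per flower (% w/w, mean over non-empty flowers)
3. sugar content per flower (mg, via volume x concentration x density)
4. sugar content per plant (mg, mean sugar per flower x open flowers)
5. number of flowers per plant

and applies the log/logit transforms and z-standardization the response
models assume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

TRAITS = (
    "mean_volume",
    "mean_concentration",
    "sugar_per_flower",
    "sugar_per_plant",
    "n_flowers",
)

TRAIT_TRANSFORMS = {
    "mean_volume": "log",
    "mean_concentration": "logit",
    "sugar_per_flower": "log",
    "sugar_per_plant": "log",
    "n_flowers": "log",
}


class DomainError(ValueError):
    """Input value outside its physical domain."""


class DegenerateInputError(ValueError):
    """Input with no usable variation."""


# ---------------------------------------------------------------------------
# sugar content

# Sucrose-solution density (g/ml = mg/µl) as a quadratic in % w/w, anchored
# at d(0) = 0.9982 and within 0.06% of standard 20 °C density tables over
# 0-75% w/w.
_DENSITY_A1 = 3.76704568e-03
_DENSITY_A2 = 1.73672688e-05


def sucrose_density(concentration) -> np.ndarray | float:
    """Density of a sucrose solution in mg/µl for concentration in % w/w."""
    c = np.asarray(concentration, dtype=float)
    if np.any((c < 0) | (c > 100)):
        raise DomainError("concentration must be within [0, 100] % w/w")
    d = 0.9982 + _DENSITY_A1 * c + _DENSITY_A2 * c**2
    return float(d) if np.isscalar(concentration) else d


def sugar_per_flower(volume, concentration):
    """Sugar content in mg from volume (µl) and concentration (% w/w)."""
    v = np.asarray(volume, dtype=float)
    if np.any(v < 0):
        raise DomainError("volume must be >= 0")
    c = np.asarray(concentration, dtype=float)
    out = v * (c / 100.0) * sucrose_density(np.where(np.isnan(c), 0.0, c))
    out = np.where(np.isnan(c), np.nan, out)
    if np.isscalar(volume) and np.isscalar(concentration):
        return float(out)
    return out


# ---------------------------------------------------------------------------
# imputation

@dataclass
class ImputationLog:
    n_imputed: int = 0
    n_flagged_plant_days: int = 0
    flagged: list = field(default_factory=list)  # (plant_id, step)


def impute_concentration(flowers: pd.DataFrame) -> tuple[pd.DataFrame, ImputationLog]:
    """Fill unmeasurable concentrations from the same plant-day.

    A non-empty flower whose nectar volume was too small to read gets the
    arithmetic mean of the concentrations observed on the other flowers of
    that plant on that day.  Empty flowers stay missing.  Plant-days where
    every flower with nectar lacks a reading are flagged and left missing
    (they drop out of the concentration and sugar traits).
    """
    out = flowers.copy()
    log = ImputationLog()
    for (plant, step), idx in out.groupby(["plant_id", "step"], sort=False).groups.items():
        sub = out.loc[idx]
        nonempty = sub[~sub["is_empty"]]
        missing = nonempty[nonempty["concentration"].isna()]
        if missing.empty:
            continue
        observed = nonempty["concentration"].dropna()
        if observed.empty:
            log.n_flagged_plant_days += 1
            log.flagged.append((plant, int(step)))
            continue
        out.loc[missing.index, "concentration"] = observed.mean()
        log.n_imputed += len(missing)
    return out, log


# ---------------------------------------------------------------------------
# plant-day aggregation

def aggregate_plant_day(flowers: pd.DataFrame, counts: pd.DataFrame) -> pd.DataFrame:
    """Collapse sampled flowers to one record per plant x temperature step.

    Empty flowers contribute 0 to mean volume and sugar but are excluded
    from the concentration mean.  ``sugar_per_plant`` multiplies the mean
    per-flower sugar by the number of open flowers counted on that day.
    """
    fl = flowers.copy()
    fl["sugar_mg"] = sugar_per_flower(fl["volume"].to_numpy(), fl["concentration"].to_numpy())
    fl.loc[fl["is_empty"], "sugar_mg"] = 0.0

    keys = ["plant_id", "species", "group", "step"]
    rows = []
    for key, sub in fl.groupby(keys, sort=False):
        n_sampled = len(sub)
        nonempty = sub[~sub["is_empty"]]
        conc = nonempty["concentration"].dropna()
        mean_conc = conc.mean() if len(conc) else np.nan
        # a non-empty flower without any concentration reading poisons the
        # sugar mean for that day: leave sugar traits missing
        sugar_ok = not nonempty["concentration"].isna().any()
        mean_sugar = sub["sugar_mg"].mean() if sugar_ok else np.nan
        rows.append(
            key
            + (
                sub["time_index"].iloc[0],
                sub["mean24_temp"].iloc[0],
                n_sampled,
                int(sub["is_empty"].sum()),
                sub["volume"].mean(),
                mean_conc,
                mean_sugar,
            )
        )
    agg = pd.DataFrame(
        rows,
        columns=keys
        + [
            "time_index", "mean24_temp", "n_sampled", "n_empty",
            "mean_volume", "mean_concentration", "sugar_per_flower",
        ],
    )
    merged = agg.merge(
        counts[["plant_id", "step", "n_flowers"]], on=["plant_id", "step"], how="left"
    )
    merged["sugar_per_plant"] = merged["sugar_per_flower"] * merged["n_flowers"]
    return merged


# ---------------------------------------------------------------------------
# transforms and standardization

@dataclass
class TraitSeries:
    """A trait vector with its transform and standardization metadata."""

    name: str
    raw: np.ndarray
    transformed: np.ndarray
    standardized: np.ndarray | None
    transform: str  # log | logit | none
    offset: float
    mean: float | None
    sd: float | None
    scope: str  # per-species | pooled


def log_offset(values: np.ndarray) -> float:
    """Half the smallest positive value, used only when zeros are present."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if not np.any(v == 0):
        return 0.0
    positive = v[v > 0]
    if positive.size == 0:
        raise DegenerateInputError("all values are zero; log transform undefined")
    return float(positive.min() / 2.0)


def logit_percent(values: np.ndarray, eps: float | None = None) -> tuple[np.ndarray, float]:
    """Logit of a percentage with boundary clamping p in [eps, 1-eps]."""
    v = np.asarray(values, dtype=float)
    if np.any((v[~np.isnan(v)] < 0) | (v[~np.isnan(v)] > 100)):
        raise DomainError("percentages must be within [0, 100]")
    if eps is None:
        n = np.sum(~np.isnan(v))
        eps = 1.0 / (2.0 * max(n, 1))
    p = np.clip(v / 100.0, eps, 1.0 - eps)
    return logit(p), eps


def transform_trait(values, name: str, scope: str = "per-species") -> TraitSeries:
    """Apply the trait's fixed transform (log for quantities, logit for %)."""
    raw = np.asarray(values, dtype=float)
    kind = TRAIT_TRANSFORMS.get(name, "none")
    offset = 0.0
    if kind == "log":
        if np.any(raw[~np.isnan(raw)] < 0):
            raise DomainError(f"{name}: negative values cannot be log-transformed")
        offset = log_offset(raw)
        transformed = np.log(raw + offset)
    elif kind == "logit":
        transformed, offset = logit_percent(raw)
    else:
        transformed = raw.copy()
    return TraitSeries(
        name=name, raw=raw, transformed=transformed, standardized=None,
        transform=kind, offset=float(offset), mean=None, sd=None, scope=scope,
    )


def standardize(values) -> tuple[np.ndarray, float, float]:
    """z-score with sample SD (n-1); errors on degenerate input."""
    v = np.asarray(values, dtype=float)
    finite = v[~np.isnan(v)]
    if finite.size < 2 or np.unique(finite).size < 2:
        raise DegenerateInputError("need >= 2 distinct values to standardize")
    mean = float(finite.mean())
    sd = float(finite.std(ddof=1))
    if sd == 0:
        raise DegenerateInputError("zero variance")
    return (v - mean) / sd, mean, sd


def standardize_series(series: TraitSeries) -> TraitSeries:
    z, mean, sd = standardize(series.transformed)
    series.standardized = z
    series.mean = mean
    series.sd = sd
    return series


def destandardize(z, mean: float, sd: float):
    return np.asarray(z, dtype=float) * sd + mean


def inverse_transform(series: TraitSeries, transformed):
    t = np.asarray(transformed, dtype=float)
    if series.transform == "log":
        return np.exp(t) - series.offset
    if series.transform == "logit":
        return 100.0 * expit(t)
    return t


def shapiro_normality(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p; reporting only, never gates a transform."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 3:
        raise DegenerateInputError("Shapiro-Wilk needs at least 3 values")
    if v.size > 5000:
        raise DomainError("Shapiro-Wilk supports at most 5000 values")
    if np.unique(v).size < 2:
        raise DegenerateInputError("constant input")
    res = stats.shapiro(v)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# model frames

def build_trait_frame(
    plant_day: pd.DataFrame, trait: str, scope: str = "per-species"
) -> tuple[pd.DataFrame, dict]:
    """Prepare a standardized modelling frame for one trait.

    Returns a frame with ``value_std``, ``temp_std`` and ``time_std`` columns
    plus a metadata dict (transform, offset, means/SDs) sufficient to map
    fitted curves back to °C and raw trait units.  ``scope='per-species'``
    requires a single-species frame; ``scope='pooled'`` standardizes across
    everything it is given.
    """
    if scope not in ("per-species", "pooled"):
        raise ValueError(f"unknown scope {scope!r}")
    if scope == "per-species" and plant_day["species"].nunique() > 1:
        raise ValueError("per-species scope requires a single species")

    df = plant_day.copy()
    series = transform_trait(df[trait].to_numpy(), trait, scope=scope)
    keep = ~np.isnan(series.transformed)
    df = df.loc[keep].copy()
    series.raw = series.raw[keep]
    series.transformed = series.transformed[keep]
    standardize_series(series)
    df["value_std"] = series.standardized

    temp_std, temp_mean, temp_sd = standardize(df["mean24_temp"].to_numpy())
    df["temp_std"] = temp_std
    try:
        time_std, time_mean, time_sd = standardize(df["time_index"].to_numpy())
    except DegenerateInputError:
        time_std, time_mean, time_sd = np.zeros(len(df)), 0.0, 1.0
    df["time_std"] = time_std

    meta = {
        "trait": trait,
        "scope": scope,
        "transform": series.transform,
        "offset": series.offset,
        "value_mean": series.mean,
        "value_sd": series.sd,
        "temp_mean": temp_mean,
        "temp_sd": temp_sd,
        "time_mean": time_mean,
        "time_sd": time_sd,
        "n_dropped_missing": int((~keep).sum()),
    }
    return df, meta
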