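"""End-to-end pipeline: simulate/load -> preprocess -> fit -> optima -> climate.

Every stage writes tidy delimited text into the output directory; a JSON
manifest records the seed, configuration, per-fit convergence and every
surfaced design decision so two runs with identical configs are
byte-comparable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .climate import (
    BASELINE,
    ClimateScenario,
    assign_flowering_group,
    build_comparison_table,
)
from .models import (
    ModelDesignError,
    aic_select,
    fit_flowering_group_model,
    fit_quadratic_lmm,
    fit_time_group_interaction,
    fit_zinb_empty,
    r2_nakagawa,
)
from .optima import (
    SHAPE_SYMBOLS,
    NoOptimumError,
    NoRangeError,
    classify_shape,
    format_range,
    optimal_range,
)
from .preprocess import (
    TRAITS,
    DegenerateInputError,
    aggregate_plant_day,
    build_trait_frame,
    impute_concentration,
)
from .simulate import (
    default_designs,
    default_profiles,
    generate_control,
    generate_experiment,
    read_records,
    write_records,
)
from .validate import has_errors, validate_counts, validate_flowers

log = logging.getLogger("nectarclim")


class ValidationFailure(RuntimeError):
    """Input tables failed validation."""


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "nectarclim_out"
    flowers_path: str | None = None   # load instead of simulating
    counts_path: str | None = None
    scenario_path: str | None = None
    levels: tuple = (BASELINE, "p75", "max")
    alpha: float = 0.05
    truncate_ranges: bool = False
    band_fraction: float = 0.05
    standardization_scope: str = "per-species"   # for the per-species fits
    time_standardization: str = "pooled"         # combined control model
    df_method: str = "normal"
    run_control_models: bool = True
    run_zinb: bool = True
    species: tuple | None = None   # subset of the default layout

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "levels" in raw:
            raw["levels"] = tuple(raw["levels"])
        if "species" in raw and raw["species"] is not None:
            raw["species"] = tuple(raw["species"])
        return cls(**raw)


def simulate_stage(config: RunConfig, outdir: Path):
    """Generate the default multi-species dataset (plus controls)."""
    profiles = default_profiles()
    designs = default_designs()
    names = config.species or tuple(profiles)
    all_flowers, all_counts, months = [], [], {}
    for name in names:
        profile, design = profiles[name], designs[name]
        months[name] = profile.flowering_month
        fl, cn = generate_experiment(profile, design, config.seed)
        all_flowers.append(fl)
        all_counts.append(cn)
        if design.control_mode != "none":
            fl_c, cn_c = generate_control(profile, design, config.seed)
            all_flowers.append(fl_c)
            all_counts.append(cn_c)
    flowers = pd.concat(all_flowers, ignore_index=True)
    counts = pd.concat(all_counts, ignore_index=True)
    write_records(flowers, outdir / "flowers.csv")
    write_records(counts, outdir / "counts.csv")
    return flowers, counts, months


def preprocess_stage(flowers: pd.DataFrame, counts: pd.DataFrame, outdir: Path):
    issues = validate_flowers(flowers) + validate_counts(counts)
    if has_errors(issues):
        (outdir / "validation.json").write_text(json.dumps(issues, indent=2))
        raise ValidationFailure(
            f"{sum(i['severity'] == 'error' for i in issues)} validation errors; "
            f"see {outdir / 'validation.json'}"
        )
    imputed, imp_log = impute_concentration(flowers)
    plant_day = aggregate_plant_day(imputed, counts)
    write_records(plant_day, outdir / "plant_day.csv")
    return plant_day, issues, imp_log


def control_models_stage(plant_day: pd.DataFrame, outdir: Path):
    """Per-species and combined time x group interaction fits (validation)."""
    rows = []
    with_control = [
        sp for sp, sub in plant_day.groupby("species")
        if set(sub["group"].unique()) == {"experimental", "control"}
    ]
    for trait in TRAITS:
        for scope_name, sub in [
            *[(sp, plant_day[plant_day["species"] == sp]) for sp in with_control],
            ("combined", plant_day[plant_day["species"].isin(with_control)]),
        ]:
            combined = scope_name == "combined"
            if combined and len(with_control) < 2:
                continue
            try:
                frame, meta = build_trait_frame(
                    sub, trait, scope="pooled" if combined else "per-species"
                )
                fit = fit_time_group_interaction(frame, meta, combined=combined)
            except (DegenerateInputError, ModelDesignError, ValueError) as err:
                log.warning("control model %s/%s failed: %s", trait, scope_name, err)
                continue
            for term in ("time:group", "time2:group"):
                rows.append(
                    {
                        "trait": trait, "scope": scope_name, "term": term,
                        "t": float(fit.zvalues.get(term, np.nan)),
                        "p": float(fit.pvalues.get(term, np.nan)),
                        "converged": fit.converged,
                    }
                )
    table = pd.DataFrame(rows)
    write_records(table, outdir / "table_control_interactions.csv")
    return table


def group_models_stage(plant_day: pd.DataFrame, months: dict, outdir: Path):
    """Early/late flowering-group interaction fits, one row block per trait."""
    exp = plant_day[plant_day["group"] == "experimental"].copy()
    exp["flowering_group"] = [
        assign_flowering_group(sp, months[sp]) for sp in exp["species"]
    ]
    rows = []
    for trait in TRAITS:
        try:
            frame, meta = build_trait_frame(exp, trait, scope="pooled")
            frame["flowering_group"] = exp.loc[frame.index, "flowering_group"]
            sel = aic_select(_pooled_plant_frame(frame), meta)
            quadratic = sel["chosen"] == "quadratic"
            fit = fit_flowering_group_model(frame, meta, quadratic=quadratic)
        except (DegenerateInputError, ModelDesignError, ValueError) as err:
            log.warning("flowering-group model for %s failed: %s", trait, err)
            continue
        r2m, r2c = r2_nakagawa(fit)
        for term in fit.params.index:
            rows.append(
                {
                    "trait": trait, "term": term,
                    "estimate": float(fit.params[term]),
                    "t": float(fit.zvalues[term]),
                    "p": float(fit.pvalues[term]),
                    "trend": sel["chosen"], "delta_aic": sel["delta_aic"],
                    "r2m": r2m, "r2c": r2c, "converged": fit.converged,
                }
            )
    table = pd.DataFrame(rows)
    write_records(table, outdir / "table_group_interactions.csv")
    return table


def _pooled_plant_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """AIC selection helper; keeps the plant random intercept only."""
    return frame[["plant_id", "value_std", "temp_std"]].assign(
        species=frame["species"]
    )


def optima_stage(plant_day: pd.DataFrame, months: dict, config: RunConfig, outdir: Path):
    """Per-species quadratic fits and 5%-band optimal ranges."""
    exp = plant_day[plant_day["group"] == "experimental"]
    rows = []
    for species, sub in exp.groupby("species"):
        for trait in TRAITS:
            row = {
                "species": species,
                "flowering_month": months[species],
                "trait": trait,
                "t_opt": np.nan, "t_lo": np.nan, "t_hi": np.nan,
                "shape": "", "annotation": "", "display": "–",
                "extrapolated": False, "note": "",
            }
            try:
                frame, meta = build_trait_frame(sub, trait, scope="per-species")
                fit = fit_quadratic_lmm(frame, meta)
                shape, annotation = classify_shape(fit, alpha=config.alpha)
                row["shape"] = SHAPE_SYMBOLS[shape]
                row["annotation"] = annotation
                opt = optimal_range(
                    fit,
                    band_fraction=config.band_fraction,
                    truncate=config.truncate_ranges,
                    alpha=config.alpha,
                    species=species,
                )
                row.update(
                    t_opt=opt.t_opt, t_lo=opt.t_lo, t_hi=opt.t_hi,
                    display=format_range(opt), extrapolated=opt.extrapolated,
                )
                log.info("fit %s/%s: shape=%s converged=%s", species, trait,
                         shape, fit.converged)
            except (DegenerateInputError, ModelDesignError, NoOptimumError,
                    NoRangeError, ValueError) as err:
                row["note"] = str(err)
                log.warning("optima %s/%s: %s", species, trait, err)
            rows.append(row)
    table = pd.DataFrame(rows)
    write_records(table, outdir / "table_optima.csv")
    return table


def climate_stage(optima_table: pd.DataFrame, config: RunConfig, outdir: Path):
    scenario = (
        ClimateScenario.from_yaml(config.scenario_path)
        if config.scenario_path
        else ClimateScenario()
    )
    table = build_comparison_table(optima_table, scenario, levels=config.levels)
    write_records(table, outdir / "table_climate_comparison.csv")
    return table


def zinb_stage(plant_day: pd.DataFrame, outdir: Path):
    """Empty-flower ZINB over the species that actually produce empties."""
    exp = plant_day[plant_day["group"] == "experimental"]
    with_empties = [
        sp for sp, sub in exp.groupby("species") if sub["n_empty"].sum() > 0
    ]
    if not with_empties:
        return pd.DataFrame()
    sub = exp[exp["species"].isin(with_empties)].copy()
    frame, meta = build_trait_frame(sub, "n_flowers", scope="pooled")
    frame["n_empty"] = sub.loc[frame.index, "n_empty"]
    fit = fit_zinb_empty(frame, meta=meta)
    rows = [
        {
            "term": term,
            "estimate": float(fit.params[term]),
            "se": float(fit.bse[term]),
            "z": float(fit.zvalues[term]),
            "p": float(fit.pvalues[term]),
            "zi_prob": fit.zi_prob,
            "species": ";".join(with_empties),
            "converged": fit.converged,
        }
        for term in fit.params.index
    ]
    table = pd.DataFrame(rows)
    write_records(table, outdir / "table_empty_flowers.csv")
    return table


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the output bundle as DataFrames."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    if config.flowers_path and config.counts_path:
        flowers = read_records(config.flowers_path)
        counts = read_records(config.counts_path)
        months = _infer_months(flowers)
    else:
        flowers, counts, months = simulate_stage(config, outdir)
    bundle["flowers"], bundle["counts"] = flowers, counts

    plant_day, issues, imp_log = preprocess_stage(flowers, counts, outdir)
    bundle["plant_day"] = plant_day

    if config.run_control_models and (flowers["group"] == "control").any():
        bundle["control_interactions"] = control_models_stage(plant_day, outdir)
    if len(set(months.values()) & {1, 2, 3, 4}) and len(set(months.values()) & {5, 6}):
        bundle["group_interactions"] = group_models_stage(plant_day, months, outdir)

    optima_table = optima_stage(plant_day, months, config, outdir)
    bundle["optima"] = optima_table
    bundle["climate"] = climate_stage(optima_table, config, outdir)
    if config.run_zinb:
        bundle["empty_flowers"] = zinb_stage(plant_day, outdir)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": {
            **dataclasses.asdict(config),
            "levels": list(config.levels),
            "species": list(config.species) if config.species else None,
        },
        "decisions": {
            "df_method": config.df_method,
            "standardization_scope_per_species_fits": config.standardization_scope,
            "time_standardization_combined": config.time_standardization,
            "truncate_ranges": config.truncate_ranges,
            "band_fraction": config.band_fraction,
            "log_offset_rule": "half smallest positive value when zeros present",
            "logit_epsilon_rule": "1/(2N)",
            "empty_flowers_in_volume_mean": True,
            "aic_refit": "ML",
            "curve_reporting": "REML",
        },
        "n_imputed_concentrations": imp_log.n_imputed,
        "n_flagged_plant_days": imp_log.n_flagged_plant_days,
        "validation_warnings": [i for i in issues if i["severity"] == "warning"],
        "extrapolation_flags": optima_table.loc[
            optima_table["extrapolated"], ["species", "trait"]
        ].to_dict("records"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    bundle["manifest"] = manifest
    return bundle


def _infer_months(flowers: pd.DataFrame) -> dict:
    """Flowering month per species, from a column if present, else unknown."""
    if "flowering_month" in flowers.columns:
        return (
            flowers.groupby("species")["flowering_month"].first().astype(int).to_dict()
        )
    profiles = default_profiles()
    months = {}
    for sp in flowers["species"].unique():
        if sp in profiles:
            months[sp] = profiles[sp].flowering_month
        else:
            raise ValueError(
                f"species {sp!r}: flowering month unknown; add a "
                "'flowering_month' column to the input"
            )
    return months
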