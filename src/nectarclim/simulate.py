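"""Synthetic climate-chamber experiments.

Generates per-flower nectar measurements and per-plant flower counts for a
stepped-temperature experiment (day setpoint raised by a fixed increment
every few days, night held 6 °C below day) together with an optional control
group kept at a constant or slowly drifting temperature.

The generative model mirrors the downstream analysis: each trait follows a
quadratic response on its model scale (log for volume and counts, logit for
concentration) around a species-specific optimum, plus a per-plant random
intercept, a shared time drift, and Gaussian residual noise.  Empty flowers
arise from a separate zero-inflation process whose probability grows with
distance from the optimum.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

NIGHT_OFFSET_C = 6.0

EXPERIMENTAL = "experimental"
CONTROL = "control"

# substream codes: changing n_plants must not reshuffle existing plants
_GROUP_CODE = {EXPERIMENTAL: 0, CONTROL: 1}


class DesignError(ValueError):
    """Invalid experiment design."""


class ProfileError(ValueError):
    """Invalid species profile."""


def compute_24h_mean(day_temp: float, dark_hours: float) -> float:
    """Time-weighted 24-h mean with night fixed 6 °C below day.

    Parameters
    ----------
    day_temp : day setpoint in °C.
    dark_hours : hours of darkness per 24 h, strictly in (0, 24).
    """
    if not 0 < dark_hours < 24:
        raise DesignError(f"dark_hours must be in (0, 24), got {dark_hours}")
    return day_temp - NIGHT_OFFSET_C * dark_hours / 24.0


@dataclass(frozen=True)
class TraitCurve:
    """Quadratic trait response on the model (log/logit) scale.

    model_value(T) = f(amplitude) - ((T - true_opt) / breadth)**2

    where f is log for log-scale traits and logit(amplitude/100) for
    concentration.  ``breadth`` may be ``inf`` for a flat (temperature
    independent) trait.
    """

    amplitude: float
    true_opt: float
    breadth: float

    def __post_init__(self):
        if not self.amplitude > 0:
            raise ProfileError(f"amplitude must be > 0, got {self.amplitude}")
        if not self.breadth > 0:
            raise ProfileError(f"breadth must be > 0, got {self.breadth}")

    def log_scale(self, temp):
        return np.log(self.amplitude) - ((np.asarray(temp, float) - self.true_opt) / self.breadth) ** 2

    def logit_scale(self, temp):
        if not 0 < self.amplitude < 100:
            raise ProfileError("concentration amplitude must be in (0, 100) % w/w")
        return logit(self.amplitude / 100.0) - ((np.asarray(temp, float) - self.true_opt) / self.breadth) ** 2


@dataclass(frozen=True)
class ExperimentDesign:
    """Stepped-temperature schedule and sampling layout for one group."""

    n_plants: int
    n_steps: int
    start_day_temp: float = 20.0
    increment: float = 3.0
    light_hours: float = 14.0
    flowers_sampled: int = 3
    control_mode: str = "none"  # none | constant_temp | ambient_series
    control_temp: float | None = None
    step_days: int = 3
    ambient_drift_per_step: float = 0.0

    def __post_init__(self):
        if self.n_plants < 1:
            raise DesignError("n_plants must be >= 1")
        if self.n_steps < 1:
            raise DesignError("n_steps must be >= 1")
        if not 0 < self.light_hours < 24:
            raise DesignError("light_hours must be in (0, 24)")
        if self.flowers_sampled < 1:
            raise DesignError("flowers_sampled must be >= 1")
        if self.control_mode not in ("none", "constant_temp", "ambient_series"):
            raise DesignError(f"unknown control_mode {self.control_mode!r}")
        if self.control_mode == "none" and not self.increment > 0:
            raise DesignError("increment must be > 0 for experimental schedules")
        if self.control_mode != "none" and self.control_temp is None:
            raise DesignError("control designs require control_temp")

    @property
    def dark_hours(self) -> float:
        return 24.0 - self.light_hours


def build_temperature_schedule(design: ExperimentDesign, group: str | None = None) -> pd.DataFrame:
    """Return one row per step with day setpoint and 24-h mean temperature.

    A design may describe both the stepped experimental schedule and a
    parallel control schedule; ``group`` selects which one.  By default a
    design with ``control_mode != 'none'`` yields the control schedule, a
    plain design the stepped one.
    """
    if group is None:
        group = CONTROL if design.control_mode != "none" else EXPERIMENTAL
    steps = np.arange(design.n_steps)
    if group == CONTROL:
        if design.control_mode == "constant_temp":
            day = np.full(design.n_steps, float(design.control_temp))
        elif design.control_mode == "ambient_series":
            day = design.control_temp + design.ambient_drift_per_step * steps
        else:
            raise DesignError("design has no control schedule (control_mode='none')")
    else:
        if not design.increment > 0:
            raise DesignError("increment must be > 0 for the experimental schedule")
        day = design.start_day_temp + design.increment * steps
    mean24 = np.array([compute_24h_mean(t, design.dark_hours) for t in day])
    return pd.DataFrame(
        {
            "step": steps,
            "time_index": steps * design.step_days,
            "day_temp": day,
            "mean24_temp": mean24,
        }
    )


@dataclass(frozen=True)
class SpeciesProfile:
    """True generative parameters for one species.

    ``nb_dispersion`` is the negative-binomial shape k (variance mu + mu^2/k);
    ``None`` switches flower counts to their deterministic means, which is
    useful for noiseless closure checks but yields non-integer counts.
    """

    species_name: str
    flowering_month: int
    volume_curve: TraitCurve = TraitCurve(2.0, 25.0, 10.0)
    concentration_curve: TraitCurve = TraitCurve(35.0, 25.0, 18.0)
    flowers_curve: TraitCurve = TraitCurve(60.0, 25.0, 14.0)
    plant_sd: float = 0.3
    resid_sd: float = 0.3
    conc_resid_sd: float = 0.15
    zero_inflation_base: float = 0.0
    zero_inflation_heat_slope: float = 0.0
    nb_dispersion: float | None = 5.0
    drift_linear: float = 0.0
    drift_quadratic: float = 0.0
    measure_threshold_ul: float = 0.05

    def __post_init__(self):
        if not 1 <= self.flowering_month <= 12:
            raise ProfileError("flowering_month must be in 1..12")
        if self.plant_sd < 0 or self.resid_sd < 0 or self.conc_resid_sd < 0:
            raise ProfileError("standard deviations must be >= 0")
        if not 0 <= self.zero_inflation_base < 1:
            raise ProfileError("zero_inflation_base must be in [0, 1)")
        if self.nb_dispersion is not None and not self.nb_dispersion > 0:
            raise ProfileError("nb_dispersion must be > 0 or None")


def _plant_rng(seed: int, group: str, plant_index: int) -> np.random.Generator:
    """Counter-scheme substream: (master seed, group code, plant index)."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_GROUP_CODE[group], plant_index))
    )


def _drift(profile: SpeciesProfile, t):
    return profile.drift_linear * t + profile.drift_quadratic * t**2


def _generate(profile: SpeciesProfile, design: ExperimentDesign, seed: int, group: str):
    schedule = build_temperature_schedule(design, group=group)
    zi_base = profile.zero_inflation_base
    zi_logit0 = logit(zi_base) if zi_base > 0 else None

    flower_rows = []
    count_rows = []
    for i in range(design.n_plants):
        rng = _plant_rng(seed, group, i)
        plant_id = f"{profile.species_name}-{group[0]}{i + 1:02d}"
        b_vol = rng.normal(0.0, profile.plant_sd)
        b_conc = rng.normal(0.0, profile.plant_sd)
        b_cnt = rng.normal(0.0, profile.plant_sd)
        for row in schedule.itertuples(index=False):
            temp, t = row.mean24_temp, row.time_index
            drift = _drift(profile, t)

            mu_cnt = np.exp(profile.flowers_curve.log_scale(temp) + drift + b_cnt)
            if profile.nb_dispersion is None:
                n_flowers = float(mu_cnt)
            else:
                lam = rng.gamma(profile.nb_dispersion, mu_cnt / profile.nb_dispersion)
                n_flowers = int(rng.poisson(lam))
            count_rows.append(
                (plant_id, profile.species_name, group, row.step, t, row.day_temp, temp, n_flowers)
            )

            eta_vol = profile.volume_curve.log_scale(temp) + drift + b_vol
            eta_conc = profile.concentration_curve.logit_scale(temp) + drift + b_conc
            if zi_logit0 is not None:
                p_empty = expit(
                    zi_logit0
                    + profile.zero_inflation_heat_slope * abs(temp - profile.volume_curve.true_opt)
                )
            else:
                p_empty = 0.0
            for j in range(design.flowers_sampled):
                volume = float(np.exp(eta_vol + rng.normal(0.0, profile.resid_sd)))
                conc = float(100.0 * expit(eta_conc + rng.normal(0.0, profile.conc_resid_sd)))
                is_empty = bool(rng.uniform() < p_empty)
                if is_empty:
                    volume = 0.0
                if is_empty or volume < profile.measure_threshold_ul:
                    conc = np.nan
                flower_rows.append(
                    (
                        plant_id, profile.species_name, group, row.step, t,
                        row.day_temp, temp, j + 1, volume, conc, is_empty,
                    )
                )

    flowers = pd.DataFrame(
        flower_rows,
        columns=[
            "plant_id", "species", "group", "step", "time_index",
            "day_temp", "mean24_temp", "flower_index", "volume",
            "concentration", "is_empty",
        ],
    )
    counts = pd.DataFrame(
        count_rows,
        columns=[
            "plant_id", "species", "group", "step", "time_index",
            "day_temp", "mean24_temp", "n_flowers",
        ],
    )
    return flowers, counts


def generate_experiment(profile: SpeciesProfile, design: ExperimentDesign, seed: int):
    """Simulate the stepped-temperature group.

    Returns ``(flowers, counts)``: per-flower records and per-plant-day
    flower counts.  Deterministic for fixed arguments; plant substreams are
    keyed by (seed, group, plant index) so growing ``n_plants`` leaves
    existing plants untouched.
    """
    return _generate(profile, design, seed, EXPERIMENTAL)


def generate_control(profile: SpeciesProfile, design: ExperimentDesign, seed: int):
    """Simulate a control group held at the control schedule.

    Temperature stays at the constant/ambient control schedule, so only the
    shared time drift moves the traits.
    """
    if design.control_mode == "none":
        raise DesignError("generate_control requires control_mode != 'none'")
    return _generate(profile, design, seed, CONTROL)


# ---------------------------------------------------------------------------
# tidy text I/O + provenance sidecar

def write_records(df: pd.DataFrame, path) -> None:
    """UTF-8 CSV, '.' decimal, missing values as empty fields."""
    df.to_csv(path, index=False, na_rep="")


def read_records(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_sidecar(profile: SpeciesProfile, design: ExperimentDesign, seed: int, path) -> None:
    payload = {
        "profile": dataclasses.asdict(profile),
        "design": dataclasses.asdict(design),
        "seed": int(seed),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def read_sidecar(path):
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    prof = dict(payload["profile"])
    for key in ("volume_curve", "concentration_curve", "flowers_curve"):
        prof[key] = TraitCurve(**prof[key])
    return SpeciesProfile(**prof), ExperimentDesign(**payload["design"]), payload["seed"]


# ---------------------------------------------------------------------------
# default study layout: six species, two flowering seasons

def default_profiles() -> dict[str, SpeciesProfile]:
    """Six seeded species profiles spanning winter to early summer flowering."""
    spec = [
        # name, month, volume opt, flowers opt
        ("early_jan", 1, 16.0, 19.5, 0.20, 0.08),
        ("early_mar", 3, 12.5, 16.0, 0.00, 0.00),
        ("early_apr", 4, 16.5, 19.0, 0.15, 0.08),
        ("late_may", 5, 23.0, 19.0, 0.00, 0.00),
        ("late_jun_a", 6, 26.0, 24.5, 0.20, 0.08),
        ("late_jun_b", 6, 30.5, 20.5, 0.02, 0.05),
    ]
    out = {}
    for name, month, vopt, fopt, zi, zi_slope in spec:
        out[name] = SpeciesProfile(
            species_name=name,
            flowering_month=month,
            volume_curve=TraitCurve(2.0, vopt, 10.0),
            concentration_curve=TraitCurve(35.0, vopt + 1.0, 18.0),
            flowers_curve=TraitCurve(60.0, fopt, 14.0),
            zero_inflation_base=zi,
            zero_inflation_heat_slope=zi_slope,
        )
    return out


def default_designs() -> dict[str, ExperimentDesign]:
    """Stepped schedules matching the default profiles' flowering seasons."""
    spec = {
        # name: (n_plants, n_steps, start_day, increment, light_hours, control_mode, control_temp)
        "early_jan": (19, 8, 7.0, 4.0, 10.0, "none", None),
        "early_mar": (12, 6, 12.0, 2.0, 11.0, "constant_temp", 15.0),
        "early_apr": (20, 7, 16.0, 2.0, 11.0, "none", None),
        "late_may": (15, 7, 14.5, 4.0, 14.0, "ambient_series", 20.0),
        "late_jun_a": (15, 8, 20.0, 3.0, 14.0, "ambient_series", 24.0),
        "late_jun_b": (15, 8, 20.0, 3.0, 14.0, "ambient_series", 24.0),
    }
    out = {}
    for name, (n_plants, n_steps, start, inc, light, mode, ctemp) in spec.items():
        out[name] = ExperimentDesign(
            n_plants=n_plants,
            n_steps=n_steps,
            start_day_temp=start,
            increment=inc,
            light_hours=light,
            control_mode=mode,
            control_temp=ctemp,
        )
    return out
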