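import numpy as np
import pandas as pd
import pytest

from nectarclim.preprocess import aggregate_plant_day, impute_concentration
from nectarclim.simulate import (
    ExperimentDesign,
    SpeciesProfile,
    TraitCurve,
    generate_control,
    generate_experiment,
)

TRUE_VOLUME_OPT = 25.0
TRUE_CONC_OPT = 26.0
TRUE_FLOWERS_OPT = 24.0


@pytest.fixture
def default_profile():
    return SpeciesProfile(
        "sp",
        flowering_month=6,
        volume_curve=TraitCurve(2.0, TRUE_VOLUME_OPT, 10.0),
        concentration_curve=TraitCurve(35.0, TRUE_CONC_OPT, 18.0),
        flowers_curve=TraitCurve(60.0, TRUE_FLOWERS_OPT, 14.0),
        zero_inflation_base=0.05,
        zero_inflation_heat_slope=0.1,
    )


@pytest.fixture
def noiseless_profile():
    return SpeciesProfile(
        "sp",
        flowering_month=6,
        volume_curve=TraitCurve(2.0, TRUE_VOLUME_OPT, 10.0),
        concentration_curve=TraitCurve(35.0, TRUE_CONC_OPT, 18.0),
        flowers_curve=TraitCurve(200.0, TRUE_FLOWERS_OPT, 14.0),
        plant_sd=0.0,
        resid_sd=0.0,
        conc_resid_sd=0.0,
        nb_dispersion=None,
    )


@pytest.fixture
def default_design():
    return ExperimentDesign(
        n_plants=15,
        n_steps=8,
        start_day_temp=20.0,
        increment=3.0,
        light_hours=14.0,
        control_mode="ambient_series",
        control_temp=24.0,
    )


@pytest.fixture
def small_dataset(default_profile, default_design):
    flowers, counts = generate_experiment(default_profile, default_design, seed=7)
    return flowers, counts


@pytest.fixture
def plant_day_table(small_dataset):
    flowers, counts = small_dataset
    imputed, _ = impute_concentration(flowers)
    return aggregate_plant_day(imputed, counts)


def make_dataset(profile, design, seed, with_control=False):
    flowers, counts = generate_experiment(profile, design, seed)
    if with_control:
        fc, cc = generate_control(profile, design, seed)
        flowers = pd.concat([flowers, fc], ignore_index=True)
        counts = pd.concat([counts, cc], ignore_index=True)
    return flowers, counts


def make_plant_day(profile, design, seed, with_control=False):
    flowers, counts = make_dataset(profile, design, seed, with_control)
    imputed, _ = impute_concentration(flowers)
    return aggregate_plant_day(imputed, counts)
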