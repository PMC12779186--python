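import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import perfusiontwin as pt
from perfusiontwin.datamodel import Campaign, RunRecord, flow_columns
from perfusiontwin.plant import PerfusionPlant, PlantConfig

settings.register_profile(
    "suite", deadline=None, max_examples=40, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

warnings.filterwarnings("ignore", message="constant input columns")
warnings.filterwarnings("ignore", category=pytest.PytestUnraisableExceptionWarning)

SEED = 42


def noiseless_config(**kw):
    cfg = PlantConfig(**kw)
    cfg.noise_cvs = {k: 0.0 for k in cfg.noise_cvs}
    cfg.via_noise_pp = 0.0
    cfg.inoc_cv = 0.0
    return cfg


@pytest.fixture(scope="session")
def mini_campaign():
    """Three short perfusion runs with default measurement noise."""
    runs = []
    for i, vvd in enumerate((0.8, 1.25, 1.8)):
        plant = PerfusionPlant(seed=SEED + i)
        for _ in range(8):
            plant.sample()
            sp = plant.protocol_setpoints()
            if plant.in_soc:
                sp = {"Temp": 35.25, "Stir": 1050.0, "VVD": vvd, "Pyr": 1.0}
            plant.advance_day(sp)
        plant.sample()
        runs.append(plant.to_run_record(f"m{i + 1}"))
    return Campaign(runs)


@pytest.fixture(scope="session")
def campaign24():
    """The standard 24-run training campaign at default noise."""
    return pt.generate_training_campaign(seed=SEED)


@pytest.fixture(scope="session")
def base_ensemble(campaign24):
    """A 20-submodel ensemble fitted on the full training campaign."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pt.train_ensemble(campaign24, seed=SEED, n_restarts=0)


def make_run(states_rows, flows_rows, run_id="h1", clone="A",
             mode="perfusion"):
    """Hand-built RunRecord from lists of dicts (missing columns filled)."""
    defaults = {"V": 0.213, "VCD": 40.0, "DCD": 1.0, "Via": 97.6, "Diam": 18.0,
                "Glc": 3.0, "Gln": 1.0, "Glu": 0.5, "Lac": 1.0, "Amm": 2.0,
                "Titer": 50.0, "Temp": 35.25, "Stir": 1050.0, "VVD": 1.0,
                "Pyr": 0.0, "DO": 50.0}
    rows = [{**defaults, **r} for r in states_rows]
    states = pd.DataFrame(rows, index=range(len(rows)))
    species = ("VCD", "DCD", "Glc", "Gln", "Glu", "Lac", "Amm", "Titer")
    fcols = flow_columns(species)
    frows = [{**dict.fromkeys(fcols, 0.0), **f} for f in flows_rows]
    flows = pd.DataFrame(frows, index=range(len(frows)))
    return RunRecord(run_id, clone, states, flows, mode=mode)
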