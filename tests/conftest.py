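import datetime as dt

import numpy as np
import pandas as pd
import pytest

from spacetoevent.occasions import OccasionTable
from spacetoevent.simulate import SimConfig, simulate_dataset
from spacetoevent.occasions import build_occasion_table
from spacetoevent.viewshed import camera_area

#: Availability ≡ 1 for one class: the estimator's own model, no diel bias.
FULL_AVAILABILITY = {
    "adult_female": {"crepuscular": 1.0, "diurnal": 1.0, "nocturnal": 1.0}
}


def make_table(
    areas_m2,
    presence,
    active=None,
    start=dt.datetime(2021, 8, 1, 9, 0),
    step=dt.timedelta(minutes=10),
) -> OccasionTable:
    """Hand-build a small occasion table from explicit presence rows."""
    presence = np.asarray(presence, dtype=bool)
    n_occ, n_cam = presence.shape
    if active is None:
        active = np.ones_like(presence)
    times = pd.date_range(start, periods=n_occ, freq=step)
    return OccasionTable(
        occasion_times=times,
        camera_ids=[f"C{i + 1}" for i in range(n_cam)],
        areas_m2=np.asarray(areas_m2, dtype=float),
        active=np.asarray(active, dtype=bool),
        presence=presence,
        step=step,
    )


def simulated_table(density=4.0, seed=0, availability=None, **config_kwargs):
    """Simulate one single-class dataset and build its occasion table."""
    cfg = SimConfig(
        true_density_per_km2={"adult_female": density},
        availability=availability or FULL_AVAILABILITY,
        seed=seed,
        **config_kwargs,
    )
    cameras, viewsheds, events, truth = simulate_dataset(cfg)
    areas = {m.camera_id: camera_area(m) for m in viewsheds}
    table = build_occasion_table(
        events,
        areas,
        (cfg.start, cfg.end, cfg.step),
        target_classes={"adult_female"},
    )
    return cfg, table, truth


@pytest.fixture(scope="session")
def big_sim_table():
    """One full-scale availability-1 dataset (~500 events), shared across
    tests that only read it."""
    cfg, table, truth = simulated_table(density=4.0, seed=2021)
    return cfg, table, truth
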