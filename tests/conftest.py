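"""Shared fixtures and small programmatic dataset builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from antcomp.dataset import (
    ARRIVALS_COLUMNS,
    Dataset,
    EVENTS_COLUMNS,
    PRESENCES_COLUMNS,
    UNITS_COLUMNS,
)
from antcomp.synthetic import generate_dataset, reference_scenarios


def make_units(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=UNITS_COLUMNS)
    df["point_index"] = df["point_index"].astype("Int64")
    return df


def tiny_dataset(events: list[tuple] | None = None, presences: list[tuple] | None = None) -> Dataset:
    """Two-forest micro-survey: one litter + one camera unit per forest."""
    units = make_units(
        [
            {"unit_id": "p-lit", "forest": "primary", "site": 1, "grid": 1,
             "method": "litter", "time_slot": "0800", "point_index": pd.NA},
            {"unit_id": "p-cam", "forest": "primary", "site": 1, "grid": 1,
             "method": "camera", "time_slot": "0800", "point_index": 1},
            {"unit_id": "l-lit", "forest": "logged", "site": 1, "grid": 1,
             "method": "litter", "time_slot": "0800", "point_index": pd.NA},
            {"unit_id": "l-cam", "forest": "logged", "site": 1, "grid": 1,
             "method": "camera", "time_slot": "0800", "point_index": 1},
        ]
    )
    pres = pd.DataFrame(presences or [], columns=PRESENCES_COLUMNS)
    if len(pres):
        pres["abundance"] = pres["abundance"].astype("int64")
    ev = pd.DataFrame(events or [], columns=EVENTS_COLUMNS)
    if len(ev):
        ev["time"] = ev["time"].astype("float64")
    arr = pd.DataFrame([], columns=ARRIVALS_COLUMNS)
    return Dataset(units=units, presences=pres, arrivals=arr, events=ev).validate()


def random_events(seed: int, n_events: int = 40, n_genera: int = 6, unit_id: str = "p-cam") -> pd.DataFrame:
    """Random valid classified-shaped events on one camera card (no mutual aggression unless asked)."""
    rng = np.random.default_rng(seed)
    genera = [f"G{i}" for i in range(n_genera)]
    rows = []
    for _ in range(n_events):
        i, j = rng.choice(n_genera, size=2, replace=False)
        u = rng.random()
        if u < 0.4:
            roles = ("neutral", "neutral")
        elif u < 0.7:
            roles = ("aggressive", "submissive")
        elif u < 0.95:
            roles = ("submissive", "aggressive")
        else:
            roles = ("aggressive", "aggressive")
        rows.append(
            {
                "unit_id": unit_id,
                "time": float(rng.uniform(0, 40)),
                "genus_a": genera[i],
                "genus_b": genera[j],
                "role_a": roles[0],
                "role_b": roles[1],
            }
        )
    return pd.DataFrame(rows, columns=EVENTS_COLUMNS)


@pytest.fixture(scope="session")
def rewired_scenario():
    return {s.name: s for s in reference_scenarios(seed=1)}["rewired"]


@pytest.fixture(scope="session")
def rewired_dataset(rewired_scenario):
    return generate_dataset(rewired_scenario.params)


@pytest.fixture(scope="session")
def null_dataset():
    params = {s.name: s for s in reference_scenarios(seed=1)}["null"].params
    return generate_dataset(params)
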