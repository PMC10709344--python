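from dataclasses import replace

import pandas as pd
import pytest

from orgscreen import default_scenarios, organoid_states, simulate_plate


def make_measurements(rows):
    """Rows of (plate, well, t, oid, bf, green, inv, inv_green) -> table."""
    df = pd.DataFrame(
        rows,
        columns=["plate_id", "well", "time_h", "organoid_id", "bf_area",
                 "green_area", "inv_area", "inv_green_area"],
    )
    df["brightness"] = 100.0
    df["texture"] = 10.0
    return df


@pytest.fixture()
def tiny_measurements():
    return make_measurements([
        ("P1", "A01", 0, 1, 1000.0, 0.0, 0.0, 0.0),
        ("P1", "A01", 24, 1, 2000.0, 100.0, 50.0, 10.0),
        ("P1", "B01", 0, 1, 800.0, 0.0, 0.0, 0.0),
        ("P1", "B01", 24, 1, 900.0, 400.0, 0.0, 0.0),
    ])


@pytest.fixture(scope="session")
def hetero_plate():
    """One simulated heterogeneous screen (70% sensitive / 30% resistant)."""
    cfg = replace(default_scenarios(11)["heterogeneous"], organoids_per_well=60.0)
    return simulate_plate(cfg)


@pytest.fixture(scope="session")
def hetero_states(hetero_plate):
    measurements, layout, _ = hetero_plate
    return organoid_states(measurements, layout)
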