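import numpy as np
import pandas as pd
import pytest

from acsnorms import ScoreTable, default_acs_battery
from acsnorms.synthetic_data import default_simulation_config, simulate_cohort


@pytest.fixture(scope="session")
def battery():
    return default_acs_battery()


@pytest.fixture(scope="session")
def cohort():
    """Mid-size clean synthetic cohort reused across read-only tests."""
    config = default_simulation_config(n_participants=300)
    return simulate_cohort(config, seed=2018)


@pytest.fixture
def small_table():
    """Hand-built two-participant, two-measure, two-occasion table."""
    rows = []
    scores = {
        ("P1", 1, "ConnectTheDotsI"): 30.0,
        ("P1", 2, "ConnectTheDotsI"): 28.0,
        ("P1", 1, "BoxTapping"): 9.0,
        ("P1", 2, "BoxTapping"): 10.0,
        ("P2", 1, "ConnectTheDotsI"): 45.0,
        ("P2", 2, "ConnectTheDotsI"): 41.0,
        ("P2", 1, "BoxTapping"): 7.0,
        ("P2", 2, "BoxTapping"): 8.0,
    }
    for (pid, occ, measure), value in scores.items():
        rows.append({"participant_id": pid, "occasion": occ,
                     "measure": measure, "raw_score": value})
    return ScoreTable(pd.DataFrame(rows))
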