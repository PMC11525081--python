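import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("stable", derandomize=True, deadline=None)
settings.load_profile("stable")

from ventrl import (
    RawEventTable,
    RewardParams,
    SimulatorConfig,
    VentilatorActionSpace,
    default_schema,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def action_space():
    return VentilatorActionSpace()


@pytest.fixture(scope="session")
def reward_params():
    return RewardParams()


@pytest.fixture(scope="session")
def small_cohort():
    """A small continuous-mode cohort shared by read-only tests."""
    return simulate_cohort(SimulatorConfig(n_patients=40, seed=7))


def make_events(rows, outcomes=None):
    """Build a RawEventTable from (pid, t, var, value) tuples."""
    events = pd.DataFrame(rows, columns=["patient_id", "time_h", "variable", "value"])
    if outcomes is None:
        pids = events["patient_id"].unique()
        outcomes = pd.DataFrame({
            "patient_id": pids,
            "hospital_mortality": np.zeros(len(pids), dtype=int),
            "wean_time_h": np.full(len(pids), np.nan),
        })
    return RawEventTable(events, outcomes)
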