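import numpy as np
import pandas as pd
import pytest

from shiftsense.day_labeling import label_days
from shiftsense.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    return CohortConfig(n_day=10, n_night=8, weeks=4, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """A small but complete simulated cohort (all streams)."""
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_labels(small_cohort):
    return label_days(small_cohort.evidence)


def make_minutes(
    participant_id: str,
    start: str,
    heart_rates,
    steps=None,
) -> pd.DataFrame:
    """Consecutive-minute stream starting at ``start``."""
    hr = np.asarray(heart_rates, dtype=float)
    n = len(hr)
    if steps is None:
        steps = np.zeros(n)
    ts = pd.Timestamp(start) + pd.to_timedelta(np.arange(n), unit="m")
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "timestamp": ts,
            "heart_rate": hr,
            "steps": np.asarray(steps, dtype=float),
        }
    )
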