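import warnings

import numpy as np
import pandas as pd
import pytest

from opstate import CohortConfig, ParticipantParams, ScenarioConfig
from opstate.difficulty import EVENT_COLUMNS

# sklearn emits convergence warnings for capped SVC fits on hopeless
# kernel configs during grid search; they are expected and harmless
warnings.filterwarnings("ignore", category=UserWarning)
try:
    from sklearn.exceptions import ConvergenceWarning
    warnings.filterwarnings("ignore", category=ConvergenceWarning)
except ImportError:  # pragma: no cover
    pass


def make_log(rows):
    """Event log from (t_appear, t_removed, kind, zone_row, zone_col) tuples."""
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


@pytest.fixture(scope="session")
def short_scenario():
    """A 5-min scenario with the same four-phase shape, for fast tests."""
    return ScenarioConfig(
        phase_durations=(30.0, 90.0, 90.0, 90.0),
        target_rate_per_phase=(0.0, 3.0, 8.0, 14.0),
        message_rate_per_phase=(0.0, 1.0, 2.0, 4.0),
        mean_processing_time=30.0,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Three participants over the default 25-min scenario."""
    from opstate import generate_cohort

    return generate_cohort(CohortConfig(n_participants=3), seed=7)


@pytest.fixture(scope="session")
def small_datasets(small_cohort):
    from opstate import cohort_datasets

    return cohort_datasets(small_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
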