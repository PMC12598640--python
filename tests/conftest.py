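import logging

import numpy as np
import pandas as pd
import pytest

from cureaudit import ScenarioConfig, generate_cohort, group_indicator

# fit-failure warnings in stress cells are expected; keep test output readable
logging.getLogger("cureaudit").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def high_rate_config():
    """The default high event-rate scenario: 25% susceptible, medians 4/4."""
    return ScenarioConfig(seed=20240901)


@pytest.fixture(scope="session")
def high_rate_cohort(high_rate_config):
    return generate_cohort(high_rate_config, 0)


@pytest.fixture(scope="session")
def well_followed_cohort():
    """n=10 000, equal medians, follow-up far past the median: the easy
    regime where every estimator should be close to truth."""
    cfg = ScenarioConfig(n_subjects=10_000, censor_upper=60.0,
                         admin_censor_times=(60.0,), seed=7)
    return group_indicator(generate_cohort(cfg, 0))


def make_toy_cohort(times, events, groups=None):
    times = np.asarray(times, float)
    events = np.asarray(events)
    groups = np.asarray(groups if groups is not None else np.ones_like(events))
    df = pd.DataFrame({
        "subject_id": np.arange(len(times)),
        "group": groups,
        "susceptible": events.astype(bool),
        "true_event_time": np.where(events == 1, times, np.inf),
        "censor_time": np.where(events == 1, np.inf, times),
        "observed_time": times,
        "event": events.astype(np.int8),
    })
    df["group2"] = (df["group"] == 2).astype(float)
    return df


@pytest.fixture
def toy_cohort():
    return make_toy_cohort
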