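"""Shared fixtures: small synthetic records and prepared channel sets.

Heavier fixtures are session-scoped so the forecaster tests share one
simulated patient instead of regenerating it per test.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from cgmbench import (SimulationConfig, inject_gaps, simulate_patient,
                      split_train_test, synthetic_seg_grid)
from cgmbench.preprocess import prepare_channels

warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="session")
def seg_grid():
    return synthetic_seg_grid()


@pytest.fixture(scope="session")
def small_config():
    """16-day record with a 2-day test tail: desk-scale study conditions."""
    return SimulationConfig(n_patients=2, duration_days=16, test_days=2,
                            seed=1)


@pytest.fixture(scope="session")
def patient_record(small_config):
    return inject_gaps(simulate_patient(small_config, 0), small_config)


@pytest.fixture(scope="session")
def prepared(patient_record):
    """(train channels, test channels, test imputed flags) for patient 0."""
    train, test = split_train_test(patient_record, 2)
    train_ch, train_imp = prepare_channels(train, mode="train")
    test_ch, test_imp = prepare_channels(test, mode="test")
    return train_ch, train_imp, test_ch, test_imp


@pytest.fixture()
def grid_series():
    """Deterministic 5-min glucose series helper."""
    def make(values, start="2024-01-01"):
        idx = pd.date_range(start, periods=len(values), freq="5min")
        return pd.Series(np.asarray(values, dtype=float), index=idx,
                         name="glucose")
    return make
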