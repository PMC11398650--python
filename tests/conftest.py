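import numpy as np
import pandas as pd
import pytest

from apclust import SimConfig, generate_cohort


def make_raw(records):
    """Long-format raw trace table from (pid, t, signal, value) tuples."""
    return pd.DataFrame(records, columns=["patient_id", "t_seconds", "signal", "value_mmHg"])


@pytest.fixture(scope="session")
def small_cohort():
    """A 120-patient cohort with corruption, shared across tests."""
    return generate_cohort(SimConfig(n_patients=120, seed=42))


@pytest.fixture(scope="session")
def clean_small_cohort(small_cohort):
    from apclust.preprocess import clean_traces
    kept, log = clean_traces(small_cohort.traces)
    return kept, log


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
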