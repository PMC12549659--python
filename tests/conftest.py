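"""Shared fixtures: small simulated cohorts built once per session."""

import numpy as np
import pytest

from crispgait import features as ft
from crispgait import synthetic_gait as sg


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Six-subject binary cohort with zero sensor noise (event/feature oracle)."""
    config = sg.GaitSimConfig(n_per_class=3, seed=7, noise_sd=0.0)
    return sg.simulate_cohort(config, task="binary")


@pytest.fixture(scope="session")
def small_cohort():
    """Twelve-subject binary cohort with realistic noise."""
    config = sg.GaitSimConfig(n_per_class=6, seed=11)
    return sg.simulate_cohort(config, task="binary")


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    return ft.cohort_feature_matrix(
        small_cohort.recordings, small_cohort.demographics, task="binary")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
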