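"""Shared fixtures: synthetic sessions and a trained ensemble.

Everything is generated programmatically with fixed seeds; the expensive
objects (feature tables, fitted learners) are session-scoped so the whole
suite trains the ensemble once.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from sharketho.dataset import LabelledDataset, stratified_split
from sharketho.ensemble import default_specs, select_members, train_all
from sharketho.features import extract_features
from sharketho.io import TriaxialSeries
from sharketho.simulate import simulate_ethogram_session

TRAIN_SEED = 11
TEST_SEED = 99


@pytest.fixture(scope="session")
def ethogram_session():
    """A 1200-s labelled session used across feature/ensemble tests."""
    return simulate_ethogram_session(total_s=1200, seed=TRAIN_SEED)


@pytest.fixture(scope="session")
def session_features(ethogram_session):
    series, track = ethogram_session
    return extract_features(series), track


@pytest.fixture(scope="session")
def session_dataset(session_features):
    frame, track = session_features
    return LabelledDataset(features=frame, labels=track)


@pytest.fixture(scope="session")
def session_splits(session_dataset):
    return stratified_split(session_dataset, seed=3)


@pytest.fixture(scope="session")
def trained_members(session_splits):
    train, _, _ = session_splits
    return train_all(default_specs(seed=0), train)


@pytest.fixture(scope="session")
def trained_ensemble(trained_members, session_splits):
    _, validation, _ = session_splits
    return select_members(trained_members, validation)


@pytest.fixture
def short_series():
    """A deterministic 60-s, 30-Hz series with a 1-Hz sway oscillation."""
    rng = np.random.default_rng(7)
    t = np.arange(60 * 30) / 30.0
    return TriaxialSeries(
        start_time=pd.Timestamp("2012-07-29T08:00:00"),
        x=rng.normal(0, 0.02, t.size),
        y=-1.0 + rng.normal(0, 0.02, t.size),
        z=0.3 * np.sin(2 * np.pi * 1.0 * t) + rng.normal(0, 0.02, t.size),
        rate_hz=30.0,
    )
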