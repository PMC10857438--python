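"""Shared fixtures: a deterministic synthetic home and its processed data.

The heavy artifacts (a week of simulated events, the windowed splits, and
a briefly pre-trained encoder) are session-scoped so the protocol tests
share one copy.
"""

import numpy as np
import pytest

from homeclr import synth
from homeclr.casas import clean_events, propagate_activity_labels
from homeclr.features import (
    Standardizer,
    featurize,
    make_sliding_windows,
    split_dataset,
)
from homeclr.pipeline import TrainConfig, pretrain

SIM_DAYS = 7
SIM_SEED = 42
PRETRAIN_EPOCHS = 10  # reduced budget for desk-scale runs


@pytest.fixture(scope="session")
def home_config():
    return synth.default_home_config()


@pytest.fixture(scope="session")
def sensor_map(home_config):
    return synth.generate_home(home_config)


@pytest.fixture(scope="session")
def simulated(home_config, sensor_map):
    """(events, ground-truth labels) for a week of simulated life."""
    return synth.simulate_events(sensor_map, home_config, SIM_DAYS, seed=SIM_SEED)


@pytest.fixture(scope="session")
def labeled_events(simulated):
    events, _ = simulated
    return propagate_activity_labels(clean_events(events))


@pytest.fixture(scope="session")
def feature_vectors(labeled_events, sensor_map):
    return featurize(labeled_events, sensor_map)


@pytest.fixture(scope="session")
def splits(feature_vectors):
    """Standardized (train, test) windows; statistics fit on train only."""
    windows = make_sliding_windows(feature_vectors)
    train, _, test = split_dataset(windows, (0.7, 0.0, 0.3), seed=0)
    stats = Standardizer.fit(train)
    return stats.transform(train), stats.transform(test)


@pytest.fixture(scope="session")
def pretrained(splits):
    """Encoder pre-trained contrastively on the training windows (no labels)."""
    train, _ = splits
    model, losses = pretrain(
        train, TrainConfig.for_pretraining(epochs=PRETRAIN_EPOCHS, batch_size=128, seed=0)
    )
    return model, losses
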