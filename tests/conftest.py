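"""Shared fixtures.

The expensive fixtures (the scaled-down corpus and the trained networks) are
session-scoped and lazy: they are built once, the first time a test needs
them.  The scaled-down study conditions are 500 trajectories per class under
the default parameter ranges, the final architecture, and a batch size shrunk
with the corpus (64 instead of 512) so the number of optimizer steps per
epoch stays comparable to the full-scale setting.
"""

from __future__ import annotations

import numpy as np
import pytest

try:  # pin BLAS to one thread: bit-reproducible results across machines
    from threadpoolctl import threadpool_limits

    threadpool_limits(1)
except ImportError:  # pragma: no cover
    pass

from anomdiff.dataset import generate_dataset
from anomdiff.model import ArchitectureConfig, build_network
from anomdiff.simulate import SimulationConfig
from anomdiff.training import TrainConfig, train

# scaled-down study conditions shared by the training-dependent tests
SCALED_N_PER_CLASS = 500
SCALED_DATA_SEED = 101
SCALED_MODEL_SEED = 11
SCALED_EPOCHS = 10
SCALED_BATCH = 32


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def scaled_dataset():
    config = SimulationConfig(n_per_class=SCALED_N_PER_CLASS, seed=SCALED_DATA_SEED)
    return generate_dataset(config)


def _train_scaled(dataset, selective_mode=None, cost="MSE"):
    network = build_network(
        ArchitectureConfig(), np.random.default_rng(SCALED_MODEL_SEED)
    )
    config = TrainConfig(
        batch_size=SCALED_BATCH,
        max_epochs=SCALED_EPOCHS,
        selective_mode=selective_mode,
        cost=cost,
        seed=SCALED_MODEL_SEED,
    )
    history = train(network, dataset, config)
    return network, history


@pytest.fixture(scope="session")
def scaled_training(scaled_dataset):
    """Final-architecture model trained on the scaled-down corpus (no
    selective backprop, MSE cost)."""
    return _train_scaled(scaled_dataset)


@pytest.fixture(scope="session")
def selective_training(scaled_dataset):
    """Same conditions as ``scaled_training`` but back-propagating only the
    samples covering 98% of each batch's loss."""
    return _train_scaled(scaled_dataset, selective_mode=("loss_coverage", 0.98))


@pytest.fixture(scope="session")
def cross_entropy_training(scaled_dataset):
    """Same conditions as ``scaled_training`` but with the cross-entropy
    cost."""
    return _train_scaled(scaled_dataset, cost="cross-entropy")
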