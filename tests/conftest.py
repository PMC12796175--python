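import numpy as np
import pytest

from plantarqc.dataio import Dataset
from plantarqc.synth import (FootShapeParams, generate_dataset,
                             simulate_valid_foot, subject_effects)
from plantarqc.types import Condition, Side


@pytest.fixture(scope="session")
def foot_params():
    return FootShapeParams()


@pytest.fixture()
def valid_sample(foot_params):
    return simulate_valid_foot(foot_params, Side.LEFT, "S0001", seed=11)


@pytest.fixture()
def valid_pair(foot_params):
    """Left/right valid samples of the same subject."""
    rng = np.random.default_rng(5)
    eff = subject_effects(rng, foot_params)
    left = simulate_valid_foot(foot_params, Side.LEFT, "S0002", seed=21,
                               effects=eff)
    right = simulate_valid_foot(foot_params, Side.RIGHT, "S0002", seed=22,
                                effects=eff)
    return left, right


@pytest.fixture(scope="session")
def small_dataset():
    """Small augmented dataset (12 subjects, 10 per outlier category)."""
    return generate_dataset(n_subjects=12, valid_per_subject=4, target=10,
                            seed=7)


@pytest.fixture(scope="session")
def toy_problem():
    """Tiny linearly distinguishable 5-class problem on the real canvas.

    Class signatures are coarse spatial patterns; 10 samples per class;
    grids are pre-standardized.
    """
    rng = np.random.default_rng(0)
    grids, sides, labels = [], [], []
    for c in range(5):
        for i in range(10):
            g = np.zeros((64, 64))
            g[12 * c:12 * c + 12, 20:44] = 1.0
            g += rng.normal(0, 0.05, g.shape)
            grids.append(g)
            sides.append(i % 2)
            labels.append(c)
    grids = np.array(grids)
    grids = (grids - grids.mean()) / grids.std()
    return grids, np.array(sides), np.array(labels)


@pytest.fixture(scope="session")
def toy_model(toy_problem):
    """CNN trained to perfection on the toy problem (shared across
    tests that need a non-degenerate trained network)."""
    from plantarqc.cnn import PlantarCNN, TrainConfig, train
    grids, sides, labels = toy_problem
    model = PlantarCNN(seed=1)
    history = train(model, (grids, sides, labels), (grids, sides, labels),
                    TrainConfig(seed=1, max_epochs=30, batch_size=16,
                                patience=30, samples_per_epoch=None))
    return model, history


@pytest.fixture(scope="session")
def cohort_stack(foot_params):
    """Stack of 60 valid left-foot maps from distinct subjects."""
    rng = np.random.default_rng(17)
    grids = []
    for i in range(60):
        eff = subject_effects(rng, foot_params)
        grids.append(simulate_valid_foot(
            foot_params, Side.LEFT, f"C{i:03d}",
            seed=int(rng.integers(2**31)), effects=eff).grid)
    return np.stack(grids)
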