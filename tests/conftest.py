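"""Shared fixtures.

The desk-scale study conditions (16 classes, 64x64, 128 train / 32 test per
class, 10-epoch training, 2 seeds) are generated once per session; the
trained-model ensemble fixture is likewise session-scoped so the scaled-down
replication tests share checkpoints instead of retraining.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from blurlab.desk import (DESK_CLASSES, DESK_EPOCHS, DESK_SEEDS,
                          DESK_IMAGE_SIZE as DESK_SIZE,
                          DESK_TEST_PER_CLASS as DESK_TEST,
                          DESK_TRAIN_PER_CLASS as DESK_TRAIN,
                          desk_train_config as desk_config)
from blurlab.policies import BlurPolicy, TrainConfig
from blurlab.synthetic import generate_cue_conflict_set, generate_dataset
from blurlab.training import BlurTraining, ModelSpec, TrainingResults

DESK_MASTER_SEED = 0


def make_untrained(spec: ModelSpec, seed: int = 0,
                   config: TrainConfig | None = None) -> TrainingResults:
    """A TrainingResults wrapper around a randomly initialized network."""
    cfg = config or desk_config()
    net = spec.build(np.random.default_rng(seed))
    empty = pd.DataFrame([{"epoch": -1, "loss": float("nan"), "acc": float("nan"),
                           "lr": cfg.lr0, "mean_sigma": 0.0, "blur_fraction": 0.0}])
    audit = pd.DataFrame([{"epoch": -1, "n_total": 0, "n_blurred": 0}])
    return TrainingResults(spec=spec, policy=BlurPolicy("S"), config=cfg,
                           seed=seed, net=net, history=empty, blur_audit=audit)


@pytest.fixture(scope="session")
def tiny_dataset():
    """4 classes, 32x32, 12 train / 6 test per class — for fast unit tests."""
    return generate_dataset(n_classes=4, n_train=12, n_test=6, image_size=32,
                            master_seed=1)


@pytest.fixture(scope="session")
def desk_dataset():
    return generate_dataset(n_classes=DESK_CLASSES, n_train=DESK_TRAIN,
                            n_test=DESK_TEST, image_size=DESK_SIZE,
                            master_seed=DESK_MASTER_SEED)


@pytest.fixture(scope="session")
def desk_cue_conflict(desk_dataset):
    return generate_cue_conflict_set(desk_dataset.classes, n_per_pair=1,
                                     image_size=DESK_SIZE,
                                     master_seed=DESK_MASTER_SEED)


@pytest.fixture(scope="session")
def trained_models(desk_dataset):
    """S / B / B+S networks, two seeds each, at desk scale (shared checkpoints)."""
    out: dict[str, list[TrainingResults]] = {}
    for kind in ("S", "B", "B+S"):
        model = BlurTraining.from_dataset(desk_dataset, BlurPolicy(kind, sigma=4.0),
                                          config=desk_config())
        out[kind] = [model.fit(seed=s) for s in DESK_SEEDS]
    return out


@pytest.fixture(scope="session")
def untrained_desk_model():
    return make_untrained(ModelSpec(n_classes=DESK_CLASSES, image_size=DESK_SIZE))


@pytest.fixture(scope="session")
def untrained_tiny_model():
    return make_untrained(ModelSpec(n_classes=4, image_size=32))
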