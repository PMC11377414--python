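"""Shared fixtures: tiny model configs and one session-scoped phantom
training run reused by every test that needs a trained network."""

from __future__ import annotations

import numpy as np
import pytest

from conunet.model import ModelConfig
from conunet.phantom import (PhantomSpec, extract_slices, generate_phantom,
                             make_ab_split)
from conunet.trainer import Trainer, TrainerConfig


@pytest.fixture(scope="session")
def tiny_config() -> ModelConfig:
    return ModelConfig(base_width=8, depth=5)


@pytest.fixture(scope="session")
def phantom_studies():
    """16 small phantom studies (64x64, 24 slices) with distractors enabled."""
    rng = np.random.default_rng(42)
    spec = PhantomSpec(image_size=(64, 64), n_slices=24)
    return [generate_phantom(spec, rng, study_id=f"s{i:02d}") for i in range(16)]


@pytest.fixture(scope="session")
def phantom_split(phantom_studies):
    return make_ab_split(phantom_studies, fractions=(0.75, 0.125, 0.125),
                         rng=np.random.default_rng(1))


@pytest.fixture(scope="session")
def training_run(phantom_split):
    """Train the base-width-8 model for 20 epochs on 200 phantom slices.

    Returns (checkpoint, trainer, test_studies); shared across the suite so
    the expensive fit happens once.
    """
    split = phantom_split
    data_a = extract_slices(split.data_a, max_slices=100,
                            rng=np.random.default_rng(2))
    data_b = extract_slices(split.data_b, max_slices=100,
                            rng=np.random.default_rng(3))
    val_b = extract_slices(split.val, rng=np.random.default_rng(4))
    cfg = TrainerConfig(model=ModelConfig(base_width=8), epochs=20, seed=0)
    trainer = Trainer(cfg)
    checkpoint = trainer.fit(data_a, data_b, val_b)
    return checkpoint, trainer, split.test
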