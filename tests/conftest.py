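"""Shared fixtures: a small building-block library, a desk-scale corpus, and
one trained prior reused by the sampling, RL and acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from pepfill.building_blocks import BuildingBlockLibrary, default_library
from pepfill.datagen import GenConfig, build_dataset, build_eval_sets, make_pairs
from pepfill.model import ModelConfig
from pepfill.training import TrainConfig, train


@pytest.fixture(scope="session")
def library() -> BuildingBlockLibrary:
    return default_library(n_nnaa=35, seed=0)


@pytest.fixture(scope="session")
def gen_config() -> GenConfig:
    return GenConfig(n_peptides=400, seed=1)


@pytest.fixture(scope="session")
def dataset_small(gen_config, library):
    return build_dataset(gen_config, library)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


# -- the shared trained prior ------------------------------------------------
# One corpus + one supervised training run back the sampling-quality and RL
# tests; session scope keeps the suite within a desktop time budget.

PRIOR_N_PEPTIDES = 1500
PRIOR_PAIRS_PER_PEPTIDE = 3
PRIOR_EPOCHS = 14


@pytest.fixture(scope="session")
def prior_setup(library):
    config = GenConfig(n_peptides=PRIOR_N_PEPTIDES, seed=7)
    dataset = build_dataset(config, library)
    rng = np.random.default_rng(42)
    train_pairs = make_pairs(
        dataset.split("train"), library, config, rng,
        pairs_per_peptide=PRIOR_PAIRS_PER_PEPTIDE,
    )
    val_pairs = make_pairs(dataset.split("validation"), library, config, rng)
    model, log = train(
        train_pairs,
        TrainConfig(
            epochs=PRIOR_EPOCHS,
            batch_size=32,
            learning_rate=2e-3,
            seed=0,
            model=ModelConfig(),
        ),
        val_pairs,
    )
    model_eval, topology_eval = build_eval_sets(
        dataset, library, config, np.random.default_rng(43)
    )
    return {
        "model": model,
        "log": log,
        "dataset": dataset,
        "config": config,
        "model_eval": model_eval,
        "topology_eval": topology_eval,
    }


@pytest.fixture(scope="session")
def prior(prior_setup):
    return prior_setup["model"]
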