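"""Shared fixtures.

The trained toy model is session-scoped: it is the study condition used by
the heavier generative checks (2000 synthetic pairs, T=200, 20 epochs,
batch 24) and takes a few minutes on one CPU, so it is built once.
"""

from __future__ import annotations

import numpy as np
import pytest

from phoregen.fixtures import COMPLEMENT, FixtureSpec, make_toy_pocket, make_training_pairs
from phoregen.training import TrainConfig, train

TOY_SEED = 11
TRAIN_SEED = 42

TOY_SPEC = FixtureSpec(n_train=2000, seed=TOY_SEED)
TOY_TRAIN = TrainConfig(T=200, epochs=20, lr=1e-3)


@pytest.fixture(scope="session")
def toy_pocket():
    pocket, planted = make_toy_pocket(FixtureSpec(seed=TOY_SEED))
    return pocket, planted


@pytest.fixture(scope="session")
def trained_toy():
    """Denoiser trained on the toy study condition (shared across tests)."""
    pairs = make_training_pairs(TOY_SPEC)
    params, history = train(pairs, TOY_TRAIN, np.random.default_rng(TRAIN_SEED))
    return params, history


@pytest.fixture(scope="session")
def planted_sites(toy_pocket):
    _, planted = toy_pocket
    sites = np.array([p for _, p in planted])
    ligand_types = [COMPLEMENT[t] for t, _ in planted]
    return sites, ligand_types
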