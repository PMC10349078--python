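"""Shared fixtures: tiny models, synthetic worlds, and trained runs.

Training tiny models on the separable planted world is the expensive part
of the suite, so the ten seeded runs are trained once per session and
shared by the trainer, interpretation, screening and acceptance tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from seq2drug.interaction_model import ModelConfig, build_model
from seq2drug.protein_seq import ReferenceEmbeddingProvider
from seq2drug.synthetic_data import World, WorldSpec, generate_world, random_splits
from seq2drug.trainer import PairFeaturizer, TrainConfig, TrainHistory, train

N_TRAIN_SEEDS = 10

TINY_TRAIN_CONFIG = dict(learning_rate=2e-3, weight_decay=1e-4, micro_batch=32,
                         effective_batch=32, max_epochs=25, patience=25)


@dataclass
class TrainedRun:
    seed: int
    world: World
    splits: object
    model: object
    provider: ReferenceEmbeddingProvider
    featurizer: PairFeaturizer
    history: TrainHistory

    def motif_protein(self) -> str:
        return next(s for _, s in self.world.proteins if self.world.protein_has_motif[s])

    def key_compound(self) -> str:
        return next(s for s in self.world.compound_has_key if self.world.compound_has_key[s])

    def decoy_compound(self) -> str:
        return next(s for s in self.world.compound_has_key
                    if not self.world.compound_has_key[s])


def train_tiny(seed: int) -> TrainedRun:
    world = generate_world(WorldSpec.separable(seed=seed))
    splits = random_splits(world.samples, seed=seed)
    model = build_model(ModelConfig.tiny(), seed=seed)
    provider = ReferenceEmbeddingProvider(width=32, seed=seed)
    config = TrainConfig(seed=seed, **TINY_TRAIN_CONFIG)
    model, history = train(model, splits, config, provider)
    return TrainedRun(seed=seed, world=world, splits=splits, model=model,
                      provider=provider, featurizer=PairFeaturizer(provider),
                      history=history)


@pytest.fixture(scope="session")
def trained_runs() -> list[TrainedRun]:
    return [train_tiny(seed) for seed in range(N_TRAIN_SEEDS)]


@pytest.fixture(scope="session")
def tiny_model():
    return build_model(ModelConfig.tiny(), seed=7)


@pytest.fixture(scope="session")
def tiny_provider():
    return ReferenceEmbeddingProvider(width=32, seed=7)


def random_linear_smiles(rng: np.random.Generator) -> str:
    """Random parseable SMILES: hetero chain, optionally capped by a ring."""
    atoms = rng.choice(["C", "N", "O", "S", "C", "C"], size=rng.integers(1, 12))
    smiles = "".join(atoms)
    if rng.random() < 0.3:
        smiles += "c1ccccc1"
    return smiles
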