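"""Supervised training with gradient accumulation and seeded selection.

The loss is binary cross-entropy on the interaction probability, computed
from the logit for numerical stability and mean-reduced over the
effective batch, so the learning rate is independent of batch size and
accumulating micro-batch gradients reproduces the single-batch update
exactly. The optimizer is rectified Adam with L2 weight decay. The epoch
with the highest validation ROC-AUC is selected; training stops early
when no improvement is seen for ``patience`` epochs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .chem_graph import molecule_graph, parse_molecule
from .dataset_builder import CPISample, DatasetSplits
from .interaction_model import CPIModel, PairBatch, make_batch, score_batch
from .metrics import RankedPredictions, pr_auc, roc_auc
from .protein_seq import EmbeddingProvider, embed_protein, tokenize

logger = logging.getLogger(__name__)


class TrainingError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    learning_rate: float = 1e-5
    weight_decay: float = 1e-3
    micro_batch: int = 1
    effective_batch: int = 64
    max_epochs: int = 10
    patience: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.effective_batch % self.micro_batch:
            raise ValueError("effective_batch must be divisible by micro_batch")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class TrainHistory:
    epochs: list[dict] = field(default_factory=list)
    selected_epoch: int = -1


class PairFeaturizer:
    """Caches molecule graphs and protein embeddings by sample key."""

    def __init__(self, provider: EmbeddingProvider):
        self.provider = provider
        self._graphs: dict[str, object] = {}
        self._embeddings: dict[str, object] = {}

    def graph(self, smiles: str):
        if smiles not in self._graphs:
            self._graphs[smiles] = molecule_graph(parse_molecule(smiles))
        return self._graphs[smiles]

    def embedding(self, sequence: str):
        if sequence not in self._embeddings:
            self._embeddings[sequence] = embed_protein(tokenize(sequence), self.provider)
        return self._embeddings[sequence]

    def batch(self, samples: list[CPISample]) -> tuple[PairBatch, np.ndarray]:
        pairs = [(self.graph(s.compound_key), self.embedding(s.protein_key)) for s in samples]
        labels = np.array([s.label for s in samples], dtype=np.float64)
        return make_batch(pairs), labels


def bce_with_logits_sum(logits: nn.Tensor, labels: np.ndarray) -> nn.Tensor:
    """Sum over samples of softplus(logit) - y * logit (= -log-likelihood)."""
    y = nn.Tensor(labels)
    return (nn.softplus(logits) - y * logits).sum()


def train(model: CPIModel, splits: DatasetSplits, config: TrainConfig,
          provider: EmbeddingProvider) -> tuple[CPIModel, TrainHistory]:
    """Train in place; returns the model restored to its best-AUC epoch."""
    if not splits.train or not splits.validation:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    featurizer = PairFeaturizer(provider)
    optimizer = nn.RAdam(model.parameters(), lr=config.learning_rate,
                         weight_decay=config.weight_decay)
    history = TrainHistory()
    best_auc, best_state, since_best = -np.inf, None, 0
    train_samples = list(splits.train)

    for epoch in range(config.max_epochs):
        t0 = time.monotonic()
        model.train()
        order = rng.permutation(len(train_samples))
        total_loss = 0.0
        for start in range(0, len(order), config.effective_batch):
            chunk = [train_samples[i] for i in order[start:start + config.effective_batch]]
            optimizer.zero_grad()
            chunk_loss = 0.0
            for ms in range(0, len(chunk), config.micro_batch):
                micro = chunk[ms:ms + config.micro_batch]
                batch, labels = featurizer.batch(micro)
                loss = bce_with_logits_sum(model.forward(batch), labels) / float(len(chunk))
                if not np.isfinite(loss.data):
                    raise TrainingError(
                        f"non-finite loss at epoch {epoch}, step {start // config.effective_batch}"
                    )
                loss.backward()
                chunk_loss += float(loss.data)
            optimizer.step()
            total_loss += chunk_loss * len(chunk)
        model.eval()
        val_scores = _score_samples(model, featurizer, splits.validation)
        val_labels = np.array([s.label for s in splits.validation])
        preds = RankedPredictions(val_labels, val_scores)
        auc, prc = roc_auc(preds), pr_auc(preds)
        history.epochs.append({
            "epoch": epoch,
            "train_loss": total_loss / len(train_samples),
            "val_auc": auc,
            "val_prc": prc,
            "wall_time_s": time.monotonic() - t0,
        })
        logger.info("epoch %d loss %.4f val_auc %.4f val_prc %.4f",
                    epoch, history.epochs[-1]["train_loss"], auc, prc)
        if auc > best_auc:
            best_auc, since_best = auc, 0
            best_state = {k: v.copy() for k, v in model.state_dict().items()}
            history.selected_epoch = epoch
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return model, history


def _score_samples(model: CPIModel, featurizer: PairFeaturizer,
                   samples: list[CPISample], chunk: int = 64) -> np.ndarray:
    scores = []
    for start in range(0, len(samples), chunk):
        part = samples[start:start + chunk]
        pairs = [(featurizer.graph(s.compound_key), featurizer.embedding(s.protein_key))
                 for s in part]
        scores.extend(s.probability for s in score_batch(model, pairs))
    return np.array(scores)
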