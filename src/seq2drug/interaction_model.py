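"""Encoder-decoder interaction network.

Per-residue protein embeddings pass through a self-attention encoder
(positional encoding off by default: the embedding provider already
carries sequence context). Atom vectors, after one graph-convolution
layer over the virtual-atom molecule graph, act as decoder queries that
cross-attend to the encoded protein; the decoder has no causal mask. The
final representation of the virtual atom feeds a small fully connected
readout ending in a logistic map, yielding the interaction probability.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .chem_graph import (
    Molecule,
    MoleculeGraph,
    N_ATOM_FEATURES,
    molecule_graph,
)
from .protein_seq import ProteinEmbedding

CHECKPOINT_SCHEMA = "seq2drug-ckpt/1"


class ConfigurationError(ValueError):
    """Raised for invalid or mismatched model configuration."""


class NumericError(ArithmeticError):
    """Raised when a forward pass produces non-finite activations."""


@dataclass
class ModelConfig:
    d_model: int = 768
    n_encoder_layers: int = 3
    n_decoder_layers: int = 3
    n_heads: int = 8
    d_feedforward: int = 3072
    readout_hidden: list[int] = field(default_factory=list)  # [] -> [d_model // 2]
    dropout: float = 0.1
    use_positional_encoding: bool = False
    embedding_width: int = 768
    n_gcn_layers: int = 1
    feature_schema: str = "ecf-34/1"

    def __post_init__(self):
        if self.d_model % self.n_heads:
            raise ConfigurationError(
                f"d_model {self.d_model} not divisible by n_heads {self.n_heads}"
            )
        if self.embedding_width != self.d_model:
            raise ConfigurationError(
                "embedding_width must equal d_model (the encoder consumes provider "
                f"embeddings without projection); got {self.embedding_width} vs {self.d_model}"
            )
        if not self.readout_hidden:
            self.readout_hidden = [max(1, self.d_model // 2)]

    @classmethod
    def tiny(cls, d_model: int = 32) -> "ModelConfig":
        """A desk-scale configuration for tests and worked examples."""
        return cls(d_model=d_model, n_encoder_layers=1, n_decoder_layers=1,
                   n_heads=4, d_feedforward=2 * d_model, dropout=0.1,
                   embedding_width=d_model)


@dataclass
class InteractionScore:
    probability: float
    logit: float


@dataclass
class PairBatch:
    """Padded arrays for a batch of (molecule graph, protein embedding) pairs."""

    atom_features: np.ndarray   # (B, La, 34)
    norm_adjacency: np.ndarray  # (B, La, La)
    atom_mask: np.ndarray       # (B, La) bool
    virtual_index: np.ndarray   # (B,)
    protein: np.ndarray         # (B, Lp, W)
    protein_mask: np.ndarray    # (B, Lp) bool


def _sinusoidal(length: int, d: int) -> np.ndarray:
    pos = np.arange(length)[:, None]
    i = np.arange(d)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d)
    pe = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return pe


class CPIModel(nn.Module):
    def __init__(self, config: ModelConfig, seed: int):
        self.config = config
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        d = config.d_model
        self.gcn = [
            nn.GraphConvLayer(N_ATOM_FEATURES if i == 0 else d, d, rng)
            for i in range(config.n_gcn_layers)
        ]
        self.encoder = [
            nn.EncoderLayer(d, config.n_heads, config.d_feedforward, config.dropout, rng)
            for _ in range(config.n_encoder_layers)
        ]
        self.decoder = [
            nn.DecoderLayer(d, config.n_heads, config.d_feedforward, config.dropout, rng)
            for _ in range(config.n_decoder_layers)
        ]
        widths = [d] + list(config.readout_hidden) + [1]
        self.readout = [nn.Linear(a, b, rng) for a, b in zip(widths, widths[1:])]
        self.eval()

    def forward(self, batch: PairBatch) -> nn.Tensor:
        """Return the (B,) logit tensor for a padded pair batch."""
        if batch.protein.shape[2] != self.config.embedding_width:
            raise ConfigurationError(
                f"protein embedding width {batch.protein.shape[2]} does not match "
                f"configured width {self.config.embedding_width}"
            )
        prot = batch.protein
        if self.config.use_positional_encoding:
            prot = prot + _sinusoidal(prot.shape[1], prot.shape[2])[None]
        x = nn.Tensor(prot)
        for layer in self.encoder:
            x = layer(x, batch.protein_mask)
        h = nn.Tensor(batch.atom_features)
        for g in self.gcn:
            h = g(h, batch.norm_adjacency)
        for layer in self.decoder:
            h = layer(h, x, batch.atom_mask, batch.protein_mask)
        B = batch.atom_features.shape[0]
        virt = h[np.arange(B), batch.virtual_index]
        z = virt
        for i, lin in enumerate(self.readout):
            z = lin(z)
            if i < len(self.readout) - 1:
                z = nn.relu(z)
        logit = z.reshape(B)
        if not np.all(np.isfinite(logit.data)):
            raise NumericError("non-finite activations in the readout layer")
        return logit


def build_model(config: ModelConfig, seed: int) -> CPIModel:
    """Instantiate a model with deterministic, seeded initialization."""
    return CPIModel(config, seed)


def make_batch(pairs: list[tuple[MoleculeGraph, ProteinEmbedding]]) -> PairBatch:
    """Pad a list of (graph, embedding) pairs into one batch."""
    if not pairs:
        raise ValueError("pair list must be non-empty")
    La = max(g.features.shape[0] for g, _ in pairs)
    Lp = max(p.matrix.shape[0] for _, p in pairs)
    W = pairs[0][1].matrix.shape[1]
    B = len(pairs)
    feats = np.zeros((B, La, N_ATOM_FEATURES))
    adj = np.zeros((B, La, La))
    amask = np.zeros((B, La), dtype=bool)
    prot = np.zeros((B, Lp, W))
    pmask = np.zeros((B, Lp), dtype=bool)
    vidx = np.zeros(B, dtype=np.int64)
    for b, (g, p) in enumerate(pairs):
        na = g.features.shape[0]
        np_ = p.matrix.shape[0]
        if p.matrix.shape[1] != W:
            raise ConfigurationError("inconsistent protein embedding widths in batch")
        feats[b, :na] = g.features
        adj[b, :na, :na] = g.adjacency
        amask[b, :na] = True
        prot[b, :np_] = p.matrix
        pmask[b, :np_] = True
        vidx[b] = g.virtual_index
    return PairBatch(atom_features=feats, norm_adjacency=nn.normalize_adjacency(adj),
                     atom_mask=amask, virtual_index=vidx, protein=prot,
                     protein_mask=pmask)


def predict_interaction(model: CPIModel,
                        graph: MoleculeGraph | Molecule,
                        protein: ProteinEmbedding) -> InteractionScore:
    """Score one (compound, protein) pair in evaluation mode."""
    return score_batch(model, [(graph, protein)])[0]


def score_batch(model: CPIModel,
                pairs: list[tuple[MoleculeGraph | Molecule, ProteinEmbedding]]
                ) -> list[InteractionScore]:
    """Score pairs jointly with padding; equals per-pair scoring to 1e-5."""
    if not pairs:
        raise ValueError("pair list must be non-empty")
    prepared = [
        (molecule_graph(g) if isinstance(g, Molecule) else g, p) for g, p in pairs
    ]
    was_training = model.training
    model.eval()
    try:
        logits = model.forward(make_batch(prepared)).data
    finally:
        if was_training:
            model.train()
    probs = 1.0 / (1.0 + np.exp(-logits))
    return [InteractionScore(probability=float(p), logit=float(l))
            for p, l in zip(probs, logits)]


# ---------------------------------------------------------------- checkpoint

def save_checkpoint(model: CPIModel, path) -> None:
    meta = json.dumps({
        "schema": CHECKPOINT_SCHEMA,
        "config": asdict(model.config),
        "seed": model.seed,
    })
    np.savez(path, __meta__=np.array(meta), **model.state_dict())


def load_checkpoint(path) -> CPIModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        if meta.get("schema") != CHECKPOINT_SCHEMA:
            raise ConfigurationError(f"unknown checkpoint schema: {meta.get('schema')}")
        config = ModelConfig(**meta["config"])
        model = CPIModel(config, meta["seed"])
        model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
    return model
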