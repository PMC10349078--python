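# seq2drug

Sequence-based compound–protein interaction (CPI) prediction, virtual
screening and model interpretation — no protein structure required.

`seq2drug` is for computational chemists and method developers who want a
fully tested, desk-scale implementation of the *sequence-to-drug* idea:
predict whether a small molecule binds a protein directly from the SMILES
string and the one-letter residue sequence, then use that predictor for
library screening, proteome-wide target ranking, and two interpretation
analyses (saturation mutation scanning and methyl→trifluoromethyl
substitution-effect analysis).

## The model

A pair (compound, protein) is scored by an encoder–decoder attention
network:

- **Protein side.** The sequence is tokenized with a fixed 26-id scheme
  (0 = `<pad>`, 1–23 = the 23 common amino acids, 24 = `<cls>`,
  25 = `<sep>`) and embedded per residue by a pluggable provider
  (reference width 768). A transformer encoder (3 layers, 8 heads,
  d_model = 768, feed-forward 3072) self-attends over the embedding;
  positional encodings are omitted because the provider already encodes
  sequence context.
- **Compound side.** Each heavy atom is a 34-dimensional binary feature
  vector (element, degree, attached H, formal charge, aromaticity, ring
  membership, hybridization). A *virtual atom* — initialized to the mean
  atom feature vector and bonded to every atom — is appended, and a single
  graph-convolution layer H′ = ReLU(D⁻¹ᐟ²ÂD⁻¹ᐟ² H W) over the self-looped
  adjacency Â produces atom embeddings.
- **Interaction.** Atom embeddings act as decoder queries that
  cross-attend (no causal mask) to the encoded protein. The final
  representation of the virtual atom passes through fully connected layers
  and a logistic map to the interaction probability
  p(interact) = σ(w·h_virtual).

Training uses binary cross-entropy, the rectified Adam optimizer, and
gradient accumulation so small micro-batches reproduce large-batch
updates exactly.

Datasets follow ChEMBL-style curation: binding assays (type ‘B’,
confidence 9) on single proteins with IC50/EC50/Ki in nM become
pActivity = 9 − log₁₀(value/nM), labelled positive at pActivity ≥ 6.5;
conflicting pairs are removed, every retained compound occurs in both
classes, and the **label-reversal split** hides chosen ligands with one
label in training and the opposite label in the test set, which defeats
ligand-memorization shortcuts.

Everything is verifiable at a desk: the `synthetic_data` module generates
worlds where activity is a known function of a planted protein motif and
a planted compound substructure, with exact oracles for every analysis.

## Worked example

Train a tiny model on a separable synthetic world, evaluate it, and ask
it where the planted motif is:

```python
import numpy as np
from seq2drug import (WorldSpec, generate_world, random_splits, ModelConfig,
                      build_model, ReferenceEmbeddingProvider, TrainConfig, train,
                      mutation_scan, RankedPredictions, roc_auc)
from seq2drug.trainer import PairFeaturizer, _score_samples

world = generate_world(WorldSpec.separable(seed=0))
splits = random_splits(world.samples, seed=0)
model = build_model(ModelConfig.tiny(), seed=0)
provider = ReferenceEmbeddingProvider(width=32, seed=0)
config = TrainConfig(learning_rate=2e-3, weight_decay=1e-4, micro_batch=32,
                     effective_batch=32, max_epochs=25, patience=25, seed=0)
model, history = train(model, splits, config, provider)

scores = _score_samples(model, PairFeaturizer(provider), splits.test)
labels = np.array([s.label for s in splits.test])
print(f"held-out ROC-AUC: {roc_auc(RankedPredictions(labels, scores)):.3f}")

seq = next(s for _, s in world.proteins if world.protein_has_motif[s])
compound = next(s for s, f in world.compound_has_key.items() if f)
scan = mutation_scan(model, provider, seq, compound)
start = seq.find(world.spec.motif) + 1
print(f"motif planted at positions {start}-{start + 4}")
print(f"important sites (dR > 0.38): {scan.important_sites}")
print(f"peak dR position: {int(scan.delta_R.argmax()) + 1}")
```

Output (about a minute on one CPU):

```
held-out ROC-AUC: 1.000
motif planted at positions 7-11
important sites (dR > 0.38): [8, 9, 10]
peak dR position: 9
```

The model separates held-out interactions perfectly, and the mutation
scan — which mutates every position to all 20 amino acids and measures
the mean absolute score change ΔS̄ᵢ, max-normalized to ΔRᵢ — places its
important sites inside the planted five-residue motif.

The same workflow is scriptable from the shell:

```bash
seq2drug synth --preset separable --out world --seed 1
seq2drug build-dataset --activities world/activity.tsv --out samples.tsv
seq2drug split --samples samples.tsv --out splits --n-neg-ligands 2 --n-pos-ligands 2
cat > cfg.yaml <<'YAML'
model: {d_model: 32, n_encoder_layers: 1, n_decoder_layers: 1, n_heads: 4,
        d_feedforward: 64, embedding_width: 32}
train: {learning_rate: 2e-3, weight_decay: 1e-4, micro_batch: 32,
        effective_batch: 32, max_epochs: 5, patience: 5, seed: 1}
YAML
seq2drug train --config cfg.yaml --splits splits --out model.npz
seq2drug mutation-scan --model model.npz --fasta world/proteins.fasta \
    --smiles "CCOc1ccncc1" --out scan
seq2drug rank-targets --model model.npz --smiles "CCOc1ccncc1" \
    --panel world/proteins.fasta --out ranks.tsv
```

(Training without `--config` uses the full-scale reference
hyperparameters — learning rate 1e-5, micro-batch 1 accumulated to 64 —
which are meant for large datasets.)

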