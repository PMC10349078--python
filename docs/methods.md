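# Methods

This note documents the models, parameter choices, numerical details and
limitations of `seq2drug`, in the order data flows through the package.

## Compound representation

Compounds are parsed from SMILES with RDKit, sanitized, and reduced to
the largest covalent fragment (heavy-atom count, canonical-SMILES tie
break); the canonical largest-fragment SMILES is the compound identity
used for deduplication and split bookkeeping. Each heavy atom is encoded
as a 34-dimensional binary vector:

| block | width |
|---|---|
| element one-hot over {C, N, O, S, F, Cl, Br, I, P, B, Si, Se, other} | 13 |
| heavy-atom degree one-hot 0–5 | 6 |
| attached hydrogens one-hot 0–4 | 5 |
| formal charge one-hot −2…+2 | 5 |
| aromatic flag | 1 |
| ring-membership flag | 1 |
| hybridization one-hot {sp, sp2, sp3} | 3 |

The schema is versioned (`ecf-34/1`) in the model configuration so an
alternative 34-wide schema can be substituted without changing contracts.
Atoms whose properties fall outside these ranges (degree > 5, |charge| >
2, > 4 hydrogens) raise a featurization error naming the atom; exotic
hybridizations simply leave the hybridization block all-zero. Bond
features, stereochemistry and 3D conformers are out of scope.

A **virtual atom** is appended to every molecule: its feature row is the
column-wise mean of the real atom rows and it is linked (undirected) to
every atom; every node, including the virtual one, carries a self-loop.
Graph convolution uses the symmetrically normalized propagation
D^(−1/2) Â D^(−1/2) with a linear map and ReLU. One layer is the default
and the recommended depth; requesting more than two layers emits an
over-smoothing warning because deep unweighted propagation drives atom
features toward each other and erases the contrasts the decoder needs.

## Protein representation

The tokenizer uses the fixed id scheme 0 = `<pad>`, 1–23 = the 23 common
amino acids, 24 = `<cls>`, 25 = `<sep>`. The 23 residues are the 20
canonical amino acids plus the ambiguity codes B, Z and X, in
alphabetical order; U, O and J map to X. Start/separator tokens are kept
in the embedded sequence by default (config-selectable), and all
mutation-scan coordinates are 1-based residue positions independent of
that choice, via the recorded residue offset.

Per-residue embeddings come from a provider object with a fixed call
contract (`ids -> L' x width matrix`). The reference provider is a small
deterministic lookup-plus-mixing network: a seeded embedding table over
the 26 ids followed by one tanh layer whose input combines each
position's vector with the mean of its two neighbours. The mixing step
matters: it gives every position a local-context signature, so motifs
(not just residue composition) are linearly detectable downstream — the
same property a pretrained protein language model provides at full
scale. An adapter for genuinely pretrained weights can implement the same
protocol; no pretrained weights are bundled or required.

`sequence_identity` is a utility (global alignment, match 1, mismatch 0,
gap −1 per gap symbol; identity = matches / alignment length) for novelty
checks; it is not part of the model.

## Interaction network

Reference configuration: d_model 768, 3 encoder and 3 decoder layers, 8
heads, feed-forward width 3072, dropout 0.1, no positional encoding.
Tests and worked examples use the `tiny` configuration (d_model 32, 1+1
layers, 4 heads, feed-forward 64) which preserves every contract at desk
scale.

Layers are post-norm transformer blocks. Padding is handled by additive
key masks of −1e30, so padded keys receive exactly zero attention weight
and batched scores equal single-pair scores to floating-point accuracy.
The decoder has no causal mask. Design choices that were genuinely open:

- **Decoder orientation.** The readout requires a decoder-side virtual
  atom, so atom embeddings are the decoder queries and the encoded
  protein is the memory; this is the only orientation in which "the last
  layer representation of the virtual atom" exists.
- **Readout.** Two affine layers (d_model → d_model/2 → 1) with ReLU
  between, then a logistic map. Sized conservatively; configurable.
- **No positional encoding on atoms either**: atom order in a SMILES
  string is chemically meaningless, and omitting it makes the predicted
  probability invariant under atom reordering (tested to 1e-5).

The whole network, including the graph convolution and the RAdam
optimizer, runs on a compact numpy reverse-mode autograd core
(`seq2drug.nn`, float64 throughout). Every operation's gradient is
checked against central finite differences in the test suite.

## Training

Loss is binary cross-entropy computed from the logit
(softplus(z) − y·z), mean-reduced over the *effective* batch. Gradient
accumulation sums micro-batch gradients divided by the effective batch
size, which reproduces the single-batch update exactly (tested to 1e-6).
Optimizer is rectified Adam with L2 weight decay. Reference full-scale
hyperparameters are lr 1e-5, weight decay 1e-3, micro-batch 1 accumulated
to 64. The desk-scale worlds train with lr 2e-3, weight decay 1e-4, batch
32, ≤ 25 epochs — small transformers on hundreds of samples need a much
larger step size than the full-scale run, and these sizes keep a full
10-seed training study around one minute on one CPU. Model selection
keeps the epoch with the highest validation ROC-AUC (the paper-trail
metric), with early stopping after `patience` epochs without improvement.
All randomness (init, shuffling, dropout) flows from explicit seeds;
identical config and seed give bitwise-identical histories.

## Dataset curation and label-reversal split

Filters: target type SINGLE PROTEIN, molecule type Small molecule,
confidence score 9, assay type ‘B’, activity type ∈ {IC50, EC50, Ki},
units nM with positive value. pActivity = 9 − log₁₀(value/nM); label
positive iff pActivity ≥ 6.5 — the boundary is inclusive, consistent with
"potency below 1 μM is active" phrasing at the p-scale. Records are
labelled individually and then deduplicated; a (compound, protein) pair
observed with both labels is removed entirely (no median aggregation —
the closest literal reading of the removal rule). Samples with > 60 heavy
atoms or > 4000 residues are dropped (boundaries inclusive). The bilabel
filter keeps only compounds observed in both classes; one pass is a fixed
point (removing a compound cannot change another compound's label set),
asserted at runtime.

The label-reversal split draws two disjoint ligand sets uniformly without
replacement (reference counts 2941 and 2900; scale them down for small
worlds): the test set is all negatives of the first set plus all
positives of the second, and the remainder splits 10:1 into
train:validation with validation = ⌊remainder/11⌋. Split outputs are
byte-stable under a fixed seed and ship with a JSON provenance sidecar.

## Metrics

ROC-AUC is the Mann–Whitney statistic (ties one half); PRC-AUC is the
step-interpolated area (average precision) — no linear interpolation,
which overestimates PR areas. The low-FPR ROC segment keeps all
threshold points (no curve simplification) so it matches a plain
threshold sweep. Enrichment factor at fraction f selects the top
k = ⌈f·n⌉ by score — ceiling guarantees a non-empty selection at 0.5% on
small libraries — with ties resolved by input order via a stable sort,
and reports (actives_in_top/k)/(n_active/n). All four agree with
brute-force reimplementations to 1e-9 on randomized instances.

## Interpretation analyses

**Mutation scan.** With wild-type score s and mutant score s′(i, j) for
position i mutated to residue j (20 canonical residues, including the
wild-type residue itself), ΔS(i, j) = |s − s′(i, j)|. A scan of a
length-L protein issues exactly 20·L + 1 forward evaluations, batched.
The per-position profile is ΔS̄ᵢ = mean over the 20 residue columns of
ΔS, and ΔRᵢ = ΔS̄ᵢ / max(ΔS̄); an all-zero profile yields all-zero ΔR
rather than 0/0. An alternative documented in the literature averages the
raw mutant scores s′ instead of ΔS; that variant is available as
`average="raw"` but the ΔS average is the default, since a raw-score
average does not measure change. Important sites are positions with
ΔR > 0.38 (an absolute cutoff that corresponds to roughly the top 5% of a
sequence) or an explicit top-quantile rule with ties kept. ΔR is
normalized per protein–compound pair.

**Substitution effect.** For matched pairs differing only by −CH₃ vs
−CF₃, Δs_c = score(CF₃) − score(CH₃) and ΔpAct = pAct(CF₃) − pAct(CH₃); a
prediction is correct iff Δs_c·ΔpAct > 0 (zero counts as incorrect —
correctness is defined by strict sign agreement). Accuracy is also
reported on the |ΔpAct| ≥ 1 and ≥ 3 subsets when potencies are provided.

Both analyses are interpretation tools: they localize what the model is
sensitive to; they are not validated predictors of resistance mutations
or activity cliffs.

## Screening

Forward pipeline order (following the published screen protocol
literally): top fraction by score → PAINS substructure filter →
fingerprint clustering → Lipinski filter → per-cluster representatives.
Fingerprints are Morgan/ECFP-like (radius 2, 2048 bits). Clustering is
leader-style sphere exclusion at Tanimoto distance 0.4 by default:
deterministic, order-stable, no library-specific semantics; cluster ids
are relabelled by descending size, and representative selection visits
clusters in the size order of the post-Lipinski survivors. The logP used
by the Lipinski rules is the Crippen atom-contribution estimate, recorded
in the report. A 10-pattern built-in substructure subset stands in for a
full PAINS catalogue in tests; full catalogues load from a TSV of SMARTS.
Inverse mode scores a protein panel against one compound and reports the
descending ranking with a top-k marker.

## Synthetic worlds

A world plants a residue motif (default `WKDHW`) in a set fraction of
random proteins (default 30 proteins of 20–28 residues, prevalence 0.5)
and a key substructure (default pyridine) in a set fraction of
template-assembled compounds (default 36, prevalence 0.5; the grammar is
a product of hand-written parseable prefixes, linkers and ring
fragments). Latent potency is base_p + effect·[motif]·[substructure] +
Gaussian noise on the p-scale; defaults base_p 5.5, effect 2.0, noise SD
0.5 — the noise level mirrors the ~0.5 log-unit scatter typical of public
potency data, and the 2-log effect is a strong, realistic potency gap
that crosses the 6.5 labelling threshold. The `separable` preset lowers
the noise to 0.25 (margin asserted). Raw ChEMBL-style records wrap every
sample, and the `filters` preset plants exact counts of records failing
each curation filter (wrong units, confidence 8, non-binding assay,
61-atom compound, 4001-residue protein). Matched −CH₃/−CF₃ pairs receive
an exact quota of large (≥ 1 log) potency shifts, default fraction
15.73%, with recorded true potencies for oracle use.

What the worlds do **not** emulate: real chemical diversity (the grammar
spans a few dozen scaffolds), realistic activity distributions,
protein-family structure, assay heterogeneity, or multiple binding
determinants per protein. Passing the planted-recovery tests shows the
architecture, training loop and analyses behave correctly end to end; it
does not certify accuracy on real ChEMBL-scale data, which requires
full-scale training outside this package's test scope. To rebuild the
full dataset, export from a ChEMBL release an activity table with the
`ActivityRecord` columns (one row per activity; sequences joined from the
target's single protein component) as TSV and feed it to
`seq2drug build-dataset` followed by `seq2drug split` with the reference
reversal counts.

## Numerical and degenerate-input choices

- float64 everywhere; attention mask constant −1e30 (underflows to exact
  zero weight after softmax).
- Softmax subtracts the row maximum as a constant; BCE is computed from
  logits via a stable softplus.
- Zero-degree (padding) rows in adjacency normalization stay zero rather
  than dividing by zero.
- Ties: EF and library rankings resolve score ties by input order; the
  quantile site rule breaks ties toward inclusion; leader clustering
  assigns to the first qualifying leader.
- Duplicate undirected bonds in graph construction are idempotent;
  adjacency is symmetric with a unit diagonal by construction.

## Known limitations

- The reference embedding provider is a deterministic stand-in with the
  contract of a protein language model, not a pretrained one; absolute
  probabilities from untrained or tiny models are not calibrated.
- The negative-control contrast for mutation scans (a signal-free
  compound producing a rank-decorrelated ΔR profile) does not manifest in
  single-motif synthetic worlds: ΔR is max-normalized and the planted
  motif is the only protein-side feature, so even near-zero absolute
  shifts rank-correlate with the signal profile. The suite instead
  verifies the causal dependence of the scan on the compound and the
  motif-recovery contrast. Distinguishing profiles by rank correlation
  requires proteins with multiple binding determinants.
- Training at full scale (hundreds of thousands of pairs, 768-dim
  encoder) is architecturally supported but computationally out of scope
  here; all quantitative guarantees in the test suite are statements
  about the desk-scale study conditions described above.
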