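"""Protein tokenization, per-residue embeddings, and sequence identity.

The tokenizer uses a fixed 26-id scheme: 0 = <pad>, ids 1-23 the 23 common
amino acids (the 20 canonical residues plus the ambiguity codes B, Z, X;
U, O and J map to X), 24 = <cls> (start), 25 = <sep> (separator). With
special tokens enabled a length-L sequence becomes L+2 ids.

Embeddings come from a pluggable provider. The reference provider is a
small deterministic lookup-plus-mixing network with the same call contract
as a pretrained protein language model: a seeded embedding table followed
by one nonlinear layer that mixes each position with its sequence
neighbours, so local sequence context (not just residue identity) is
encoded. An adapter for genuinely pretrained weights can implement the
same protocol.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np
from Bio import Align, SeqIO

PAD_ID = 0
CLS_ID = 24
SEP_ID = 25
# 23 "common" amino acids: 20 canonical + B, Z, X, in alphabetical order.
RESIDUE_ALPHABET = "ABCDEFGHIKLMNPQRSTVWXYZ"
CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUOUS_ID = RESIDUE_ALPHABET.index("X") + 1

_RES_TO_ID = {aa: i + 1 for i, aa in enumerate(RESIDUE_ALPHABET)}
for _alias in "UOJ":  # selenocysteine, pyrrolysine, ambiguous Leu/Ile -> X
    _RES_TO_ID[_alias] = AMBIGUOUS_ID
_ID_TO_RES = {i + 1: aa for i, aa in enumerate(RESIDUE_ALPHABET)}


@dataclass
class TokenizedProtein:
    ids: np.ndarray          # integer token ids
    residue_offset: int      # index of the first residue token
    length: int              # residue count L


@dataclass
class ProteinEmbedding:
    matrix: np.ndarray       # token count x width
    provider_name: str


class EmbeddingProvider(Protocol):
    name: str
    width: int

    def __call__(self, ids: np.ndarray) -> np.ndarray: ...


def tokenize(sequence: str, add_special_tokens: bool = True) -> TokenizedProtein:
    """Map a one-letter residue string to token ids.

    Case-insensitive; non-letter characters raise a ``ValueError`` listing
    the offending positions.
    """
    seq = sequence.upper()
    bad = [i for i, c in enumerate(seq) if not c.isalpha()]
    if bad:
        raise ValueError(f"non-letter characters at positions {bad} in sequence")
    ids = [_RES_TO_ID[c] for c in seq]
    if add_special_tokens:
        ids = [CLS_ID] + ids + [SEP_ID]
        offset = 1
    else:
        offset = 0
    return TokenizedProtein(ids=np.array(ids, dtype=np.int64),
                            residue_offset=offset, length=len(seq))


def detokenize(tokens: TokenizedProtein) -> str:
    core = tokens.ids[tokens.residue_offset:tokens.residue_offset + tokens.length]
    return "".join(_ID_TO_RES[int(i)] for i in core)


class ReferenceEmbeddingProvider:
    """Deterministic per-residue embedding network (desk-scale provider).

    A seeded lookup table over the 26 token ids feeds one tanh layer whose
    input is the position's own vector plus half the mean of its two
    neighbours, giving every position a local-context signature. Frozen at
    construction; identical (seed, width) always yields identical output.
    """

    def __init__(self, width: int = 768, seed: int = 0):
        self.width = int(width)
        self.seed = int(seed)
        self.name = f"reference-lookup-mix/w{width}/s{seed}"
        rng = np.random.default_rng(seed)
        scale = 1.0 / np.sqrt(self.width)
        self._table = rng.normal(0.0, 1.0, size=(26, self.width))
        self._w_self = rng.normal(0.0, scale, size=(self.width, self.width))
        self._w_ctx = rng.normal(0.0, scale, size=(self.width, self.width))

    def __call__(self, ids: np.ndarray) -> np.ndarray:
        x = self._table[np.asarray(ids, dtype=np.int64)]
        left = np.vstack([x[:1], x[:-1]])
        right = np.vstack([x[1:], x[-1:]])
        ctx = 0.5 * (left + right)
        return np.tanh(x @ self._w_self + ctx @ self._w_ctx)


def embed_protein(tokens: TokenizedProtein, provider: EmbeddingProvider,
                  expected_width: int | None = None) -> ProteinEmbedding:
    """Embed token ids with ``provider``; optionally enforce the width."""
    ids = tokens.ids
    if ids.min() < 0 or ids.max() > 25:
        raise ValueError("token ids must lie in [0, 25]")
    if expected_width is not None and provider.width != expected_width:
        raise ValueError(
            f"provider width {provider.width} does not match expected width {expected_width}"
        )
    matrix = np.asarray(provider(ids), dtype=np.float64)
    if matrix.shape != (len(ids), provider.width):
        raise ValueError("provider returned a matrix of the wrong shape")
    if not np.all(np.isfinite(matrix)):
        raise ValueError("provider returned non-finite values")
    return ProteinEmbedding(matrix=matrix, provider_name=provider.name)


def sequence_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment length.

    Needleman-Wunsch with match 1, mismatch 0, and a linear gap penalty of
    1 per gap symbol; identity is the fraction of aligned identical pairs
    over the full alignment length (gap columns included).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    a, b = a.upper(), b.upper()
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    aln = aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    matches = sum(x == y and x != "-" for x, y in zip(sa, sb))
    return matches / len(sa)


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a multi-record FASTA; returns (description, sequence) pairs."""
    return [(rec.description, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_token_tsv(records: list[tuple[str, str]], path,
                    add_special_tokens: bool = True) -> None:
    """Write (id, space-separated token ids) rows for FASTA-style records."""
    with open(path, "w") as fh:
        fh.write("id\ttoken_ids\n")
        for ident, seq in records:
            toks = tokenize(seq, add_special_tokens=add_special_tokens)
            fh.write(f"{ident}\t{' '.join(map(str, toks.ids))}\n")
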