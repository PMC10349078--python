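"""ChEMBL-style activity-table curation and label-reversal splitting.

The cleaning pipeline keeps single-protein, small-molecule, binding-assay
(type 'B') records with confidence score 9 and IC50/EC50/Ki potencies in
nM; potencies become pActivity = 9 - log10(value_nM) and samples are
labelled positive at the 6.5 boundary (inclusive). Pairs measured with
both labels are removed outright, oversized compounds (>60 heavy atoms)
and proteins (>4000 residues) are dropped, and only compounds appearing
in both classes are retained, which removes ligand-identity shortcuts.

The label-reversal split then hides two disjoint ligand sets: all negative
samples of set A and all positive samples of set B form the test set, so
those ligands carry the opposite label in training - a model that only
memorizes ligands is anti-correlated on the test set. Reference counts
are 2941 (negative pool) and 2900 (positive pool) ligands with the
remainder split 10:1 into train:validation.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass

import numpy as np

from .chem_graph import SmilesParseError, parse_molecule

logger = logging.getLogger(__name__)

ALLOWED_ACTIVITY_TYPES = {"IC50", "EC50", "Ki"}
POSITIVE_THRESHOLD = 6.5
MAX_HEAVY_ATOMS = 60
MAX_SEQUENCE_LENGTH = 4000
DEFAULT_NEG_REVERSAL_LIGANDS = 2941
DEFAULT_POS_REVERSAL_LIGANDS = 2900


@dataclass
class ActivityRecord:
    """One raw assay measurement with its curation metadata."""

    compound_id: str
    smiles: str
    target_id: str
    sequence: str
    activity_type: str
    value_nM: float
    confidence_score: int
    assay_type: str
    target_type: str
    molecule_type: str
    units: str = "nM"


@dataclass(frozen=True)
class CPISample:
    compound_key: str   # canonical largest-fragment SMILES
    protein_key: str    # exact residue string
    label: int          # 1 positive, 0 negative
    p_activity: float


@dataclass
class DatasetSplits:
    train: list[CPISample]
    validation: list[CPISample]
    test: list[CPISample]
    neg_reversal_ligands: set[str]
    pos_reversal_ligands: set[str]
    seed: int


def clean_records(records: list[ActivityRecord]) -> list[ActivityRecord]:
    """Apply the curation filters; keeps input order, never raises on content."""
    kept = []
    for r in records:
        if r.target_type != "SINGLE PROTEIN":
            continue
        if r.molecule_type != "Small molecule":
            continue
        if r.confidence_score != 9:
            continue
        if r.assay_type != "B":
            continue
        if r.activity_type not in ALLOWED_ACTIVITY_TYPES:
            continue
        if r.units != "nM":
            continue
        if r.value_nM is None or not np.isfinite(r.value_nM) or r.value_nM <= 0:
            continue
        kept.append(r)
    return kept


def to_p_activity(value_nM: float) -> float:
    """pActivity = -log10(molar value) = 9 - log10(value in nM)."""
    if not np.isfinite(value_nM) or value_nM <= 0:
        raise ValueError(f"potency must be a positive finite nM value, got {value_nM}")
    return 9.0 - math.log10(value_nM)


def assign_label(p_activity: float) -> int:
    """Positive iff pActivity >= 6.5 (boundary inclusive)."""
    if not np.isfinite(p_activity):
        raise ValueError(f"p_activity must be finite, got {p_activity}")
    return int(p_activity >= POSITIVE_THRESHOLD)


def records_to_samples(records: list[ActivityRecord]) -> list[CPISample]:
    """Label each cleaned record; compounds keyed by canonical SMILES.

    Unparsable compounds are dropped with a logged warning.
    """
    samples = []
    for r in records:
        try:
            mol = parse_molecule(r.smiles)
        except (ValueError, SmilesParseError):
            logger.warning("dropping record %s: unparsable SMILES %r", r.compound_id, r.smiles)
            continue
        p = to_p_activity(r.value_nM)
        samples.append(CPISample(compound_key=mol.canonical_smiles,
                                 protein_key=r.sequence.upper(),
                                 label=assign_label(p), p_activity=p))
    return samples


def remove_conflicts(samples: list[CPISample]) -> list[CPISample]:
    """Collapse duplicates; drop any pair observed with both labels.

    Keeps the first occurrence of each (compound, protein, label); a pair
    carrying both labels is removed entirely.
    """
    labels_by_pair: dict[tuple[str, str], set[int]] = {}
    for s in samples:
        labels_by_pair.setdefault((s.compound_key, s.protein_key), set()).add(s.label)
    out, emitted = [], set()
    for s in samples:
        pair = (s.compound_key, s.protein_key)
        if len(labels_by_pair[pair]) > 1 or pair in emitted:
            continue
        emitted.add(pair)
        out.append(s)
    return out


def filter_sizes(samples: list[CPISample],
                 max_atoms: int = MAX_HEAVY_ATOMS,
                 max_length: int = MAX_SEQUENCE_LENGTH) -> list[CPISample]:
    """Keep samples with <= 60 heavy atoms and sequences <= 4000 residues."""
    out = []
    for s in samples:
        if len(s.protein_key) > max_length:
            continue
        try:
            mol = parse_molecule(s.compound_key)
        except (ValueError, SmilesParseError):
            logger.warning("dropping sample with unparsable compound %r", s.compound_key)
            continue
        if mol.n_atoms > max_atoms:
            continue
        out.append(s)
    return out


def enforce_bilabel_compounds(samples: list[CPISample]) -> list[CPISample]:
    """Keep only compounds observed with both labels (on different proteins).

    A single pass suffices: removing a compound's samples cannot change the
    label multiset of any other compound (asserted below).
    """
    labels: dict[str, set[int]] = {}
    for s in samples:
        labels.setdefault(s.compound_key, set()).add(s.label)
    out = [s for s in samples if len(labels[s.compound_key]) == 2]
    assert enforce_bilabel_count(out) == len(out), "bilabel filter must be a fixed point"
    return out


def enforce_bilabel_count(samples: list[CPISample]) -> int:
    labels: dict[str, set[int]] = {}
    for s in samples:
        labels.setdefault(s.compound_key, set()).add(s.label)
    return sum(1 for s in samples if len(labels[s.compound_key]) == 2)


def label_reversal_split(samples: list[CPISample], n_neg_ligands: int,
                         n_pos_ligands: int, seed: int,
                         val_denominator: int = 11) -> DatasetSplits:
    """Hide opposite-label ligand sets in the test partition.

    Draws ``n_neg_ligands + n_pos_ligands`` distinct compounds uniformly
    without replacement under ``seed``. Test = negatives of the first set
    plus positives of the second; the remainder is split 10:1 into
    train:validation (validation = floor(remainder / 11)).
    """
    compounds = sorted({s.compound_key for s in samples})
    total = n_neg_ligands + n_pos_ligands
    if total > len(compounds):
        raise ValueError(
            f"requested {total} reversal ligands but only {len(compounds)} distinct compounds"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(compounds), size=total, replace=False)
    neg_set = {compounds[i] for i in chosen[:n_neg_ligands]}
    pos_set = {compounds[i] for i in chosen[n_neg_ligands:]}
    test, remainder = [], []
    for s in samples:
        if s.compound_key in neg_set and s.label == 0:
            test.append(s)
        elif s.compound_key in pos_set and s.label == 1:
            test.append(s)
        else:
            remainder.append(s)
    order = rng.permutation(len(remainder))
    n_val = len(remainder) // val_denominator
    val_idx = set(order[:n_val].tolist())
    validation = [remainder[i] for i in sorted(val_idx)]
    train = [remainder[i] for i in range(len(remainder)) if i not in val_idx]
    return DatasetSplits(train=train, validation=validation, test=test,
                         neg_reversal_ligands=neg_set, pos_reversal_ligands=pos_set,
                         seed=seed)


def build_dataset(records: list[ActivityRecord]) -> list[CPISample]:
    """Full curation pipeline: clean -> label -> de-conflict -> size filter
    -> bilabel enforcement."""
    return enforce_bilabel_compounds(
        filter_sizes(remove_conflicts(records_to_samples(clean_records(records))))
    )


# ----------------------------------------------------------------------- I/O

_COLUMNS = ["compound_id", "smiles", "target_id", "sequence", "activity_type",
            "value_nM", "confidence_score", "assay_type", "target_type",
            "molecule_type", "units"]


def read_activity_table(path) -> list[ActivityRecord]:
    """Read a TSV/CSV activity table (header required) into records."""
    import pandas as pd

    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in _COLUMNS if c not in df.columns and c != "units"]
    if missing:
        raise ValueError(f"activity table missing columns: {missing}")
    if "units" not in df.columns:
        df["units"] = "nM"
    return [
        ActivityRecord(
            compound_id=str(row.compound_id), smiles=str(row.smiles),
            target_id=str(row.target_id), sequence=str(row.sequence),
            activity_type=str(row.activity_type), value_nM=float(row.value_nM),
            confidence_score=int(row.confidence_score), assay_type=str(row.assay_type),
            target_type=str(row.target_type), molecule_type=str(row.molecule_type),
            units=str(row.units),
        )
        for row in df.itertuples(index=False)
    ]


def write_splits(splits: DatasetSplits, out_dir) -> None:
    """Write train/validation/test TSVs plus a JSON provenance sidecar."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("train", "validation", "test"):
        with open(out / f"{name}.tsv", "w") as fh:
            fh.write("compound_key\tprotein_key\tlabel\tp_activity\n")
            for s in getattr(splits, name):
                fh.write(f"{s.compound_key}\t{s.protein_key}\t{s.label}\t{s.p_activity:.6f}\n")
    sidecar = {
        "seed": splits.seed,
        "neg_reversal_ligands": sorted(splits.neg_reversal_ligands),
        "pos_reversal_ligands": sorted(splits.pos_reversal_ligands),
        "counts": {"train": len(splits.train), "validation": len(splits.validation),
                   "test": len(splits.test)},
    }
    (out / "provenance.json").write_text(json.dumps(sidecar, indent=2))


def read_split_tsv(path) -> list[CPISample]:
    samples = []
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("compound_key")
        for line in fh:
            ck, pk, label, p = line.rstrip("\n").split("\t")
            samples.append(CPISample(ck, pk, int(label), float(p)))
    return samples
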