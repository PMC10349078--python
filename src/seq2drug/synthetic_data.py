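"""Synthetic compound-protein worlds with planted, known ground truth.

A world consists of random protein sequences, a fraction of which carry a
planted sequence motif, and template-assembled compounds, a fraction of
which carry a planted substructure. The latent potency of a pair is

    p = base_p + effect_size * [protein has motif] * [compound has
        substructure] + Gaussian noise (p-scale),

and the binary label is p >= threshold. Because the ground truth is a
known closed-form rule, every downstream module (curation, training,
metrics, mutation scanning, substitution analysis, screening) can be
tested against an exact oracle without any external data. The Gaussian
p-scale noise emulates the ~0.5 log-unit experimental scatter typical of
public potency data; the default effect size of 2 p-units is a strong but
realistic potency gap between motif-matched binders and non-binders.

The generator also emits ChEMBL-style raw activity records wrapping each
sample with assay metadata, optionally planting records that fail each
curation filter in known numbers, and matched methyl/trifluoromethyl
compound pairs with an exactly assigned fraction of large potency shifts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem_graph import parse_molecule
from .dataset_builder import ActivityRecord, CPISample, DatasetSplits
from .protein_seq import CANONICAL_RESIDUES

_PREFIXES = ["CCO", "CCN", "CC(C)", "CC(=O)N", "CCCC", "COC"]
_LINKERS = ["", "C", "CC", "C(C)"]
_DECOY_FRAGMENTS = ["c1ccccc1", "C1CCCCC1", "C1CCCC1", "C1CCOC1"]

_PAIR_TEMPLATES = [
    "CC(=O)Nc1ccc({M})cc1",
    "OCc1ccc({M})cc1",
    "CCOc1ccc({M})cc1",
    "NC(=O)c1ccc({M})cc1",
    "Cc1ccc({M})cc1",
    "CCC(=O)c1ccc({M})cc1",
    "Oc1ccc({M})cc1",
    "CN(C)c1ccc({M})cc1",
]


@dataclass
class WorldSpec:
    n_proteins: int = 30
    protein_length_range: tuple[int, int] = (20, 28)
    motif: str = "WKDHW"
    motif_prevalence: float = 0.5
    n_compounds: int = 36
    key_substructure: str = "c1ccncc1"
    substructure_prevalence: float = 0.5
    base_p: float = 5.5
    effect_size: float = 2.0
    noise_sd: float = 0.5
    threshold: float = 6.5
    pairs_per_compound: int = 10
    planted_failures: dict[str, int] = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def separable(cls, seed: int = 0, **kw) -> "WorldSpec":
        """Low-noise preset: effect_size > 2 * noise_sd (asserted)."""
        spec = cls(noise_sd=0.25, seed=seed, **kw)
        assert spec.effect_size > 2 * spec.noise_sd, "separable preset requires a clear margin"
        return spec

    @classmethod
    def noisy(cls, seed: int = 0, **kw) -> "WorldSpec":
        return cls(noise_sd=0.5, seed=seed, **kw)

    @classmethod
    def filters(cls, seed: int = 0, **kw) -> "WorldSpec":
        """Preset planting records that fail each curation filter."""
        return cls(
            planted_failures={"bad_units": 2, "bad_confidence": 2, "bad_assay": 2,
                              "big_compound": 1, "long_protein": 1},
            seed=seed, **kw,
        )


@dataclass
class World:
    spec: WorldSpec
    proteins: list[tuple[str, str]]           # (id, sequence)
    compounds: list[tuple[str, str]]          # (id, canonical smiles)
    samples: list[CPISample]
    records: list[ActivityRecord]
    protein_has_motif: dict[str, bool]        # keyed by sequence
    compound_has_key: dict[str, bool]         # keyed by canonical smiles
    manifest: dict


def _random_protein(rng: np.random.Generator, length: int, motif: str | None) -> str:
    res = rng.choice(list(CANONICAL_RESIDUES), size=length)
    seq = "".join(res)
    if motif:
        pos = int(rng.integers(0, length - len(motif) + 1))
        seq = seq[:pos] + motif + seq[pos + len(motif):]
    return seq


def _compound_pool(key_fragment: str) -> tuple[list[str], list[str]]:
    """Enumerate parseable, canonical-distinct compounds with/without the key."""
    key_q = Chem.MolFromSmarts(key_fragment)
    with_key, without_key = [], []
    seen = set()
    for frag in [key_fragment] + _DECOY_FRAGMENTS:
        for prefix in _PREFIXES:
            for linker in _LINKERS:
                smiles = prefix + linker + frag
                mol = Chem.MolFromSmiles(smiles)
                if mol is None:
                    raise RuntimeError(f"compound grammar produced unparsable SMILES {smiles!r}")
                canonical = Chem.MolToSmiles(mol)
                if canonical in seen:
                    continue
                seen.add(canonical)
                (with_key if mol.HasSubstructMatch(key_q) else without_key).append(canonical)
    return with_key, without_key


def generate_world(spec: WorldSpec) -> World:
    """Generate a seeded world; identical specs yield identical worlds."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.protein_length_range
    if hi < lo or lo <= len(spec.motif):
        raise ValueError("protein_length_range must exceed the motif length")

    n_motif = round(spec.motif_prevalence * spec.n_proteins)
    has_motif_flags = np.array([True] * n_motif + [False] * (spec.n_proteins - n_motif))
    rng.shuffle(has_motif_flags)
    proteins, protein_has_motif = [], {}
    for i, flag in enumerate(has_motif_flags):
        while True:
            length = int(rng.integers(lo, hi + 1))
            seq = _random_protein(rng, length, spec.motif if flag else None)
            # reject accidental motifs in background proteins and duplicates
            if not flag and spec.motif in seq:
                continue
            if seq not in protein_has_motif:
                break
        proteins.append((f"P{i:04d}", seq))
        protein_has_motif[seq] = bool(flag)

    with_key, without_key = _compound_pool(spec.key_substructure)
    n_key = round(spec.substructure_prevalence * spec.n_compounds)
    if n_key > len(with_key) or spec.n_compounds - n_key > len(without_key):
        raise ValueError("compound grammar too small for the requested world size")
    key_pick = rng.choice(len(with_key), size=n_key, replace=False)
    decoy_pick = rng.choice(len(without_key), size=spec.n_compounds - n_key, replace=False)
    chosen = [(with_key[i], True) for i in key_pick] + [(without_key[i], False) for i in decoy_pick]
    rng.shuffle(chosen)
    compounds = [(f"C{i:04d}", smi) for i, (smi, _) in enumerate(chosen)]
    compound_has_key = {smi: flag for smi, flag in chosen}

    samples: list[CPISample] = []
    records: list[ActivityRecord] = []
    act_types = ["IC50", "EC50", "Ki"]
    for ci, (cid, smi) in enumerate(compounds):
        prot_idx = rng.choice(spec.n_proteins, size=min(spec.pairs_per_compound, spec.n_proteins),
                              replace=False)
        for pi in prot_idx:
            pid, seq = proteins[pi]
            hit = protein_has_motif[seq] and compound_has_key[smi]
            p = spec.base_p + spec.effect_size * hit + spec.noise_sd * rng.normal()
            samples.append(CPISample(compound_key=smi, protein_key=seq,
                                     label=int(p >= spec.threshold), p_activity=float(p)))
            records.append(ActivityRecord(
                compound_id=cid, smiles=smi, target_id=pid, sequence=seq,
                activity_type=act_types[(ci + int(pi)) % 3],
                value_nM=float(10.0 ** (9.0 - p)), confidence_score=9, assay_type="B",
                target_type="SINGLE PROTEIN", molecule_type="Small molecule", units="nM",
            ))

    planted = dict(spec.planted_failures)
    if planted and not records:
        raise ValueError("cannot plant failing records in an empty world")
    base = records[0] if records else None
    fail_makers = {
        "bad_units": lambda r: _clone(r, units="uM"),
        "bad_confidence": lambda r: _clone(r, confidence_score=8),
        "bad_assay": lambda r: _clone(r, assay_type="F"),
        "big_compound": lambda r: _clone(r, smiles="C" * 61, compound_id="C_BIG"),
        "long_protein": lambda r: _clone(
            r, sequence="".join(rng.choice(list(CANONICAL_RESIDUES), size=4001)),
            target_id="P_LONG"),
    }
    for kind, count in planted.items():
        if kind not in fail_makers:
            raise ValueError(f"unknown planted failure kind {kind!r}")
        for _ in range(count):
            records.append(fail_makers[kind](base))

    manifest = {
        "spec": {**asdict(spec), "protein_length_range": list(spec.protein_length_range)},
        "n_motif_proteins": int(n_motif),
        "n_key_compounds": int(n_key),
        "n_samples": len(samples),
        "n_positive": int(sum(s.label for s in samples)),
        "n_records": len(records),
        "planted_failures": planted,
        "n_cleaner_failing_records": sum(
            planted.get(k, 0) for k in ("bad_units", "bad_confidence", "bad_assay")),
    }
    return World(spec=spec, proteins=proteins, compounds=compounds, samples=samples,
                 records=records, protein_has_motif=protein_has_motif,
                 compound_has_key=compound_has_key, manifest=manifest)


def _clone(r: ActivityRecord, **kw) -> ActivityRecord:
    d = asdict(r)
    d.update(kw)
    return ActivityRecord(**d)


class OracleScorer:
    """Exact scorer implementing the world's generative rule (noiseless)."""

    def __init__(self, world: World):
        self._world = world
        self._compounds = set(world.compound_has_key)
        self._proteins = set(world.protein_has_motif)
        self._key_q = Chem.MolFromSmarts(world.spec.key_substructure)

    def p_activity(self, smiles: str, sequence: str) -> float:
        spec = self._world.spec
        canonical = parse_molecule(smiles).canonical_smiles
        if canonical not in self._compounds:
            raise LookupError(f"compound {smiles!r} is not part of this world")
        if sequence not in self._proteins:
            raise LookupError("protein sequence is not part of this world")
        hit = self._world.protein_has_motif[sequence] and self._world.compound_has_key[canonical]
        return spec.base_p + spec.effect_size * hit

    def __call__(self, smiles: str, sequence: str) -> float:
        """Logistic-squashed latent potency centred on the label threshold."""
        p = self.p_activity(smiles, sequence)
        return 1.0 / (1.0 + np.exp(-(p - self._world.spec.threshold)))


def make_oracle(world: World) -> OracleScorer:
    return OracleScorer(world)


def generate_substitution_pairs(n_pairs: int, fraction_large_shift: float = 0.1573,
                                shift_magnitude_range: tuple[float, float] = (1.0, 3.0),
                                small_shift_range: tuple[float, float] = (0.05, 0.95),
                                seed: int = 0) -> pd.DataFrame:
    """Matched -CH3/-CF3 pairs with an exact large-shift quota.

    Each pair differs only at the methyl slot of its template. Exactly
    ``round(fraction_large_shift * n_pairs)`` pairs receive a potency
    shift of at least one log unit (|dpAct| in ``shift_magnitude_range``,
    sign random); the rest receive |dpAct| in ``small_shift_range``.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    n_large = round(fraction_large_shift * n_pairs)
    large_flags = np.array([True] * n_large + [False] * (n_pairs - n_large))
    rng.shuffle(large_flags)
    rows = []
    for i, is_large in enumerate(large_flags):
        template = _PAIR_TEMPLATES[i % len(_PAIR_TEMPLATES)]
        if "{M}" not in template:
            raise ValueError(f"template {template!r} lacks the methyl slot")
        smiles_ch3 = template.replace("{M}", "C")
        smiles_cf3 = template.replace("{M}", "C(F)(F)F")
        for smi in (smiles_ch3, smiles_cf3):
            if Chem.MolFromSmiles(smi) is None:
                raise RuntimeError(f"pair grammar produced unparsable SMILES {smi!r}")
        lo, hi = shift_magnitude_range if is_large else small_shift_range
        delta = float(rng.uniform(lo, hi)) * (1 if rng.random() < 0.5 else -1)
        pact_ch3 = float(rng.uniform(5.0, 8.0))
        sequence = _random_protein(rng, int(rng.integers(20, 29)), None)
        rows.append({"smiles_ch3": smiles_ch3, "smiles_cf3": smiles_cf3,
                     "pact_ch3": pact_ch3, "pact_cf3": pact_ch3 + delta,
                     "sequence": sequence, "large_shift": bool(is_large)})
    return pd.DataFrame(rows)


def pair_oracle(pairs: pd.DataFrame):
    """Scorer returning the recorded true pActivity for pair compounds."""
    table: dict[tuple[str, str], float] = {}
    for row in pairs.itertuples(index=False):
        table[(Chem.MolToSmiles(Chem.MolFromSmiles(row.smiles_ch3)), row.sequence)] = row.pact_ch3
        table[(Chem.MolToSmiles(Chem.MolFromSmiles(row.smiles_cf3)), row.sequence)] = row.pact_cf3

    def score(smiles: str, sequence: str) -> float:
        key = (Chem.MolToSmiles(Chem.MolFromSmiles(smiles)), sequence)
        if key not in table:
            raise LookupError(f"pair ({smiles!r}, ...) not in the substitution table")
        return table[key]

    return score


def random_splits(samples: list[CPISample], seed: int,
                  fractions: tuple[float, float] = (0.8, 0.1)) -> DatasetSplits:
    """Plain random train/validation/test split (no label reversal)."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    n_train = int(fractions[0] * len(samples))
    n_val = int(fractions[1] * len(samples))
    pick = lambda idx: [samples[i] for i in idx]
    return DatasetSplits(train=pick(order[:n_train]),
                         validation=pick(order[n_train:n_train + n_val]),
                         test=pick(order[n_train + n_val:]),
                         neg_reversal_ligands=set(), pos_reversal_ligands=set(),
                         seed=seed)


def write_world(world: World, out_dir) -> None:
    """Write FASTA, .smi, activity TSV and the ground-truth manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "proteins.fasta", "w") as fh:
        for pid, seq in world.proteins:
            fh.write(f">{pid} motif={int(world.protein_has_motif[seq])}\n{seq}\n")
    with open(out / "compounds.smi", "w") as fh:
        for cid, smi in world.compounds:
            fh.write(f"{smi}\t{cid}\n")
    df = pd.DataFrame([asdict(r) for r in world.records])
    df.to_csv(out / "activity.tsv", sep="\t", index=False)
    (out / "manifest.json").write_text(json.dumps(world.manifest, indent=2))
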