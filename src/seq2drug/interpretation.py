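"""Model interpretation: in-silico mutation scanning and the methyl /
trifluoromethyl substitution-effect analysis.

Mutation scanning mimics alanine scanning at saturation: every position
of the protein is mutated to each of the 20 canonical residues (including
itself) and the absolute change of the predicted interaction score,
dS(i, j) = |s - s'(i, j)|, is recorded. The per-position mean of dS is
max-normalized into the relative activity change profile dR in [0, 1];
positions with high dR are called important sites (absolute cutoff 0.38,
corresponding to the top ~5% of a sequence, or an explicit top-quantile
rule).

The substitution analysis scores matched compound pairs differing only by
-CH3 vs -CF3 and compares the sign of the predicted score change with the
sign of the true potency change; a prediction is correct iff the signs
agree (a zero change counts as incorrect).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .chem_graph import Molecule, SmilesParseError, molecule_graph, parse_molecule
from .interaction_model import CPIModel, score_batch
from .protein_seq import CANONICAL_RESIDUES, EmbeddingProvider, embed_protein, tokenize

logger = logging.getLogger(__name__)

IMPORTANT_SITE_CUTOFF = 0.38
IMPORTANT_SITE_QUANTILE = 0.05


@dataclass
class MutationScanResult:
    delta_S: np.ndarray          # L x 20 absolute score changes
    s_prime: np.ndarray          # L x 20 raw mutant scores
    delta_S_bar: np.ndarray      # per-position mean shift (length L)
    delta_R: np.ndarray          # max-normalized profile in [0, 1]
    base_score: float            # wild-type score s
    alphabet: str                # column order of delta_S
    important_sites: list[int]   # 1-based positions
    wild_type: str
    n_evaluations: int           # distinct forward evaluations issued


@dataclass
class SubstitutionPair:
    smiles_ch3: str
    smiles_cf3: str
    p_act_ch3: float
    p_act_cf3: float
    delta_pact: float
    delta_s_c: float
    correct: bool


@dataclass
class SubstitutionEffectResult:
    pairs: list[SubstitutionPair]
    accuracy: float
    accuracy_shift_ge1: float | None
    accuracy_shift_ge3: float | None
    n_skipped: int


def mutation_scan(model: CPIModel, provider: EmbeddingProvider, sequence: str,
                  compound: Molecule | str, batch_size: int = 64,
                  average: str = "delta",
                  site_cutoff: float = IMPORTANT_SITE_CUTOFF) -> MutationScanResult:
    """Saturation mutation scan of ``sequence`` against ``compound``.

    Issues exactly 20 * L + 1 forward evaluations (batched). ``average``
    selects what feeds the per-position profile: ``"delta"`` (default)
    averages the absolute shifts dS; ``"raw"`` averages the raw mutant
    scores s' instead.
    """
    if not sequence:
        raise ValueError("protein sequence must be non-empty")
    if average not in ("delta", "raw"):
        raise ValueError(f"average must be 'delta' or 'raw', got {average!r}")
    mol = parse_molecule(compound) if isinstance(compound, str) else compound
    graph = molecule_graph(mol)
    seq = sequence.upper()
    L = len(seq)
    noncanonical = [i + 1 for i, c in enumerate(seq) if c not in CANONICAL_RESIDUES]
    if noncanonical:
        logger.info("positions %s carry non-canonical residues; scanned against "
                    "the canonical alphabet", noncanonical)

    def embed(s: str):
        return embed_protein(tokenize(s), provider)

    base_score = score_batch(model, [(graph, embed(seq))])[0].probability
    n_evaluations = 1
    mutants = []
    for i in range(L):
        for aa in CANONICAL_RESIDUES:
            mutants.append(seq[:i] + aa + seq[i + 1:])
    s_prime = np.empty(L * 20)
    for start in range(0, len(mutants), batch_size):
        part = mutants[start:start + batch_size]
        pairs = [(graph, embed(m)) for m in part]
        scores = score_batch(model, pairs)
        s_prime[start:start + len(part)] = [s.probability for s in scores]
        n_evaluations += len(part)
    s_prime = s_prime.reshape(L, 20)
    delta_S = np.abs(base_score - s_prime)
    profile_source = delta_S if average == "delta" else s_prime
    delta_S_bar, delta_R = relative_activity_change(profile_source)
    sites = important_sites(delta_R, mode="absolute", value=site_cutoff)
    return MutationScanResult(delta_S=delta_S, s_prime=s_prime,
                              delta_S_bar=delta_S_bar, delta_R=delta_R,
                              base_score=base_score, alphabet=CANONICAL_RESIDUES,
                              important_sites=sites, wild_type=seq,
                              n_evaluations=n_evaluations)


def relative_activity_change(delta_S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-position mean of the residue columns, then max-normalization.

    An all-zero mean profile yields an all-zero dR (the normalization is
    undefined there).
    """
    delta_S = np.asarray(delta_S, dtype=np.float64)
    if delta_S.ndim != 2 or delta_S.size == 0:
        raise ValueError("delta_S must be a non-empty L x 20 matrix")
    delta_S_bar = delta_S.mean(axis=1)
    peak = delta_S_bar.max()
    if peak > 0:
        delta_R = delta_S_bar / peak
    else:
        delta_R = np.zeros_like(delta_S_bar)
    return delta_S_bar, delta_R


def important_sites(delta_R: np.ndarray, mode: str = "absolute",
                    value: float = IMPORTANT_SITE_CUTOFF) -> list[int]:
    """1-based positions called important.

    ``absolute`` mode returns positions with dR > value (default 0.38);
    ``quantile`` mode returns the top ceil(value * L) positions with ties
    broken toward inclusion.
    """
    delta_R = np.asarray(delta_R, dtype=np.float64)
    if mode == "absolute":
        return [int(i) + 1 for i in np.nonzero(delta_R > value)[0]]
    if mode == "quantile":
        if not 0 < value < 1:
            raise ValueError(f"quantile must lie in (0, 1), got {value}")
        k = max(1, int(np.ceil(value * delta_R.size)))
        cutoff = np.sort(delta_R)[::-1][k - 1]
        return [int(i) + 1 for i in np.nonzero(delta_R >= cutoff)[0]]
    raise ValueError(f"unknown mode {mode!r}")


def substitution_effect(scorer, pairs) -> SubstitutionEffectResult:
    """Sign-agreement analysis of -CH3 -> -CF3 substitution pairs.

    ``scorer(smiles, sequence) -> float`` must be deterministic. ``pairs``
    is an iterable of mappings (or a DataFrame) with columns smiles_ch3,
    smiles_cf3, pact_ch3, pact_cf3, sequence. A pair is predicted
    correctly iff delta_s_c and delta_pAct share a strict sign
    (product > 0); unparseable pairs are skipped and excluded from the
    denominator.
    """
    try:
        rows = pairs.to_dict("records")
    except AttributeError:
        rows = list(pairs)
    results: list[SubstitutionPair] = []
    n_skipped = 0
    for row in rows:
        try:
            parse_molecule(row["smiles_ch3"])
            parse_molecule(row["smiles_cf3"])
        except (ValueError, SmilesParseError):
            logger.warning("skipping pair with unparsable structure: %r / %r",
                           row["smiles_ch3"], row["smiles_cf3"])
            n_skipped += 1
            continue
        delta_pact = float(row["pact_cf3"]) - float(row["pact_ch3"])
        delta_s_c = (scorer(row["smiles_cf3"], row["sequence"])
                     - scorer(row["smiles_ch3"], row["sequence"]))
        results.append(SubstitutionPair(
            smiles_ch3=row["smiles_ch3"], smiles_cf3=row["smiles_cf3"],
            p_act_ch3=float(row["pact_ch3"]), p_act_cf3=float(row["pact_cf3"]),
            delta_pact=delta_pact, delta_s_c=float(delta_s_c),
            correct=bool(delta_pact * delta_s_c > 0)))
    if not results:
        raise ValueError("no scorable pairs")
    accuracy = float(np.mean([p.correct for p in results]))

    def subset_acc(threshold: float) -> float | None:
        subset = [p for p in results if abs(p.delta_pact) >= threshold]
        return float(np.mean([p.correct for p in subset])) if subset else None

    return SubstitutionEffectResult(pairs=results, accuracy=accuracy,
                                    accuracy_shift_ge1=subset_acc(1.0),
                                    accuracy_shift_ge3=subset_acc(3.0),
                                    n_skipped=n_skipped)


def model_scorer(model: CPIModel, provider: EmbeddingProvider):
    """Adapt a trained model into a (smiles, sequence) -> probability scorer."""
    from .trainer import PairFeaturizer

    featurizer = PairFeaturizer(provider)

    def score(smiles: str, sequence: str) -> float:
        pair = (featurizer.graph(parse_molecule(smiles).canonical_smiles),
                featurizer.embedding(sequence.upper()))
        return score_batch(model, [pair])[0].probability

    return score


def write_scan_tsv(result: MutationScanResult, prefix, protein_id: str = "protein") -> None:
    """Write heatmap-ready dS, the dR profile, and important sites as TSVs."""
    from pathlib import Path

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(f"{prefix}.delta_s.tsv", "w") as fh:
        fh.write("position\twild_type\t" + "\t".join(result.alphabet) + "\n")
        for i in range(result.delta_S.shape[0]):
            row = "\t".join(f"{v:.6f}" for v in result.delta_S[i])
            fh.write(f"{i + 1}\t{result.wild_type[i]}\t{row}\n")
    with open(f"{prefix}.delta_r.tsv", "w") as fh:
        fh.write("position\twild_type\tdelta_r\n")
        for i, v in enumerate(result.delta_R):
            fh.write(f"{i + 1}\t{result.wild_type[i]}\t{v:.6f}\n")
    with open(f"{prefix}.sites.tsv", "w") as fh:
        fh.write("protein_id\tstart\tend\tdelta_r\n")
        for pos in result.important_sites:
            fh.write(f"{protein_id}\t{pos}\t{pos}\t{result.delta_R[pos - 1]:.6f}\n")
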