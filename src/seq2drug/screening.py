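"""Virtual screening pipeline and inverse target ranking.

Forward mode scores a compound library against one protein and distils
hits through the stages: top-fraction by score, PAINS substructure
filter, fingerprint clustering, drug-likeness (Lipinski) filter, and
per-cluster representative selection. Inverse mode ranks a protein panel
against one compound by predicted interaction probability.

Clustering is leader-style sphere exclusion on Tanimoto distance over
Morgan (ECFP-like) fingerprints: compounds are visited in input order,
join the first leader within the cutoff, or found a new cluster.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski
from rdkit.Chem import rdFingerprintGenerator

from .chem_graph import Molecule, SmilesParseError, molecule_graph, parse_molecule
from .interaction_model import CPIModel, score_batch
from .protein_seq import EmbeddingProvider, embed_protein, tokenize

logger = logging.getLogger(__name__)

# Small built-in catalogue of promiscuous-binder (PAINS-style) substructures
# for desk-scale tests; a full catalogue can be loaded from a SMARTS file.
DEFAULT_PAINS_SUBSET: list[tuple[str, str]] = [
    ("quinone_a", "O=C1C=CC(=O)C=C1"),
    ("catechol_a", "c1cc(O)c(O)cc1"),
    ("azo_aryl", "cN=Nc"),
    ("rhodanine", "S=C1SCC(=O)N1"),
    ("nitro_aryl", "c[N+](=O)[O-]"),
    ("aldehyde_aryl", "c[CH]=O"),
    ("hydrazone", "C=NN"),
    ("thiourea", "NC(=S)N"),
    ("michael_acceptor_ketone", "C=CC(=O)C=C"),
    ("beta_lactam_fused_thiazolidine", "O=C1CC2SCCN12"),
]


@dataclass
class ScreeningConfig:
    top_fraction: float = 0.02
    cluster_cutoff: float = 0.4          # Tanimoto distance
    lipinski_max_violations: int = 1
    fingerprint_radius: int = 2
    fingerprint_width: int = 2048
    representatives_per_cluster: int = 1

    def __post_init__(self):
        if not 0 < self.top_fraction <= 1:
            raise ValueError(f"top_fraction must lie in (0, 1], got {self.top_fraction}")


@dataclass
class ScreeningReport:
    ranked: pd.DataFrame                  # id, smiles, score (descending)
    stage_counts: dict[str, int]
    clusters: dict[str, int]              # compound id -> cluster id
    representatives: list[str]            # compound ids
    logp_method: str = "Crippen atom-contribution (RDKit)"


def load_pains_catalog(path=None) -> list[tuple[str, Chem.Mol]]:
    """Compile the bundled subset or a file of `id<TAB>SMARTS` lines."""
    if path is None:
        entries = DEFAULT_PAINS_SUBSET
    else:
        entries = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                ident, smarts = line.split("\t")
                entries.append((ident, smarts))
    catalog = []
    for ident, smarts in entries:
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"malformed substructure pattern {ident!r}: {smarts!r}")
        catalog.append((ident, patt))
    return catalog


def score_library(model: CPIModel, provider: EmbeddingProvider,
                  library: list[tuple[str, str]], sequence: str,
                  chunk: int = 64) -> pd.DataFrame:
    """Score (id, smiles) entries against one protein; descending by score.

    Unparseable entries are skipped with a logged warning; score ties keep
    input order.
    """
    if not library:
        raise ValueError("library must be non-empty")
    embedding = embed_protein(tokenize(sequence), provider)
    rows = []
    graphs = []
    for ident, smiles in library:
        try:
            mol = parse_molecule(smiles)
        except (ValueError, SmilesParseError):
            logger.warning("skipping unparsable library entry %s: %r", ident, smiles)
            continue
        rows.append((ident, mol.canonical_smiles))
        graphs.append(molecule_graph(mol))
    scores = []
    for start in range(0, len(graphs), chunk):
        part = graphs[start:start + chunk]
        scores.extend(s.probability for s in score_batch(model, [(g, embedding) for g in part]))
    df = pd.DataFrame(rows, columns=["id", "smiles"])
    df["score"] = scores
    return df.sort_values("score", ascending=False, kind="stable").reset_index(drop=True)


def lipinski_filter(mol: Molecule | str, max_violations: int = 1) -> tuple[bool, list[str]]:
    """Oral drug-likeness rules: MW<=500, logP<=5, donors<=5, acceptors<=10."""
    mol = parse_molecule(mol) if isinstance(mol, str) else mol
    rd = mol._rdmol
    violations = []
    mw = Descriptors.MolWt(rd)
    logp = Crippen.MolLogP(rd)
    donors = Lipinski.NumHDonors(rd)
    acceptors = Lipinski.NumHAcceptors(rd)
    if mw > 500:
        violations.append(f"MW {mw:.1f} > 500")
    if logp > 5:
        violations.append(f"logP {logp:.2f} > 5")
    if donors > 5:
        violations.append(f"{donors} H-bond donors > 5")
    if acceptors > 10:
        violations.append(f"{acceptors} H-bond acceptors > 10")
    return len(violations) <= max_violations, violations


def pains_filter(mol: Molecule | str, catalog=None) -> tuple[bool, list[str]]:
    """Returns (flagged, matched pattern ids)."""
    mol = parse_molecule(mol) if isinstance(mol, str) else mol
    if catalog is None:
        catalog = load_pains_catalog()
    matched = [ident for ident, patt in catalog if mol._rdmol.HasSubstructMatch(patt)]
    return bool(matched), matched


def fingerprint(mol: Molecule | str, radius: int = 2, width: int = 2048) -> frozenset[int]:
    """Morgan (circular / ECFP-like) fingerprint as a set of on-bits."""
    mol = parse_molecule(mol) if isinstance(mol, str) else mol
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=width)
    return frozenset(gen.GetFingerprint(mol._rdmol).GetOnBits())


def tanimoto(a: frozenset[int], b: frozenset[int]) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def cluster_compounds(fingerprints: list[frozenset[int]], cutoff: float) -> np.ndarray:
    """Leader clustering on Tanimoto distance; ids ordered by cluster size.

    Visits fingerprints in input order; each joins the first leader whose
    Tanimoto distance is <= cutoff, otherwise founds a new cluster.
    Cluster ids are relabelled by descending size (ties: first-founded).
    """
    if not fingerprints:
        raise ValueError("need at least one fingerprint")
    leaders: list[tuple[int, frozenset[int]]] = []
    raw = np.empty(len(fingerprints), dtype=np.int64)
    for idx, fp in enumerate(fingerprints):
        for lid, lfp in leaders:
            if 1.0 - tanimoto(fp, lfp) <= cutoff:
                raw[idx] = lid
                break
        else:
            lid = len(leaders)
            leaders.append((lid, fp))
            raw[idx] = lid
    sizes = np.bincount(raw, minlength=len(leaders))
    order = sorted(range(len(leaders)), key=lambda l: (-sizes[l], l))
    relabel = {old: new for new, old in enumerate(order)}
    return np.array([relabel[l] for l in raw], dtype=np.int64)


def select_representatives(scores: dict[str, float], clusters: dict[str, int],
                           k_per_cluster: int = 1) -> list[str]:
    """Top-k compounds by score within each cluster, largest clusters first."""
    if set(scores) != set(clusters):
        raise ValueError("scores and clusters must cover the same compound ids")
    members: dict[int, list[str]] = {}
    for ident, cl in clusters.items():
        members.setdefault(cl, []).append(ident)
    ordered_clusters = sorted(members, key=lambda c: (-len(members[c]), c))
    picks = []
    for cl in ordered_clusters:
        ranked = sorted(members[cl], key=lambda i: -scores[i])
        picks.extend(ranked[:k_per_cluster])
    return picks


def novelty_check(query_fp: frozenset[int],
                  references: list[tuple[str, frozenset[int]]]) -> tuple[float, str]:
    """Maximum Tanimoto of the query to a reference set, with the argmax id."""
    if not references:
        raise ValueError("reference set must be non-empty")
    best_sim, best_id = -1.0, None
    for ident, fp in references:
        sim = tanimoto(query_fp, fp)
        if sim > best_sim:
            best_sim, best_id = sim, ident
    return best_sim, best_id


def run_screening(model: CPIModel, provider: EmbeddingProvider,
                  library: list[tuple[str, str]], sequence: str,
                  config: ScreeningConfig | None = None,
                  pains_catalog=None) -> ScreeningReport:
    """Full forward pipeline: score -> top fraction -> PAINS -> cluster ->
    Lipinski -> representatives."""
    config = config or ScreeningConfig()
    ranked = score_library(model, provider, library, sequence)
    counts = {"scored": len(ranked)}
    k = math.ceil(config.top_fraction * len(ranked))
    top = ranked.head(k).copy()
    counts["top_fraction"] = len(top)

    catalog = pains_catalog if pains_catalog is not None else load_pains_catalog()
    mols = {row.id: parse_molecule(row.smiles) for row in top.itertuples(index=False)}
    clean_ids = [i for i in top["id"] if not pains_filter(mols[i], catalog)[0]]
    counts["pains"] = len(clean_ids)

    fps = [fingerprint(mols[i], config.fingerprint_radius, config.fingerprint_width)
           for i in clean_ids]
    assignment = cluster_compounds(fps, config.cluster_cutoff) if clean_ids else np.array([], dtype=int)
    counts["clusters"] = int(assignment.max()) + 1 if len(assignment) else 0

    druglike = [i for i in clean_ids
                if lipinski_filter(mols[i], config.lipinski_max_violations)[0]]
    counts["lipinski"] = len(druglike)

    scores = dict(zip(ranked["id"], ranked["score"]))
    cluster_map = {i: int(c) for i, c in zip(clean_ids, assignment)}
    survivor_clusters = {i: cluster_map[i] for i in druglike}
    reps = select_representatives({i: scores[i] for i in druglike}, survivor_clusters,
                                  config.representatives_per_cluster) if druglike else []
    counts["representatives"] = len(reps)
    assert all(b <= a for a, b in zip(
        [counts["scored"], counts["top_fraction"], counts["pains"], counts["lipinski"]],
        [counts["top_fraction"], counts["pains"], counts["lipinski"], counts["representatives"]],
    )), "stage survivor counts must be non-increasing"
    return ScreeningReport(ranked=ranked, stage_counts=counts, clusters=cluster_map,
                           representatives=reps)


def rank_targets(model: CPIModel, provider: EmbeddingProvider, compound: str,
                 panel: list[tuple[str, str]], top_k: int = 20) -> pd.DataFrame:
    """Rank a protein panel against one compound by interaction probability.

    Returns the full ranking with a boolean ``in_top_k`` column; ties keep
    panel order.
    """
    if not panel:
        raise ValueError("panel must be non-empty")
    mol = parse_molecule(compound)
    graph = molecule_graph(mol)
    rows, scores = [], []
    for ident, seq in panel:
        emb = embed_protein(tokenize(seq), provider)
        scores.append(score_batch(model, [(graph, emb)])[0].probability)
        rows.append(ident)
    df = pd.DataFrame({"protein_id": rows, "score": scores})
    df = df.sort_values("score", ascending=False, kind="stable").reset_index(drop=True)
    df["in_top_k"] = df.index < top_k
    return df
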