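"""Molecular-graph featurization with a virtual readout atom.

Compounds enter as SMILES, are sanitized and reduced to their largest
covalent fragment, and leave as a 34-dimensional per-atom feature matrix
augmented with one *virtual atom*: an extra node initialized to the mean
feature vector of the real atoms and linked to every atom. The virtual
atom's representation downstream serves as the whole-molecule readout.

Feature schema (34 columns):
    element one-hot over {C,N,O,S,F,Cl,Br,I,P,B,Si,Se,other}   13
    heavy-atom degree one-hot 0..5                               6
    attached-hydrogen count one-hot 0..4                         5
    formal charge one-hot -2..+2                                 5
    aromatic flag                                                1
    in-ring flag                                                 1
    hybridization one-hot {sp, sp2, sp3}                         3
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

N_ATOM_FEATURES = 34
FEATURE_SCHEMA_VERSION = "ecf-34/1"

_ELEMENTS = ["C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "B", "Si", "Se"]
_HYBRID = {
    Chem.HybridizationType.SP: 0,
    Chem.HybridizationType.SP2: 1,
    Chem.HybridizationType.SP3: 2,
}


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed or sanitized."""


class FeaturizationError(ValueError):
    """Raised when an atom property falls outside the feature schema."""


@dataclass
class AtomInfo:
    element: str
    degree: int
    formal_charge: int
    aromatic: bool
    n_hydrogens: int
    in_ring: bool
    hybridization: str


@dataclass
class Molecule:
    """Sanitized largest-fragment compound with 0-based contiguous atoms."""

    atoms: list[AtomInfo]
    bonds: list[tuple[int, int]]
    source_smiles: str
    canonical_smiles: str
    _rdmol: Chem.Mol = field(repr=False, compare=False, default=None)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


@dataclass
class MoleculeGraph:
    """(n_atoms+1) x 34 features and self-looped adjacency; virtual atom last."""

    features: np.ndarray
    adjacency: np.ndarray
    virtual_index: int


def parse_molecule(smiles: str) -> Molecule:
    """Parse a SMILES string into a sanitized :class:`Molecule`.

    Salts/mixtures are reduced to the largest covalent fragment (by heavy
    atom count; canonical-SMILES tie break). Raises
    :class:`SmilesParseError` for unparsable input and ``ValueError`` for
    an empty string.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise ValueError("SMILES string must be non-empty")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparsable SMILES: {smiles!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) > 1:
        mol = max(frags, key=lambda f: (f.GetNumAtoms(), Chem.MolToSmiles(f)))
    canonical = Chem.MolToSmiles(mol)
    atoms = [
        AtomInfo(
            element=a.GetSymbol(),
            degree=a.GetDegree(),
            formal_charge=a.GetFormalCharge(),
            aromatic=a.GetIsAromatic(),
            n_hydrogens=a.GetTotalNumHs(),
            in_ring=a.IsInRing(),
            hybridization=str(a.GetHybridization()),
        )
        for a in mol.GetAtoms()
    ]
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
    return Molecule(atoms=atoms, bonds=bonds, source_smiles=smiles,
                    canonical_smiles=canonical, _rdmol=mol)


def _one_hot(index: int, width: int) -> np.ndarray:
    v = np.zeros(width)
    v[index] = 1.0
    return v


def atom_feature_matrix(mol: Molecule) -> np.ndarray:
    """Return the n_atoms x 34 binary feature matrix of a molecule."""
    if mol.n_atoms < 1:
        raise ValueError("molecule has no atoms")
    rows = []
    for i, atom in enumerate(mol.atoms):
        try:
            elem_idx = _ELEMENTS.index(atom.element)
        except ValueError:
            elem_idx = len(_ELEMENTS)  # "other"
        if not 0 <= atom.degree <= 5:
            raise FeaturizationError(f"atom {i} ({atom.element}): degree {atom.degree} out of range 0-5")
        if not 0 <= atom.n_hydrogens <= 4:
            raise FeaturizationError(f"atom {i} ({atom.element}): {atom.n_hydrogens} hydrogens out of range 0-4")
        if not -2 <= atom.formal_charge <= 2:
            raise FeaturizationError(f"atom {i} ({atom.element}): charge {atom.formal_charge} out of range -2..+2")
        hyb = np.zeros(3)
        hyb_idx = {"SP": 0, "SP2": 1, "SP3": 2}.get(atom.hybridization)
        if hyb_idx is not None:
            hyb[hyb_idx] = 1.0
        rows.append(np.concatenate([
            _one_hot(elem_idx, 13),
            _one_hot(atom.degree, 6),
            _one_hot(atom.n_hydrogens, 5),
            _one_hot(atom.formal_charge + 2, 5),
            [float(atom.aromatic)],
            [float(atom.in_ring)],
            hyb,
        ]))
    out = np.array(rows)
    assert out.shape == (mol.n_atoms, N_ATOM_FEATURES)
    return out


def add_virtual_atom(features: np.ndarray, bonds: list[tuple[int, int]]) -> MoleculeGraph:
    """Append the virtual atom (mean feature row, linked to all atoms).

    The adjacency contains every real bond (symmetric), every
    virtual-real edge, and a self-loop on each node.
    """
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2 or features.shape[0] < 1:
        raise ValueError("features must be a non-empty 2-D matrix")
    n = features.shape[0]
    full = np.vstack([features, features.mean(axis=0, keepdims=True)])
    adj = np.eye(n + 1)
    for i, j in bonds:
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"bond ({i}, {j}) references a missing atom")
        adj[i, j] = adj[j, i] = 1.0
    adj[n, :] = 1.0
    adj[:, n] = 1.0
    return MoleculeGraph(features=full, adjacency=adj, virtual_index=n)


def molecule_graph(mol: Molecule) -> MoleculeGraph:
    """Convenience: featurize and attach the virtual atom in one call."""
    return add_virtual_atom(atom_feature_matrix(mol), mol.bonds)


def graph_convolution(graph: MoleculeGraph, weights, n_layers: int = 1,
                      activation: str = "relu") -> np.ndarray:
    """Standalone graph convolution over a molecule graph.

    Each layer computes ``act(D^{-1/2} A D^{-1/2} H W + b)`` on the
    self-looped adjacency. ``weights`` is a sequence of ``(W, b)`` pairs
    (``b`` may be None), one per layer; layer 1 must map 34 -> d_model.
    One layer is the recommended depth; more than two over-smooths atom
    features and a warning is emitted.
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    if n_layers > 2:
        warnings.warn(
            f"{n_layers} graph-convolution layers requested; depths above 2 "
            "over-smooth atom features and degrade interaction learning",
            stacklevel=2,
        )
    if len(weights) != n_layers:
        raise ValueError(f"expected {n_layers} weight sets, got {len(weights)}")
    act = {"relu": lambda x: np.maximum(x, 0.0), "linear": lambda x: x}.get(activation)
    if act is None:
        raise ValueError(f"unknown activation {activation!r}")
    deg = graph.adjacency.sum(axis=1)
    norm = graph.adjacency * (deg**-0.5)[:, None] * (deg**-0.5)[None, :]
    h = graph.features
    for layer, wb in enumerate(weights):
        W, b = wb if isinstance(wb, tuple) else (wb, None)
        W = np.asarray(W, dtype=np.float64)
        if W.shape[0] != h.shape[1]:
            raise ValueError(
                f"layer {layer}: weight input dim {W.shape[0]} does not match features {h.shape[1]}"
            )
        h = norm @ h @ W
        if b is not None:
            h = h + np.asarray(b, dtype=np.float64)
        h = act(h)
    return h


# ---------------------------------------------------------------------- I/O

def read_smiles_file(path) -> list[tuple[str, str]]:
    """Read a .smi file: one SMILES per line, optional tab-separated id."""
    entries = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            smiles = parts[0].strip()
            ident = parts[1].strip() if len(parts) > 1 else f"mol{lineno}"
            entries.append((ident, smiles))
    return entries


def read_smiles_csv(path, column: str, id_column: str | None = None) -> list[tuple[str, str]]:
    import pandas as pd

    df = pd.read_csv(path)
    if column not in df.columns:
        raise KeyError(f"column {column!r} not found in {path}")
    ids = df[id_column].astype(str) if id_column else [f"mol{i}" for i in range(len(df))]
    return list(zip(ids, df[column].astype(str)))


def write_canonical_smiles_tsv(entries: list[tuple[str, str]], path) -> None:
    """Write (id, canonical_smiles, n_atoms) rows; unparsable entries skipped."""
    with open(path, "w") as fh:
        fh.write("id\tcanonical_smiles\tn_atoms\n")
        for ident, smiles in entries:
            try:
                mol = parse_molecule(smiles)
            except (ValueError, SmilesParseError):
                warnings.warn(f"skipping unparsable SMILES for {ident}", stacklevel=2)
                continue
            fh.write(f"{ident}\t{mol.canonical_smiles}\t{mol.n_atoms}\n")
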