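"""SMILES ingestion, canonicalization, graph featurization and descriptors.

Molecules are represented as heavy-atom graphs (hydrogens implicit) with the
canonical 74-dimensional atom / 12-dimensional bond feature layout used by
mainstream molecular message-passing toolkits:

atom (74) = element one-hot (43) + degree one-hot (0..10, 11)
          + implicit valence one-hot (0..6, 7) + formal charge (1)
          + radical electrons (1) + hybridization one-hot (SP..SP3D2, 5)
          + aromaticity (1) + total-H-count one-hot (0..4, 5)

bond (12) = bond-type one-hot (single/double/triple/aromatic, 4)
          + conjugation (1) + ring membership (1) + stereo one-hot (6)

Out-of-vocabulary elements fall into the final element slot; one-hot segments
with no matching category encode as all-zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

FEATURIZER_VERSION = "mpff-canonical-74x12/1"

ATOM_FEATURE_DIM = 74
BOND_FEATURE_DIM = 12

# canonical 43-element vocabulary; the last slot doubles as "unknown"
_ELEMENTS = [
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg", "Na", "Ca", "Fe",
    "As", "Al", "I", "B", "V", "K", "Tl", "Yb", "Sb", "Sn", "Ag", "Pd", "Co",
    "Se", "Ti", "Zn", "H", "Li", "Ge", "Cu", "Au", "Ni", "Cd", "In", "Mn",
    "Zr", "Cr", "Pt", "Hg", "Pb",
]
_ELEMENT_INDEX = {s: i for i, s in enumerate(_ELEMENTS)}

_HYBRIDIZATIONS = [
    Chem.rdchem.HybridizationType.SP,
    Chem.rdchem.HybridizationType.SP2,
    Chem.rdchem.HybridizationType.SP3,
    Chem.rdchem.HybridizationType.SP3D,
    Chem.rdchem.HybridizationType.SP3D2,
]

_BOND_TYPES = [
    Chem.rdchem.BondType.SINGLE,
    Chem.rdchem.BondType.DOUBLE,
    Chem.rdchem.BondType.TRIPLE,
    Chem.rdchem.BondType.AROMATIC,
]

_STEREO = [
    Chem.rdchem.BondStereo.STEREONONE,
    Chem.rdchem.BondStereo.STEREOANY,
    Chem.rdchem.BondStereo.STEREOZ,
    Chem.rdchem.BondStereo.STEREOE,
    Chem.rdchem.BondStereo.STEREOCIS,
    Chem.rdchem.BondStereo.STEREOTRANS,
]


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


@dataclass
class MoleculeRecord:
    id: str
    smiles: str
    canonical_smiles: str = ""
    ic50_nM: Optional[float] = None
    label: Optional[int] = None
    source: Optional[str] = None

    def __post_init__(self):
        if not self.canonical_smiles:
            self.canonical_smiles = canonicalize_smiles(self.smiles)
        if self.ic50_nM is not None and not self.ic50_nM > 0:
            raise ValueError(f"ic50_nM must be positive, got {self.ic50_nM!r} for {self.id}")


@dataclass
class MolecularGraph:
    num_atoms: int
    atom_features: np.ndarray          # (num_atoms, 74)
    edges: np.ndarray                  # (2m, 2) directed pairs, both directions per bond
    bond_features: np.ndarray          # (2m, 12), aligned with `edges`
    adjacency: np.ndarray              # (num_atoms, num_atoms) binary symmetric
    edge_group_cache: Optional[list] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        assert self.atom_features.shape == (self.num_atoms, ATOM_FEATURE_DIM)
        assert self.bond_features.shape == (len(self.edges), BOND_FEATURE_DIM)


@dataclass
class BatchedGraph:
    """Block-diagonal disjoint union of molecular graphs."""
    num_atoms: int
    atom_features: np.ndarray
    edges: np.ndarray
    bond_features: np.ndarray
    graph_ids: np.ndarray              # (num_atoms,) membership vector
    atom_offsets: np.ndarray           # (n_graphs + 1,) prefix sums
    num_graphs: int
    edge_group_cache: Optional[list] = field(default=None, repr=False, compare=False)

    def atom_slice(self, g: int) -> slice:
        return slice(int(self.atom_offsets[g]), int(self.atom_offsets[g + 1]))


@dataclass
class DescriptorSet:
    mw: float
    logp: float
    hbd: int
    hba: int


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    if not smiles or not isinstance(smiles, str):
        raise SmilesParseError(f"empty or non-string SMILES: {smiles!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparsable SMILES: {smiles!r}")
    return mol


def canonicalize_smiles(smiles: str) -> str:
    """Canonical SMILES (RDKit canonical writer, isomeric). Idempotent."""
    return Chem.MolToSmiles(_mol_from_smiles(smiles))


def _one_hot(value, choices, vec, offset, unknown_last: bool = False) -> None:
    try:
        idx = choices.index(value) if isinstance(choices, list) else choices[value]
    except (ValueError, KeyError):
        if unknown_last:
            idx = len(choices) - 1
        else:
            return
    vec[offset + idx] = 1.0


def atom_feature_vector(atom: Chem.Atom) -> np.ndarray:
    v = np.zeros(ATOM_FEATURE_DIM)
    sym = atom.GetSymbol()
    v[_ELEMENT_INDEX.get(sym, len(_ELEMENTS) - 1)] = 1.0
    off = 43
    deg = atom.GetDegree()
    if deg <= 10:
        v[off + deg] = 1.0
    off += 11
    val = atom.GetImplicitValence()
    if val <= 6:
        v[off + val] = 1.0
    off += 7
    v[off] = atom.GetFormalCharge()
    v[off + 1] = atom.GetNumRadicalElectrons()
    off += 2
    _one_hot(atom.GetHybridization(), _HYBRIDIZATIONS, v, off)
    off += 5
    v[off] = 1.0 if atom.GetIsAromatic() else 0.0
    off += 1
    nh = atom.GetTotalNumHs()
    if nh <= 4:
        v[off + nh] = 1.0
    return v


def bond_feature_vector(bond: Chem.Bond) -> np.ndarray:
    v = np.zeros(BOND_FEATURE_DIM)
    _one_hot(bond.GetBondType(), _BOND_TYPES, v, 0)
    v[4] = 1.0 if bond.GetIsConjugated() else 0.0
    v[5] = 1.0 if bond.IsInRing() else 0.0
    _one_hot(bond.GetStereo(), _STEREO, v, 6)
    return v


def featurize_molecule(smiles: str) -> MolecularGraph:
    """Heavy-atom graph with 74-d atom and 12-d bond features."""
    mol = _mol_from_smiles(smiles)
    n = mol.GetNumAtoms()
    if n < 1:
        raise SmilesParseError(f"no heavy atoms in SMILES: {smiles!r}")
    atom_feats = np.stack([atom_feature_vector(a) for a in mol.GetAtoms()])
    edges, bond_feats = [], []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        bf = bond_feature_vector(bond)
        edges.append((i, j))
        bond_feats.append(bf)
        edges.append((j, i))
        bond_feats.append(bf)
    edges_arr = np.array(edges, dtype=np.intp).reshape(-1, 2)
    bond_arr = (np.stack(bond_feats) if bond_feats
                else np.zeros((0, BOND_FEATURE_DIM)))
    adj = np.zeros((n, n))
    for i, j in edges_arr:
        adj[i, j] = 1.0
    return MolecularGraph(n, atom_feats, edges_arr, bond_arr, adj)


def compute_descriptors(smiles: str) -> DescriptorSet:
    """Average-isotope MW, Crippen LogP, Lipinski HBD/HBA counts."""
    mol = _mol_from_smiles(smiles)
    return DescriptorSet(
        mw=Descriptors.MolWt(mol),
        logp=Crippen.MolLogP(mol),
        hbd=Lipinski.NumHDonors(mol),
        hba=Lipinski.NumHAcceptors(mol),
    )


def batch_graphs(graphs: Sequence[MolecularGraph]) -> BatchedGraph:
    """Disjoint union with per-graph atom-index offsets (block-diagonal)."""
    if len(graphs) == 0:
        raise ValueError("cannot batch an empty list of graphs")
    offsets = np.concatenate([[0], np.cumsum([g.num_atoms for g in graphs])])
    atom_feats = np.concatenate([g.atom_features for g in graphs])
    edges = np.concatenate(
        [g.edges + offsets[i] for i, g in enumerate(graphs)]
    ).reshape(-1, 2)
    bond_feats = np.concatenate([g.bond_features for g in graphs])
    graph_ids = np.concatenate(
        [np.full(g.num_atoms, i, dtype=np.intp) for i, g in enumerate(graphs)]
    )
    return BatchedGraph(
        num_atoms=int(offsets[-1]),
        atom_features=atom_feats,
        edges=edges.astype(np.intp),
        bond_features=bond_feats,
        graph_ids=graph_ids,
        atom_offsets=offsets.astype(np.intp),
        num_graphs=len(graphs),
    )


# -- tabular I/O ---------------------------------------------------------------

def read_molecule_table(path, *, source: Optional[str] = None) -> list[MoleculeRecord]:
    """Read a CSV/TSV with a required `smiles` column into molecule records.

    Optional columns: `id`, `ic50_nM`, `label`. Unparsable SMILES raise.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    if "smiles" not in df.columns:
        raise ValueError(f"{path}: required column 'smiles' missing")
    records = []
    for i, row in df.iterrows():
        rec = MoleculeRecord(
            id=str(row["id"]) if "id" in df.columns else f"mol{i}",
            smiles=str(row["smiles"]),
            ic50_nM=float(row["ic50_nM"]) if "ic50_nM" in df.columns and pd.notna(row["ic50_nM"]) else None,
            label=int(row["label"]) if "label" in df.columns and pd.notna(row["label"]) else None,
            source=source,
        )
        records.append(rec)
    return records


def save_graph_cache(graphs: dict[str, MolecularGraph], path) -> None:
    """Serialize graphs keyed by canonical SMILES (npz + JSON sidecar)."""
    path = Path(path)
    arrays, index = {}, {}
    for k, (smi, g) in enumerate(graphs.items()):
        arrays[f"g{k}_atoms"] = g.atom_features
        arrays[f"g{k}_edges"] = g.edges
        arrays[f"g{k}_bonds"] = g.bond_features
        index[smi] = k
    np.savez(path, **arrays)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"featurizer_version": FEATURIZER_VERSION, "index": index}))


def load_graph_cache(path) -> dict[str, MolecularGraph]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    if sidecar["featurizer_version"] != FEATURIZER_VERSION:
        raise ValueError(
            f"graph cache featurizer version {sidecar['featurizer_version']!r} "
            f"!= current {FEATURIZER_VERSION!r}"
        )
    data = np.load(path)
    out = {}
    for smi, k in sidecar["index"].items():
        atoms = data[f"g{k}_atoms"]
        edges = data[f"g{k}_edges"].astype(np.intp).reshape(-1, 2)
        bonds = data[f"g{k}_bonds"]
        n = atoms.shape[0]
        adj = np.zeros((n, n))
        for i, j in edges:
            adj[i, j] = 1.0
        out[smi] = MolecularGraph(n, atoms, edges, bonds, adj)
    return out
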