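"""Seeded synthetic fixtures: molecule libraries, activity datasets, proteins.

The generators build valid molecules by decorating ring scaffolds drawn from
a combinatorial pool (single rings and linker-joined ring pairs) with small
acyclic substituents.  Activity is governed by a pharmacophore rule rather
than random labels: a molecule is active against the default target iff it
carries the pharmacophore substituent (default: a trifluoromethyl group,
which no other building block contains, so substructure presence is
unambiguous and representable by a graph encoder).  IC50 values are drawn
log-normally on the correct side of the 6.1 nM activity threshold, so
threshold labeling reproduces the generated labels exactly.

These fixtures emulate the *shape* of a bioactivity-database extract
(SMILES, IC50 in nM, binary label, scaffold diversity); they do not emulate
real medicinal-chemistry property distributions, assay noise, or activity
cliffs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from rdkit import Chem

from .data_pipeline import ActivityRecord, IC50_THRESHOLD_NM
from .mol_graph import MoleculeRecord, canonicalize_smiles
from .protein_repr import AA_ALPHABET, ProteinSequence

DEFAULT_PHARMACOPHORE = "C(F)(F)F"

_BASE_RINGS = [
    "c1ccccc1", "C1CCCCC1", "c1ccncc1", "C1CCNCC1", "c1ccsc1", "c1ccoc1",
    "c1cc[nH]c1", "C1CCOC1", "C1CCCC1", "C1CCNC1", "c1cncnc1", "C1CCOCC1",
]
_LINKERS = ["", "C", "CC", "O", "N", "CO", "CN", "S"]
# substituents are fluorine-free so the default pharmacophore never occurs
# by accident on a negative molecule
_SUBSTITUENTS = ["C", "CC", "O", "N", "OC", "C(C)C", "C(=O)C", "C#N", "CO", "CN", "Cl", "Br"]


@dataclass
class SyntheticSpec:
    n_molecules: int = 1000
    seed: int = 0
    scaffold_pool_size: int = 100
    positive_rate: float = 0.4
    pharmacophore: str = DEFAULT_PHARMACOPHORE
    ic50_lognormal: tuple = (0.0, 2.7, 0.5)   # (mu_pos, mu_neg, sigma) in log10 nM
    label_flip_rate: float = 0.0
    target_id: str = "T1"

    def __post_init__(self):
        if not 0.0 < self.positive_rate < 1.0:
            raise ValueError("positive_rate must lie in (0, 1)")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be positive")


def _attach(mol: Chem.Mol, frag_smiles: str, atom_idx: int) -> Optional[Chem.Mol]:
    """Bond the first atom of `frag_smiles` to `atom_idx` of `mol` (single bond)."""
    frag = Chem.MolFromSmiles(frag_smiles)
    combo = Chem.RWMol(Chem.CombineMols(mol, frag))
    combo.AddBond(atom_idx, mol.GetNumAtoms(), Chem.BondType.SINGLE)
    try:
        out = combo.GetMol()
        Chem.SanitizeMol(out)
        return out
    except Exception:
        return None


def _open_sites(mol: Chem.Mol) -> list[int]:
    return [a.GetIdx() for a in mol.GetAtoms() if a.GetTotalNumHs() > 0]


def build_scaffold_pool(size: int, seed: int) -> list[str]:
    """Deterministic pool of canonical scaffold SMILES (single rings and
    linker-joined ring pairs), seeded subsample of the combinatorial space."""
    pool: list[str] = []
    seen = set()

    def add(mol):
        if mol is None:
            return
        smi = Chem.MolToSmiles(mol)
        if smi not in seen:
            seen.add(smi)
            pool.append(smi)

    for r in _BASE_RINGS:
        add(Chem.MolFromSmiles(r))
    for r1 in _BASE_RINGS:
        for r2 in _BASE_RINGS:
            for link in _LINKERS:
                m1 = Chem.MolFromSmiles(r1)
                sites1 = _open_sites(m1)
                if not sites1:
                    continue
                if link == "":
                    joined = _attach(m1, r2, sites1[0])
                else:
                    with_link = _attach(m1, link, sites1[0])
                    if with_link is None:
                        continue
                    # attach the second ring to the end of the linker chain
                    tail = with_link.GetNumAtoms() - 1
                    joined = _attach(with_link, r2, tail)
                add(joined)
    if size > len(pool):
        raise ValueError(
            f"scaffold_pool_size {size} exceeds combinatorial space ({len(pool)})"
        )
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(pool))[:size]
    return [pool[i] for i in sorted(idx)]


def _decorate(scaffold_smiles: str, rng: np.random.Generator,
              with_pharmacophore: bool, pharmacophore: str) -> str:
    for _ in range(50):
        mol = Chem.MolFromSmiles(scaffold_smiles)
        ok = True
        for _ in range(int(rng.integers(1, 4))):
            sites = _open_sites(mol)
            if not sites:
                break
            sub = _SUBSTITUENTS[int(rng.integers(0, len(_SUBSTITUENTS)))]
            new = _attach(mol, sub, int(rng.choice(sites)))
            if new is not None:
                mol = new
        if with_pharmacophore:
            sites = _open_sites(mol)
            if not sites:
                ok = False
            else:
                new = _attach(mol, pharmacophore, int(rng.choice(sites)))
                if new is None:
                    ok = False
                else:
                    mol = new
        if ok:
            return Chem.MolToSmiles(mol)
    raise RuntimeError(f"could not decorate scaffold {scaffold_smiles!r}")


def generate_library(spec: SyntheticSpec) -> list[MoleculeRecord]:
    """Seeded molecule library with ≥ `scaffold_pool_size` distinct Murcko scaffolds.

    The first `scaffold_pool_size` molecules cycle through the pool so every
    scaffold is represented; the rest draw scaffolds at random.
    """
    if spec.n_molecules < spec.scaffold_pool_size:
        raise ValueError("n_molecules must be ≥ scaffold_pool_size")
    pool = build_scaffold_pool(spec.scaffold_pool_size, spec.seed)
    rng = np.random.default_rng(spec.seed + 1)
    pharm = Chem.MolFromSmiles(spec.pharmacophore)
    if pharm is None:
        raise ValueError(f"invalid pharmacophore {spec.pharmacophore!r}")
    records = []
    for i in range(spec.n_molecules):
        scaffold = pool[i % len(pool)] if i < len(pool) else pool[int(rng.integers(0, len(pool)))]
        positive = bool(rng.random() < spec.positive_rate)
        smi = _decorate(scaffold, rng, positive, spec.pharmacophore)
        records.append(MoleculeRecord(id=f"syn{i}", smiles=smi, source="synthetic"))
    return records


def _draw_ic50(label: int, rng: np.random.Generator, params: tuple) -> float:
    mu_pos, mu_neg, sigma = params
    mu = mu_pos if label == 1 else mu_neg
    val = 10.0 ** rng.normal(mu, sigma)
    # enforce threshold sidedness by construction
    if label == 1:
        return min(val, IC50_THRESHOLD_NM)
    return max(val, IC50_THRESHOLD_NM * 1.01)


def generate_activity_dataset(spec: SyntheticSpec) -> list[ActivityRecord]:
    """Pharmacophore-labeled activity records with side-consistent IC50 draws."""
    library = generate_library(spec)
    rng = np.random.default_rng(spec.seed + 2)
    pharm = Chem.MolFromSmiles(spec.pharmacophore)
    out = []
    for rec in library:
        mol = Chem.MolFromSmiles(rec.canonical_smiles)
        label = int(mol.HasSubstructMatch(pharm))
        if spec.label_flip_rate > 0 and rng.random() < spec.label_flip_rate:
            label = 1 - label
        out.append(
            ActivityRecord(
                id=rec.id,
                smiles=rec.smiles,
                canonical_smiles=rec.canonical_smiles,
                ic50_nM=_draw_ic50(label, rng, spec.ic50_lognormal),
                label=label,
                source="synthetic",
                target_id=spec.target_id,
            )
        )
    return out


def generate_protein(length: int, seed: int, id: str = "synthetic_target") -> ProteinSequence:
    """Uniform random sequence over the 20 standard residues."""
    if length < 1:
        raise ValueError("length must be ≥ 1")
    rng = np.random.default_rng(seed)
    residues = "".join(AA_ALPHABET[i] for i in rng.integers(0, 20, size=length))
    return ProteinSequence(id=id, residues=residues)


def generate_interaction_dataset(
    n: int,
    seed: int,
    protein_length: int = 48,
    pharmacophore: str = DEFAULT_PHARMACOPHORE,
    scaffold_pool_size: int = 60,
) -> tuple[list[ActivityRecord], dict[str, ProteinSequence]]:
    """Two-target task with opposite activity rules.

    Against target TA a molecule is active iff it carries the pharmacophore;
    against target TB iff it does not.  The compound alone carries no signal
    marginally over targets — only the protein-compound pairing does — so
    any model that solves the task must combine the two entities.
    """
    spec = SyntheticSpec(
        n_molecules=n, seed=seed, scaffold_pool_size=scaffold_pool_size,
        positive_rate=0.5, pharmacophore=pharmacophore,
    )
    library = generate_library(spec)
    rng = np.random.default_rng(seed + 3)
    pharm = Chem.MolFromSmiles(pharmacophore)
    records = []
    for i, rec in enumerate(library):
        mol = Chem.MolFromSmiles(rec.canonical_smiles)
        has = int(mol.HasSubstructMatch(pharm))
        target = "TA" if i % 2 == 0 else "TB"
        label = has if target == "TA" else 1 - has
        records.append(
            ActivityRecord(
                id=rec.id,
                smiles=rec.smiles,
                canonical_smiles=rec.canonical_smiles,
                ic50_nM=_draw_ic50(label, rng, spec.ic50_lognormal),
                label=label,
                source="synthetic",
                target_id=target,
            )
        )
    proteins = {
        "TA": generate_protein(protein_length, seed + 10, id="TA"),
        "TB": generate_protein(protein_length, seed + 11, id="TB"),
    }
    return records, proteins


def anagram_targets(length: int, seed: int, n_letters: int = 4) -> tuple[ProteinSequence, ProteinSequence]:
    """Diagnostic target pair with identical residue composition but opposite
    local structure: TA interleaves `n_letters` residue types, TB arranges
    the same multiset in homogeneous blocks.  Any composition-only summary
    (e.g. mean pooling of residue-wise features) is bitwise identical for
    the two, so they isolate whether a protein representation carries
    sequence order; local, order-sensitive features (trigrams, convolutions)
    differ maximally."""
    rng = np.random.default_rng(seed)
    letters = [AA_ALPHABET[i] for i in rng.choice(20, size=n_letters, replace=False)]
    a = "".join(letters[i % n_letters] for i in range(length))
    counts = [a.count(ch) for ch in letters]
    b = "".join(ch * c for ch, c in zip(letters, counts))
    return ProteinSequence(id="TA", residues=a), ProteinSequence(id="TB", residues=b)


# pairwise-distinct pharmacophore substituents, disjoint from the decoy
# substituent pool and from every scaffold, so substructure matches are
# unambiguous (first SMILES atom is the attachment point)
PAIRING_PHARMACOPHORES = [
    "C(F)(F)F",        # trifluoromethyl
    "S(=O)(=O)C",      # methylsulfonyl
    "I",               # iodo
    "C#C",             # terminal alkyne
    "[N+](=O)[O-]",    # nitro
    "C=S",             # thiocarbonyl
]


def generate_pairing_dataset(
    n: int,
    seed: int,
    n_targets: int = 6,
    protein_length: int = 48,
    scaffold_pool_size: int = 60,
) -> tuple[list[ActivityRecord], dict[str, ProteinSequence]]:
    """Many-way protein-pharmacophore matching task.

    Every molecule carries exactly one of `n_targets` distinctive
    pharmacophore groups; a (molecule, target) pair is active iff the
    pharmacophore index matches the target index.  Pairings are balanced so
    half the records are matches.  A pooled concatenation of the two entities
    must learn the full T×T pairing table in its head, whereas the bilinear
    association can express matching directly — this is the regime meant to
    separate cross-coupled fusion from the "cat" baseline.
    """
    if not 2 <= n_targets <= len(PAIRING_PHARMACOPHORES):
        raise ValueError(f"n_targets must be in [2, {len(PAIRING_PHARMACOPHORES)}]")
    pool = build_scaffold_pool(scaffold_pool_size, seed)
    rng = np.random.default_rng(seed + 4)
    pharms = PAIRING_PHARMACOPHORES[:n_targets]
    records = []
    sigma_params = SyntheticSpec().ic50_lognormal
    for i in range(n):
        scaffold = pool[i % len(pool)] if i < len(pool) else pool[int(rng.integers(0, len(pool)))]
        k = int(rng.integers(0, n_targets))
        smi = _decorate(scaffold, rng, True, pharms[k])
        if rng.random() < 0.5:
            t = k
        else:
            t = int(rng.integers(0, n_targets - 1))
            if t >= k:
                t += 1
        label = int(t == k)
        records.append(
            ActivityRecord(
                id=f"pair{i}",
                smiles=smi,
                ic50_nM=_draw_ic50(label, rng, sigma_params),
                label=label,
                source="synthetic",
                target_id=f"T{t}",
            )
        )
    proteins = {
        f"T{t}": generate_protein(protein_length, seed + 20 + t, id=f"T{t}")
        for t in range(n_targets)
    }
    return records, proteins
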