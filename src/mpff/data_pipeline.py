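"""Dataset construction: activity labeling, deduplication, scaffold splitting
and physicochemical library filtering.

The pipeline mirrors standard practice for building target-specific activity
datasets from bioactivity databases:

* records are labeled active when IC50 ≤ 6.1 nM (the activity level of a
  reference clinical-stage inhibitor of the target); the boundary value is
  called active;
* duplicates are collapsed per (canonical SMILES, target) by the median IC50
  and relabeled;
* train/validation/test splitting assigns whole Bemis-Murcko scaffold groups
  greedily so that no scaffold straddles subsets, targeting an 8:1:1 size
  split while keeping each subset's positive rate close to the global rate;
* screening libraries are filtered to the physicochemical windows typical of
  inhibitors of this target class (MW 550-1500 Da, LogP 4-8, HBD 1-4,
  HBA 7-13, all inclusive) and deduplicated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .mol_graph import MoleculeRecord, SmilesParseError, canonicalize_smiles, compute_descriptors

IC50_THRESHOLD_NM = 6.1
DEFAULT_FRACTIONS = (0.8, 0.1, 0.1)
SUBSETS = ("train", "val", "test")


@dataclass
class ActivityRecord(MoleculeRecord):
    target_id: str = "target"


@dataclass
class FilterCriteria:
    mw: tuple = (550.0, 1500.0)
    logp: tuple = (4.0, 8.0)
    hbd: tuple = (1, 4)
    hba: tuple = (7, 13)

    def __post_init__(self):
        for name in ("mw", "logp", "hbd", "hba"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"criterion {name}: lower bound {lo} > upper bound {hi}")


@dataclass
class SplitAssignment:
    assignment: dict                  # canonical_smiles -> subset
    scaffold_subsets: dict            # scaffold -> subset
    size_fractions: dict              # subset -> fraction of records
    positive_fractions: dict          # subset -> positive-label rate
    global_positive_fraction: float
    warnings: list = field(default_factory=list)

    def report_json(self) -> str:
        return json.dumps(
            {
                "size_fractions": self.size_fractions,
                "positive_fractions": self.positive_fractions,
                "global_positive_fraction": self.global_positive_fraction,
                "n_scaffolds": len(self.scaffold_subsets),
                "warnings": self.warnings,
            }
        )


def label_by_ic50(
    records: list, threshold_nM: float = IC50_THRESHOLD_NM
) -> tuple[list, list]:
    """Label active iff IC50 ≤ threshold (boundary counts as active).

    Returns (labeled records, rejected (record, reason) pairs); records with
    missing or non-positive IC50 are rejected.
    """
    labeled, rejected = [], []
    for rec in records:
        if rec.ic50_nM is None:
            rejected.append((rec, "missing ic50"))
            continue
        if not rec.ic50_nM > 0:
            rejected.append((rec, "non-positive ic50"))
            continue
        labeled.append(replace(rec, label=int(rec.ic50_nM <= threshold_nM)))
    return labeled, rejected


def deduplicate(
    records: list, threshold_nM: float = IC50_THRESHOLD_NM, strict: bool = False
) -> tuple[list, int]:
    """One record per (canonical SMILES, target); duplicates collapse by
    median IC50 and are relabeled.  In strict mode, groups whose members
    disagree on the label are dropped instead.  Returns (survivors, n collapsed)."""
    groups: dict[tuple, list] = {}
    order: list[tuple] = []
    for rec in records:
        key = (rec.canonical_smiles, getattr(rec, "target_id", None))
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(rec)
    survivors, collapsed = [], 0
    for key in order:
        group = groups[key]
        if len(group) == 1:
            survivors.append(group[0])
            continue
        collapsed += len(group) - 1
        labels = {g.label for g in group if g.label is not None}
        if strict and len(labels) > 1:
            continue
        ic50s = [g.ic50_nM for g in group if g.ic50_nM is not None]
        rep = group[0]
        if ic50s:
            med = float(np.median(ic50s))
            rep = replace(rep, ic50_nM=med, label=int(med <= threshold_nM))
        survivors.append(rep)
    return survivors, collapsed


def murcko_scaffold(smiles: str) -> str:
    """Canonical Bemis-Murcko scaffold; acyclic molecules yield ''."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparsable SMILES: {smiles!r}")
    return MurckoScaffold.MurckoScaffoldSmiles(mol=mol)


def scaffold_split(
    records: list,
    fractions: tuple = DEFAULT_FRACTIONS,
    seed: int = 0,
    lam: float = 1.0,
    split_acyclic_singletons: bool = False,
) -> SplitAssignment:
    """Constrained greedy assignment of whole scaffold groups to train/val/test.

    Groups are visited in decreasing size (ties by scaffold string) and each
    is placed in the subset minimizing the global squared deviation of subset
    size fractions from `fractions` plus `lam` times the size-weighted squared
    deviation of per-subset positive rates from the global rate.  The split is
    deterministic; `seed` is accepted for interface stability.  Compounds
    (not compound-target pairs) are the unit of assignment, so a compound
    never straddles subsets even across targets.
    """
    if abs(sum(fractions) - 1.0) > 1e-9 or len(fractions) != 3:
        raise ValueError("fractions must be three values summing to 1")
    by_smiles: dict[str, list] = {}
    for rec in records:
        by_smiles.setdefault(rec.canonical_smiles, []).append(rec)
    groups: dict[str, list] = {}
    for smi, recs in by_smiles.items():
        scaf = murcko_scaffold(smi)
        if scaf == "" and split_acyclic_singletons:
            scaf = f"__acyclic__{smi}"
        groups.setdefault(scaf, []).append(smi)

    warnings = []
    if len(groups) < 3:
        warnings.append(
            f"only {len(groups)} scaffold group(s); some subsets will be empty"
        )

    n_total = len(records)
    pos_total = sum(1 for r in records if r.label == 1)
    global_rate = pos_total / n_total if n_total else 0.0

    def group_stats(smis):
        n = sum(len(by_smiles[s]) for s in smis)
        p = sum(1 for s in smis for r in by_smiles[s] if r.label == 1)
        return n, p

    ordered = sorted(groups.items(), key=lambda kv: (-group_stats(kv[1])[0], kv[0]))
    sizes = np.zeros(3)
    positives = np.zeros(3)
    scaffold_subsets: dict[str, str] = {}
    assignment: dict[str, str] = {}
    targets = np.asarray(fractions, dtype=np.float64)

    for scaf, smis in ordered:
        gn, gp = group_stats(smis)
        best_s, best_cost = 0, np.inf
        for s in range(3):
            trial_sizes = sizes.copy()
            trial_pos = positives.copy()
            trial_sizes[s] += gn
            trial_pos[s] += gp
            size_dev = np.sum((trial_sizes / n_total - targets) ** 2)
            # deviation of each subset's positive mass from expectation, in
            # the same count-fraction units as the size term
            label_dev = np.sum(((trial_pos - global_rate * trial_sizes) / n_total) ** 2)
            cost = size_dev + lam * label_dev
            if cost < best_cost - 1e-12:
                best_cost, best_s = cost, s
        sizes[best_s] += gn
        positives[best_s] += gp
        scaffold_subsets[scaf] = SUBSETS[best_s]
        for smi in smis:
            assignment[smi] = SUBSETS[best_s]

    return SplitAssignment(
        assignment=assignment,
        scaffold_subsets=scaffold_subsets,
        size_fractions={SUBSETS[s]: float(sizes[s] / n_total) for s in range(3)},
        positive_fractions={
            SUBSETS[s]: float(positives[s] / sizes[s]) if sizes[s] else 0.0
            for s in range(3)
        },
        global_positive_fraction=global_rate,
        warnings=warnings,
    )


def split_records(records: list, split: SplitAssignment) -> dict[str, list]:
    out = {s: [] for s in SUBSETS}
    for rec in records:
        out[split.assignment[rec.canonical_smiles]].append(rec)
    return out


def filter_library(
    records: list, criteria: FilterCriteria = FilterCriteria()
) -> tuple[list, list]:
    """Inclusive four-window physicochemical filter, then canonical-SMILES dedup.

    Returns (survivors, rejection log of (id, reason)); the first failing
    criterion is recorded per molecule, and unparsable SMILES are logged
    rather than fatal.
    """
    survivors, log = [], []
    seen = set()
    for rec in records:
        try:
            d = compute_descriptors(rec.smiles)
        except SmilesParseError:
            log.append((rec.id, "parse_error"))
            continue
        reason = None
        for name, value in (("mw", d.mw), ("logp", d.logp), ("hbd", d.hbd), ("hba", d.hba)):
            lo, hi = getattr(criteria, name)
            if not lo <= value <= hi:
                reason = name
                break
        if reason is not None:
            log.append((rec.id, reason))
            continue
        if rec.canonical_smiles in seen:
            log.append((rec.id, "duplicate"))
            continue
        seen.add(rec.canonical_smiles)
        survivors.append(rec)
    return survivors, log


# -- tabular I/O ---------------------------------------------------------------

def records_to_frame(records: list, split: Optional[SplitAssignment] = None) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "smiles": r.smiles,
                "canonical_smiles": r.canonical_smiles,
                "target_id": getattr(r, "target_id", ""),
                "ic50_nM": r.ic50_nM,
                "label": r.label,
                "split": split.assignment.get(r.canonical_smiles) if split else None,
            }
        )
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> list:
    records = []
    for i, row in df.iterrows():
        records.append(
            ActivityRecord(
                id=str(row.get("id", f"mol{i}")),
                smiles=str(row["smiles"]),
                canonical_smiles=str(row["canonical_smiles"]) if pd.notna(row.get("canonical_smiles")) and row.get("canonical_smiles") else "",
                ic50_nM=float(row["ic50_nM"]) if pd.notna(row.get("ic50_nM")) else None,
                label=int(row["label"]) if pd.notna(row.get("label")) else None,
                target_id=str(row.get("target_id") or "target"),
            )
        )
    return records
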