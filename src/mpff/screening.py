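"""Model-based virtual screening of a compound library against one target.

Every featurizable molecule receives an inference-mode activity probability;
results are ranked by probability (ties broken by id) and candidates are the
molecules whose probability strictly exceeds the confidence threshold.  The
0.5 default is the classification cut; stricter cuts (0.9, 0.99) trade
recall for reliability, and counts at all three are reported so the choice
is explicit.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .model import ActivityModel
from .mol_graph import MoleculeRecord, SmilesParseError, featurize_molecule
from .protein_repr import ResidueEmbedding
from .training import PreparedDataset, predict_scores

REPORT_THRESHOLDS = (0.5, 0.9, 0.99)


@dataclass
class ScreeningResult:
    ranked: list                      # (id, canonical_smiles, probability, label)
    threshold: float
    n_screened: int
    n_predicted_active: int           # probability > 0.5
    n_above_threshold: int
    threshold_counts: dict = field(default_factory=dict)
    skipped: list = field(default_factory=list)   # (id, reason)

    @property
    def candidates(self) -> list:
        return [r for r in self.ranked if r[2] > self.threshold]


def screen_library(
    model: ActivityModel,
    embedding: ResidueEmbedding,
    molecules: Sequence[MoleculeRecord],
    confidence_threshold: float = 0.5,
    batch_size: int = 64,
) -> ScreeningResult:
    """Rank a library by predicted activity probability against one target."""
    if not 0.0 <= confidence_threshold <= 1.0:
        raise ValueError("confidence_threshold must lie in [0, 1]")
    if len(molecules) == 0:
        raise ValueError("empty screening library")
    graphs, kept, skipped = [], [], []
    for rec in molecules:
        try:
            graphs.append(featurize_molecule(rec.canonical_smiles))
            kept.append(rec)
        except SmilesParseError:
            skipped.append((rec.id, "parse_error"))
    if not kept:
        raise ValueError("no featurizable molecules in the library")
    data = PreparedDataset(
        graphs=graphs,
        labels=np.zeros(len(kept)),
        target_ids=["target"] * len(kept),
        embeddings={"target": embedding},
    )
    probs = predict_scores(model, data, batch_size=batch_size)
    rows = [
        (rec.id, rec.canonical_smiles, float(p), int(p > 0.5))
        for rec, p in zip(kept, probs)
    ]
    rows.sort(key=lambda r: (-r[2], r[0]))
    return ScreeningResult(
        ranked=rows,
        threshold=confidence_threshold,
        n_screened=len(rows),
        n_predicted_active=sum(r[3] for r in rows),
        n_above_threshold=sum(1 for r in rows if r[2] > confidence_threshold),
        threshold_counts={t: sum(1 for r in rows if r[2] > t) for t in REPORT_THRESHOLDS},
        skipped=skipped,
    )


def write_results(result: ScreeningResult, path) -> None:
    """CSV export (id, smiles, probability, label); 6-decimal probabilities."""
    with open(Path(path), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "smiles", "probability", "label"])
        for rid, smi, p, lab in result.ranked:
            w.writerow([rid, smi, f"{p:.6f}", lab])


def read_results(path) -> list:
    with open(Path(path), newline="") as fh:
        reader = csv.DictReader(fh)
        return [
            (row["id"], row["smiles"], float(row["probability"]), int(row["label"]))
            for row in reader
        ]
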