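"""Protein sequence encoding and projection to the 64-d fusion width.

Two interchangeable residue-embedding backends sit behind one interface:

* ``onehot`` — an L×20 indicator matrix over the standard amino-acid
  alphabet ('X' encodes as an all-zero row: an unknown residue carries no
  evidence).
* ``plm`` — precomputed L×1280 residue embeddings from a frozen pretrained
  protein language model, consumed from an ``.npz`` archive produced by an
  external embedding step.  This package never loads language-model weights.

Either backend is projected residue-wise d → 256 (affine, ReLU, dropout 0.3
during training) → 64, yielding the residue-resolved feature matrix Fp that
enters cross-coupled fusion; mean pooling over residues produces the
fixed-length protein vector used by the concatenation ("cat") baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from Bio import SeqIO

from .autodiff import Tensor, relu

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}
ONEHOT_DIM = 20
PLM_DIM = 1280
PROJECTED_DIM = 64


@dataclass
class ProteinSequence:
    id: str
    residues: str

    def __post_init__(self):
        if len(self.residues) < 1:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.residues):
            if ch not in _AA_INDEX and ch != "X":
                raise ValueError(
                    f"protein {self.id!r}: disallowed residue {ch!r} at position {pos}"
                )

    def __len__(self):
        return len(self.residues)


@dataclass
class ResidueEmbedding:
    matrix: np.ndarray      # (L, d)
    backend: str            # {"onehot", "plm"}

    @property
    def length(self) -> int:
        return self.matrix.shape[0]


def encode_onehot(seq: ProteinSequence) -> ResidueEmbedding:
    m = np.zeros((len(seq), ONEHOT_DIM))
    for i, ch in enumerate(seq.residues):
        if ch != "X":
            m[i, _AA_INDEX[ch]] = 1.0
    return ResidueEmbedding(matrix=m, backend="onehot")


def load_plm_embeddings(path, seq: ProteinSequence) -> ResidueEmbedding:
    """Load a precomputed L×1280 residue-embedding matrix for `seq`.

    The archive holds one named array per sequence id. The row count is
    validated against the sequence length.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"embedding file not found: {path}")
    with np.load(path) as data:
        if seq.id not in data:
            raise KeyError(f"no embedding for sequence id {seq.id!r} in {path}")
        m = np.asarray(data[seq.id], dtype=np.float64)
    if m.ndim != 2 or m.shape[1] != PLM_DIM:
        raise ValueError(f"embedding for {seq.id!r} has shape {m.shape}, expected (L, {PLM_DIM})")
    if m.shape[0] != len(seq):
        raise ValueError(
            f"embedding rows ({m.shape[0]}) != sequence length ({len(seq)}) for {seq.id!r}"
        )
    return ResidueEmbedding(matrix=m, backend="plm")


def project_protein(
    emb: ResidueEmbedding,
    params: dict,
    training: bool = False,
    rng: Optional[np.random.Generator] = None,
    dropout: float = 0.3,
) -> Tensor:
    """Residue-wise projection d → 256 (affine, ReLU, dropout) → 64.

    `params` holds Tensors W1 (d×256), b1, W2 (256×64), b2. Inference
    (training=False) is deterministic. Returns the L×64 matrix Fp.
    """
    x = emb.matrix if isinstance(emb.matrix, Tensor) else Tensor(emb.matrix)
    w1 = params["prot_W1"]
    if x.shape[1] != w1.shape[0]:
        raise ValueError(
            f"backend width {x.shape[1]} does not match projection input {w1.shape[0]}"
        )
    h = relu(x @ w1 + params["prot_b1"])
    if training and dropout > 0.0:
        if rng is None:
            raise ValueError("training-mode projection requires an rng for dropout")
        mask = (rng.random(h.shape) >= dropout) / (1.0 - dropout)
        h = h * Tensor(mask)
    return h @ params["prot_W2"] + params["prot_b2"]


def pool_protein(fp: Tensor, mask: Optional[np.ndarray] = None) -> Tensor:
    """Mean over residue rows; with a length mask, padded rows are ignored."""
    fp = fp if isinstance(fp, Tensor) else Tensor(fp)
    if fp.shape[0] < 1:
        raise ValueError("cannot pool an empty residue matrix")
    if mask is None:
        return fp.mean(axis=0)
    mask = np.asarray(mask, dtype=np.float64)
    denom = mask.sum()
    if denom == 0:
        raise ValueError("mask excludes every residue")
    return (fp * Tensor(mask[:, None])).sum(axis=0) * (1.0 / denom)


def read_fasta(path) -> list[ProteinSequence]:
    """Read a (multi-record) FASTA file; the first word of the header is the id."""
    seqs = [
        ProteinSequence(id=rec.id, residues=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not seqs:
        raise ValueError(f"no FASTA records found in {path}")
    return seqs


def write_fasta(seqs: list[ProteinSequence], path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n{s.residues}\n")
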