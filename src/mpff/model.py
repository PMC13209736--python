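"""End-to-end activity-prediction model: protein encoder → MPNN → fusion → MLP head.

The head applies the stack 64 → 128 (ReLU) → 256 (ReLU) → 64 (ReLU + dropout
0.3) → 1 to the fused vector; the scalar output is a logit.  Training uses the
numerically stable binary cross-entropy on logits; classification thresholds
the sigmoid probability strictly at 0.5 (a probability of exactly 0.5 is
called inactive).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .autodiff import Tensor, concatenate, exp, log, relu
from . import fusion as fusion_mod
from . import mpnn as mpnn_mod
from .mol_graph import (
    ATOM_FEATURE_DIM,
    BOND_FEATURE_DIM,
    FEATURIZER_VERSION,
    MolecularGraph,
    batch_graphs,
    featurize_molecule,
)
from .protein_repr import ONEHOT_DIM, PLM_DIM, ResidueEmbedding, project_protein

HEAD_WIDTHS = (64, 128, 256, 64, 1)
EDGE_HIDDEN = 32


@dataclass
class ModelConfig:
    protein_backend: str = "onehot"        # {"onehot", "plm"}
    fusion_mode: str = "fusion"            # {"fusion", "cat"}
    mpnn_rounds: int = 6
    fusion_rounds: int = 2
    dropout: float = 0.3
    head_widths: tuple = HEAD_WIDTHS
    freeze_association: bool = False
    edge_hidden: int = EDGE_HIDDEN
    seed: int = 0

    def __post_init__(self):
        if self.protein_backend not in {"onehot", "plm"}:
            raise ValueError(f"unknown protein backend {self.protein_backend!r}")
        if self.fusion_mode not in {"fusion", "cat"}:
            raise ValueError(f"unknown fusion mode {self.fusion_mode!r}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        self.head_widths = tuple(self.head_widths)

    @property
    def protein_dim(self) -> int:
        return ONEHOT_DIM if self.protein_backend == "onehot" else PLM_DIM


@dataclass
class PredictionResult:
    logit: float
    probability: float
    label: int


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, gain: float = 1.0) -> np.ndarray:
    limit = gain * np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_params(config: ModelConfig) -> dict[str, Tensor]:
    """Seeded Glorot-uniform weights, zero biases, in a fixed naming order."""
    rng = np.random.default_rng(config.seed)
    d = config.protein_dim
    eh = config.edge_hidden
    w = {}
    w["prot_W1"] = _glorot(rng, d, 256)
    w["prot_b1"] = np.zeros(256)
    w["prot_W2"] = _glorot(rng, 256, 64)
    w["prot_b2"] = np.zeros(64)
    w["mpnn_W_in"] = _glorot(rng, ATOM_FEATURE_DIM, 64)
    w["mpnn_b_in"] = np.zeros(64)
    w["mpnn_We1"] = _glorot(rng, BOND_FEATURE_DIM, eh)
    w["mpnn_be1"] = np.zeros(eh)
    # small gain keeps the spectral norm of the message matrices < 1 at init,
    # so six residual rounds cannot blow up the node states
    w["mpnn_We2"] = _glorot(rng, eh, 64 * 64, gain=0.1)
    w["mpnn_be2"] = np.zeros(64 * 64)
    w["mpnn_Wr"] = _glorot(rng, 64, 64)
    w["mpnn_br"] = np.zeros(64)
    w["fus_Wp"] = _glorot(rng, 64, 64)
    w["fus_bp"] = np.zeros(64)
    w["fus_Wd"] = _glorot(rng, 64, 64)
    w["fus_bd"] = np.zeros(64)
    w["fus_dwc_k"] = rng.uniform(-1.0, 1.0, size=(3, 64)) * np.sqrt(1.0 / 3.0)
    w["fus_dwc_b"] = np.zeros(64)
    w["fus_Wout"] = _glorot(rng, 128, 64)
    w["fus_bout"] = np.zeros(64)
    widths = config.head_widths
    for k in range(len(widths) - 1):
        w[f"head_W{k + 1}"] = _glorot(rng, widths[k], widths[k + 1])
        w[f"head_b{k + 1}"] = np.zeros(widths[k + 1])
    return {k: Tensor(v, requires_grad=True) for k, v in w.items()}


def head_forward(
    x: Tensor,
    params: dict,
    widths: tuple = HEAD_WIDTHS,
    training: bool = False,
    dropout: float = 0.3,
    rng: Optional[np.random.Generator] = None,
) -> Tensor:
    """MLP head on (B, 64); ReLU on hidden layers, dropout on the 64-wide layer."""
    h = x
    n_layers = len(widths) - 1
    for k in range(1, n_layers + 1):
        h = h @ params[f"head_W{k}"] + params[f"head_b{k}"]
        if k < n_layers:
            h = relu(h)
            if k == n_layers - 1 and training and dropout > 0.0:
                if rng is None:
                    raise ValueError("training-mode head requires an rng for dropout")
                mask = (rng.random(h.shape) >= dropout) / (1.0 - dropout)
                h = h * Tensor(mask)
    return h.reshape(-1)


class ActivityModel:
    """Trainable end-to-end model over (protein embedding, molecular graph) pairs."""

    def __init__(self, config: ModelConfig, params: Optional[dict] = None):
        self.config = config
        self.params = params if params is not None else init_params(config)

    # -- forward passes -------------------------------------------------------
    def project_target(
        self, emb: ResidueEmbedding, training: bool = False, rng=None
    ) -> Tensor:
        return project_protein(
            emb, self.params, training=training, rng=rng, dropout=self.config.dropout
        )

    def forward_batch(
        self,
        embeddings: dict[str, ResidueEmbedding],
        graphs: Sequence[MolecularGraph],
        target_ids: Sequence[str],
        training: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> Tensor:
        """Logits for a batch of (target, molecule) pairs. Deterministic at inference.

        Molecules run through the MPNN as one block-diagonal graph; fusion runs
        on zero-padded (B, L, 64) stacks with residue/atom masks, an exact
        vectorization of the per-sample fusion ops.
        """
        if len(graphs) != len(target_ids):
            raise ValueError("graphs and target_ids must have equal length")
        B = len(graphs)
        batched = batch_graphs(list(graphs))
        states = mpnn_mod.init_node_states(batched, self.params)
        for _ in range(self.config.mpnn_rounds):
            states = mpnn_mod.message_pass_round(states, batched, self.params)

        # pad per-molecule atom states into (B, Ldmax, 64) via one gather; the
        # appended zero row backs every padding position
        sizes = np.diff(batched.atom_offsets)
        ld_max = int(sizes.max())
        pad_idx = np.full((B, ld_max), batched.num_atoms, dtype=np.intp)
        atom_mask = np.zeros((B, ld_max))
        for b in range(B):
            n = int(sizes[b])
            pad_idx[b, :n] = np.arange(batched.atom_offsets[b], batched.atom_offsets[b + 1])
            atom_mask[b, :n] = 1.0
        h_pad = concatenate([states.h, Tensor(np.zeros((1, states.h.shape[1])))], axis=0)
        Fd3 = h_pad[pad_idx]

        uniq_targets = sorted(set(target_ids))
        fps = {
            tid: self.project_target(embeddings[tid], training=training, rng=rng)
            for tid in uniq_targets
        }
        lp_max = max(fp.shape[0] for fp in fps.values())
        fp_rows, prot_masks = [], {}
        for tid in uniq_targets:
            fp = fps[tid]
            lp = fp.shape[0]
            if lp < lp_max:
                fp = concatenate([fp, Tensor(np.zeros((lp_max - lp, fp.shape[1])))], axis=0)
            fp_rows.append(fp.reshape(1, lp_max, -1))
            prot_masks[tid] = np.concatenate([np.ones(lp), np.zeros(lp_max - lp)])
        fp_stack = concatenate(fp_rows, axis=0)
        tidx = np.array([uniq_targets.index(t) for t in target_ids], dtype=np.intp)
        Fp3 = fp_stack[tidx]
        prot_mask = np.stack([prot_masks[t] for t in target_ids])

        if self.config.fusion_mode == "cat":
            fused = fusion_mod.fuse_cat_batch(Fp3, Fd3, self.params, prot_mask, atom_mask)
        else:
            Ad3 = np.zeros((B, ld_max, ld_max))
            for b, g in enumerate(graphs):
                n = g.num_atoms
                Ad3[b, :n, :n] = g.adjacency
            fused = fusion_mod.fuse_batch(
                Fp3, Fd3, Ad3, self.params, prot_mask, atom_mask,
                n_rounds=self.config.fusion_rounds,
                freeze_association=self.config.freeze_association,
            )
        return head_forward(
            fused,
            self.params,
            widths=self.config.head_widths,
            training=training,
            dropout=self.config.dropout,
            rng=rng,
        )

    def forward(
        self,
        embedding: ResidueEmbedding,
        molecule: Union[str, MolecularGraph],
        training: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> float:
        """Single-pair logit; accepts a SMILES string or a prebuilt graph."""
        graph = featurize_molecule(molecule) if isinstance(molecule, str) else molecule
        logits = self.forward_batch(
            {"t": embedding}, [graph], ["t"], training=training, rng=rng
        )
        return float(logits.data[0])

    # -- persistence ----------------------------------------------------------
    def save(self, path) -> None:
        """Single-archive checkpoint: parameter arrays + JSON config."""
        meta = {
            "config": asdict(self.config),
            "featurizer_version": FEATURIZER_VERSION,
        }
        arrays = {k: t.data for k, t in self.params.items()}
        np.savez(Path(path), __meta__=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path) -> "ActivityModel":
        with np.load(Path(path)) as data:
            meta = json.loads(str(data["__meta__"]))
            params = {
                k: Tensor(data[k], requires_grad=True)
                for k in data.files
                if k != "__meta__"
            }
        cfg = meta["config"]
        cfg["head_widths"] = tuple(cfg["head_widths"])
        return cls(ModelConfig(**cfg), params=params)


# -- losses and classification -------------------------------------------------

def bce_with_logits(logits, labels) -> Tensor:
    """Mean binary cross-entropy on logits, in the stable form
    max(z,0) − z·y + log(1 + exp(−|z|))."""
    z = logits if isinstance(logits, Tensor) else Tensor(logits)
    y = np.asarray(labels, dtype=np.float64)
    if z.data.shape != y.shape:
        raise ValueError(f"shape mismatch: logits {z.data.shape} vs labels {y.shape}")
    if y.size < 1:
        raise ValueError("empty batch")
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("labels must be binary (0/1)")
    abs_z = relu(z) + relu(-z)
    per = relu(z) - z * Tensor(y) + log(exp(-abs_z) + 1.0)
    return per.mean()


def classify(logit: float) -> PredictionResult:
    """Sigmoid probability; active iff probability strictly exceeds 0.5."""
    if not np.isfinite(logit):
        raise ValueError(f"non-finite logit: {logit!r}")
    p = float(1.0 / (1.0 + np.exp(-logit)))
    return PredictionResult(logit=float(logit), probability=p, label=int(p > 0.5))
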