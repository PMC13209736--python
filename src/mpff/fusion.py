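"""Cross-coupled protein-compound feature fusion.

A row-stochastic association matrix C = softmax(Fp Fdᵀ) (softmax over the
compound-atom axis, so each residue distributes attention over atoms)
bridges the protein "sub-graph" — whose adjacency is stood in for by a
per-channel length-3 depthwise convolution along the residue axis — and the
compound graph with its chemical adjacency Ad.  Each fusion round applies the
residual cross-updates

    Fp ← DWC(ω_p(Fp)) + C·ω_d(Fd) + Fp
    Fd ← Cᵀ·ω_p(Fp) + Ad·ω_d(Fd) + Fd

with ω an affine map plus ReLU.  By default C is recomputed from the current
features at the start of every round; ``freeze_association`` keeps the
initial C throughout.  After N rounds both feature matrices are mean-pooled,
concatenated (128) and projected to the 64-d fused vector consumed by the
prediction head.  The "cat" baseline skips the cross-coupling entirely:
pool, concatenate, project.

Protein padding rows are handled through an optional binary length mask:
masked rows produce zero association rows, are zeroed inside ω_p, and are
excluded from pooling, so padding never influences the fused vector.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .autodiff import Tensor, concatenate, exp, relu

FUSED_DIM = 64
DEFAULT_FUSION_ROUNDS = 2


def _lift(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def compute_association(Fp, Fd, mask: Optional[np.ndarray] = None) -> Tensor:
    """C = row-wise softmax of Fp·Fdᵀ over the atom axis; masked rows are zero."""
    Fp, Fd = _lift(Fp), _lift(Fd)
    if Fp.shape[1] != Fd.shape[1]:
        raise ValueError(f"feature widths differ: {Fp.shape[1]} vs {Fd.shape[1]}")
    z = Fp @ Fd.T
    # constant shift for numerical stability (does not change the softmax)
    shift = z.data.max(axis=1, keepdims=True)
    e = exp(z - Tensor(shift))
    C = e / e.sum(axis=1, keepdims=True)
    if mask is not None:
        C = C * Tensor(np.asarray(mask, dtype=np.float64)[:, None])
    return C


def depthwise_conv_protein(X, params: dict) -> Tensor:
    """Per-channel 1-D convolution along residues; kernel length 3, zero padding 1."""
    X = _lift(X)
    k, b = params["fus_dwc_k"], params["fus_dwc_b"]   # (3, 64), (64,)
    L, C = X.shape
    zrow = Tensor(np.zeros((1, C)))
    xp = concatenate([zrow, X, zrow], axis=0)
    return xp[0:L] * k[0] + xp[1 : L + 1] * k[1] + xp[2 : L + 2] * k[2] + b


def _omega(X: Tensor, W: Tensor, b: Tensor) -> Tensor:
    return relu(X @ W + b)


def fusion_round(
    Fp,
    Fd,
    Ad: np.ndarray,
    params: dict,
    mask: Optional[np.ndarray] = None,
    C: Optional[Tensor] = None,
) -> tuple[Tensor, Tensor]:
    """One residual cross-update; C recomputed from the current features unless given."""
    Fp, Fd = _lift(Fp), _lift(Fd)
    if C is None:
        C = compute_association(Fp, Fd, mask=mask)
    wp = _omega(Fp, params["fus_Wp"], params["fus_bp"])
    if mask is not None:
        wp = wp * Tensor(np.asarray(mask, dtype=np.float64)[:, None])
    wd = _omega(Fd, params["fus_Wd"], params["fus_bd"])
    Fp_new = depthwise_conv_protein(wp, params) + C @ wd + Fp
    Fd_new = C.T @ wp + Tensor(np.asarray(Ad, dtype=np.float64)) @ wd + Fd
    return Fp_new, Fd_new


def _masked_mean(X: Tensor, mask: Optional[np.ndarray]) -> Tensor:
    if mask is None:
        return X.mean(axis=0)
    m = np.asarray(mask, dtype=np.float64)
    return (X * Tensor(m[:, None])).sum(axis=0) * (1.0 / m.sum())


def fuse(
    Fp0,
    Fd0,
    Ad: np.ndarray,
    params: dict,
    n_rounds: int = DEFAULT_FUSION_ROUNDS,
    mask: Optional[np.ndarray] = None,
    freeze_association: bool = False,
) -> Tensor:
    """N fusion rounds, then mask-aware pooling, concatenation and 128→64 projection."""
    if n_rounds < 1:
        raise ValueError("n_rounds must be ≥ 1")
    Fp, Fd = _lift(Fp0), _lift(Fd0)
    C0 = compute_association(Fp, Fd, mask=mask) if freeze_association else None
    for _ in range(n_rounds):
        Fp, Fd = fusion_round(Fp, Fd, Ad, params, mask=mask, C=C0)
    pooled = concatenate([_masked_mean(Fp, mask), Fd.mean(axis=0)], axis=0)
    return pooled @ params["fus_Wout"] + params["fus_bout"]


def fuse_cat_baseline(Fp0, Fd0, params: dict, mask: Optional[np.ndarray] = None) -> Tensor:
    """Ablation "cat" mode: pool both entities, concatenate, project; no cross-coupling."""
    pooled = concatenate([_masked_mean(_lift(Fp0), mask), _lift(Fd0).mean(axis=0)], axis=0)
    return pooled @ params["fus_Wout"] + params["fus_bout"]


# -- batched (B, L, 64) path ---------------------------------------------------
#
# Exact vectorization of the per-sample operations above over a padded batch;
# the tests assert elementwise agreement with the 2-D route.  Masks are binary
# (B, Lp) / (B, Ld) arrays marking real residues/atoms.

def compute_association_batch(Fp3, Fd3, prot_mask: np.ndarray, atom_mask: np.ndarray) -> Tensor:
    Fp3, Fd3 = _lift(Fp3), _lift(Fd3)
    z = Fp3 @ Fd3.transpose((0, 2, 1))                       # (B, Lp, Ld)
    am = atom_mask[:, None, :]
    shift = np.where(am > 0, z.data, -np.inf).max(axis=2, keepdims=True)
    e = exp(z - Tensor(shift)) * Tensor(am)
    C = e / e.sum(axis=2, keepdims=True)
    return C * Tensor(prot_mask[:, :, None])


def depthwise_conv_batch(X3, params: dict) -> Tensor:
    X3 = _lift(X3)
    k, b = params["fus_dwc_k"], params["fus_dwc_b"]
    B, L, C = X3.shape
    zrow = Tensor(np.zeros((B, 1, C)))
    xp = concatenate([zrow, X3, zrow], axis=1)
    sl = lambda lo: (slice(None), slice(lo, lo + L))
    return xp[sl(0)] * k[0] + xp[sl(1)] * k[1] + xp[sl(2)] * k[2] + b


def fusion_round_batch(Fp3, Fd3, Ad3: np.ndarray, params: dict,
                       prot_mask: np.ndarray, atom_mask: np.ndarray,
                       C: Optional[Tensor] = None) -> tuple[Tensor, Tensor]:
    Fp3, Fd3 = _lift(Fp3), _lift(Fd3)
    if C is None:
        C = compute_association_batch(Fp3, Fd3, prot_mask, atom_mask)
    wp = _omega(Fp3, params["fus_Wp"], params["fus_bp"]) * Tensor(prot_mask[:, :, None])
    wd = _omega(Fd3, params["fus_Wd"], params["fus_bd"]) * Tensor(atom_mask[:, :, None])
    Fp_new = depthwise_conv_batch(wp, params) + C @ wd + Fp3
    Fd_new = C.transpose((0, 2, 1)) @ wp + Tensor(Ad3) @ wd + Fd3
    return Fp_new, Fd_new


def _masked_mean_batch(X3: Tensor, mask: np.ndarray) -> Tensor:
    pooled = (X3 * Tensor(mask[:, :, None])).sum(axis=1)
    return pooled * Tensor(1.0 / mask.sum(axis=1)[:, None])


def fuse_batch(Fp3, Fd3, Ad3: np.ndarray, params: dict,
               prot_mask: np.ndarray, atom_mask: np.ndarray,
               n_rounds: int = DEFAULT_FUSION_ROUNDS,
               freeze_association: bool = False) -> Tensor:
    """Batched fusion: (B, Lp, 64) × (B, Ld, 64) → (B, 64) fused vectors."""
    if n_rounds < 1:
        raise ValueError("n_rounds must be ≥ 1")
    Fp3, Fd3 = _lift(Fp3), _lift(Fd3)
    C0 = (compute_association_batch(Fp3, Fd3, prot_mask, atom_mask)
          if freeze_association else None)
    for _ in range(n_rounds):
        Fp3, Fd3 = fusion_round_batch(Fp3, Fd3, Ad3, params, prot_mask, atom_mask, C=C0)
    pooled = concatenate(
        [_masked_mean_batch(Fp3, prot_mask), _masked_mean_batch(Fd3, atom_mask)], axis=1
    )
    return pooled @ params["fus_Wout"] + params["fus_bout"]


def fuse_cat_batch(Fp3, Fd3, params: dict,
                   prot_mask: np.ndarray, atom_mask: np.ndarray) -> Tensor:
    pooled = concatenate(
        [_masked_mean_batch(_lift(Fp3), prot_mask), _masked_mean_batch(_lift(Fd3), atom_mask)],
        axis=1,
    )
    return pooled @ params["fus_Wout"] + params["fus_bout"]
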