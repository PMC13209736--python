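# mpff

Molecular-protein feature-fusion models for binary inhibitor-activity
prediction and virtual screening.

`mpff` is for computational chemists building target-specific activity
classifiers from bioactivity-database extracts (SMILES + IC50) and using
them to rank screening libraries.  It provides the full desk-scale
pipeline: dataset construction (IC50 labeling, canonical-SMILES
deduplication, Bemis-Murcko scaffold splitting, physicochemical filtering),
an end-to-end neural model, training with AdamW/early stopping and
Gaussian-process hyperparameter search, the standard classification
metrics, model-based library screening, and seeded synthetic data
generators so every stage is testable without external downloads.

## Model

A compound and a protein are encoded separately and fused:

* **Compound:** heavy-atom graph with 74-d atom / 12-d bond features; six
  residual rounds of edge-conditioned message passing
  (`h_i ← h_i + Σ_j M(e_ij) h_j`, shared weights) give per-atom states
  `F_d ∈ R^{L_d×64}`.
* **Protein:** residue embeddings (one-hot L×20, or precomputed
  protein-language-model L×1280) projected residue-wise 1280/20 → 256 → 64
  to `F_p ∈ R^{L_p×64}`.
* **Fusion:** a row-stochastic association matrix
  `C = softmax(F_p F_dᵀ)` cross-couples the entities through N residual
  rounds `F_p ← DWC(ω(F_p)) + C ω(F_d) + F_p`,
  `F_d ← Cᵀ ω(F_p) + A_d ω(F_d) + F_d`, where DWC is a per-channel
  length-3 convolution along the residue axis and `A_d` the chemical
  adjacency; pooling, concatenation and projection give a 64-d fused vector.
* **Head:** MLP 64 → 128 → 256 → 64 → 1 (ReLU, dropout 0.3) producing a
  logit; `P(active) = σ(logit)`, active iff P > 0.5.

Everything is NumPy float64 on a small reverse-mode autodiff core —
deterministic under a fixed seed and cross-checked against explicit-loop
oracles in the tests.  See `docs/methods.md` for assumptions, parameter
defaults and numerical choices.

## Worked example

```
mpff synth --n 300 --seed 7 --scaffold-pool 60 --protein-length 48 \
    --out data.csv --fasta-out target.fasta
mpff split --data data.csv --out split.csv --report split_report.json
mpff train --data split.csv --protein target.fasta --max-epochs 15 \
    --seed 0 --out model.npz
mpff evaluate --model model.npz --data split.csv --protein target.fasta
mpff screen --model model.npz --protein target.fasta --library data.csv \
    --confidence-threshold 0.9 --out hits.csv
```

The `split` step prints the deviation report:

```
{"size_fractions": {"train": 0.8, "val": 0.1, "test": 0.1},
 "positive_fractions": {"train": 0.4208, "val": 0.4, "test": 0.4333},
 "global_positive_fraction": 0.42, "n_scaffolds": 60, "warnings": []}
```

— whole scaffold groups land exactly on the 8:1:1 target here, with each
subset's positive rate within 2 points of the global 42%.  Training prints
per-epoch loss/validation lines and stops at the best-validation epoch
(`best epoch 9, val loss 0.0000`).  `evaluate` prints one row in the
standard column order:

```
accuracy	roc_auc	f1	mcc	recall	precision	specificity
1.0000	1.0000	1.0000	1.0000	1.0000	1.0000	1.0000
```

— the synthetic activity rule is a single substructure, so the model
separates the held-out scaffolds perfectly; real bioactivity data will not
be this clean (see `docs/methods.md` on what the synthetic fixtures do and
do not emulate).  `screen` then reports

```
{"screened": 300, "predicted_active": 126, "above_threshold": 126,
 "threshold_counts": {"0.5": 126, "0.9": 126, "0.99": 126}}
```

— all 126 predicted actives are held with ≥0.99 confidence — and writes the
ranked list to `hits.csv`.

The same pipeline is available as a library (`mpff.synthetic`,
`mpff.data_pipeline`, `mpff.training`, `mpff.screening`) for scripted use,
including the precomputed-embedding protein backend
(`--backend plm --embeddings embeddings.npz`).

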