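"""Cross-coupled fusion: association matrix, DWC, rounds, pooling, batching."""

import numpy as np
import pytest

from mpff.autodiff import Tensor
from mpff.fusion import (
    compute_association,
    compute_association_batch,
    depthwise_conv_batch,
    depthwise_conv_protein,
    fuse,
    fuse_batch,
    fuse_cat_baseline,
    fuse_cat_batch,
    fusion_round,
    fusion_round_batch,
)
from mpff.mol_graph import featurize_molecule
from mpff.model import ActivityModel, ModelConfig


def dense_fusion_oracle(Fp, Fd, Ad, p):
    """Plain-NumPy reimplementation of one fusion round (loops and formulas)."""
    z = Fp @ Fd.T
    C = np.zeros_like(z)
    for r in range(z.shape[0]):
        e = np.exp(z[r] - z[r].max())
        C[r] = e / e.sum()
    wp = np.maximum(Fp @ p["fus_Wp"].data + p["fus_bp"].data, 0.0)
    wd = np.maximum(Fd @ p["fus_Wd"].data + p["fus_bd"].data, 0.0)
    k, b = p["fus_dwc_k"].data, p["fus_dwc_b"].data
    L = wp.shape[0]
    dwc = np.zeros_like(wp)
    padded = np.vstack([np.zeros(64), wp, np.zeros(64)])
    for i in range(L):
        dwc[i] = k[0] * padded[i] + k[1] * padded[i + 1] + k[2] * padded[i + 2] + b
    return dwc + C @ wd + Fp, C.T @ wp + Ad @ wd + Fd


class TestAssociation:
    def test_zero_protein_features_give_uniform_rows(self, rng):
        Fd = rng.normal(size=(5, 64))
        C = compute_association(np.zeros((3, 64)), Fd)
        np.testing.assert_allclose(C.data, np.full((3, 5), 0.2), atol=1e-12)

    def test_one_by_one(self, rng):
        C = compute_association(rng.normal(size=(1, 64)), rng.normal(size=(1, 64)))
        np.testing.assert_allclose(C.data, [[1.0]], atol=1e-15)

    def test_matches_brute_force_softmax(self, rng):
        Fp, Fd = rng.normal(size=(3, 64)), rng.normal(size=(4, 64))
        C = compute_association(Fp, Fd).data
        for r in range(3):
            dots = np.array([Fp[r] @ Fd[a] for a in range(4)])
            expect = np.exp(dots) / np.exp(dots).sum()
            np.testing.assert_allclose(C[r], expect, atol=1e-6)

    def test_row_stochastic_and_nonnegative(self, rng):
        C = compute_association(rng.normal(size=(7, 64)), rng.normal(size=(9, 64))).data
        assert np.all(C >= 0)
        np.testing.assert_allclose(C.sum(axis=1), np.ones(7), atol=1e-6)

    def test_width_mismatch(self, rng):
        with pytest.raises(ValueError):
            compute_association(rng.normal(size=(3, 32)), rng.normal(size=(4, 64)))

    def test_masked_rows_are_zero(self, rng):
        mask = np.array([1.0, 0.0, 1.0])
        C = compute_association(rng.normal(size=(3, 64)), rng.normal(size=(4, 64)), mask=mask)
        np.testing.assert_array_equal(C.data[1], np.zeros(4))


class TestDepthwiseConv:
    def _params(self, model_params, k, b=None):
        p = dict(model_params)
        p["fus_dwc_k"] = Tensor(np.tile(np.asarray(k)[:, None], (1, 64)))
        p["fus_dwc_b"] = Tensor(b if b is not None else np.zeros(64))
        return p

    def test_identity_kernel(self, model_params, rng):
        X = rng.normal(size=(6, 64))
        out = depthwise_conv_protein(Tensor(X), self._params(model_params, [0, 1, 0]))
        np.testing.assert_allclose(out.data, X, atol=1e-12)

    def test_single_residue_boundary(self, model_params, rng):
        X = rng.normal(size=(1, 64))
        b = rng.normal(size=64)
        out = depthwise_conv_protein(Tensor(X), self._params(model_params, [0.3, 0.5, -0.2], b))
        np.testing.assert_allclose(out.data, 0.5 * X + b, atol=1e-12)

    def test_matches_sliding_window_loop(self, model_params, rng):
        X = rng.normal(size=(6, 64))
        k, b = model_params["fus_dwc_k"].data, model_params["fus_dwc_b"].data
        out = depthwise_conv_protein(Tensor(X), model_params).data
        padded = np.vstack([np.zeros(64), X, np.zeros(64)])
        for i in range(6):
            expect = k[0] * padded[i] + k[1] * padded[i + 1] + k[2] * padded[i + 2] + b
            np.testing.assert_allclose(out[i], expect, atol=1e-6)


class TestFusionRound:
    def test_zero_weights_pure_residual(self, rng):
        p = {k: Tensor(np.zeros_like(v.data))
             for k, v in ActivityModel(ModelConfig(seed=0)).params.items()}
        Fp, Fd = rng.normal(size=(3, 64)), rng.normal(size=(4, 64))
        Ad = np.zeros((4, 4))
        for _ in range(4):   # residual identity holds for any number of rounds
            Fp_t, Fd_t = fusion_round(Tensor(Fp), Tensor(Fd), Ad, p)
            np.testing.assert_array_equal(Fp_t.data, Fp)
            np.testing.assert_array_equal(Fd_t.data, Fd)
            Fp, Fd = Fp_t.data, Fd_t.data

    def test_shapes_preserved(self, model_params, rng):
        Fp, Fd = rng.normal(size=(5, 64)), rng.normal(size=(7, 64))
        Ad = (rng.random((7, 7)) < 0.3).astype(float)
        Ad = np.triu(Ad, 1) + np.triu(Ad, 1).T
        Fp2, Fd2 = fusion_round(Tensor(Fp), Tensor(Fd), Ad, model_params)
        assert Fp2.shape == (5, 64) and Fd2.shape == (7, 64)

    def test_matches_dense_oracle(self, model_params, rng):
        g = featurize_molecule("CC(O)CN")   # 5 heavy atoms
        Fp, Fd = rng.normal(size=(3, 64)), rng.normal(size=(g.num_atoms, 64))
        Fp2, Fd2 = fusion_round(Tensor(Fp), Tensor(Fd), g.adjacency, model_params)
        eFp, eFd = dense_fusion_oracle(Fp, Fd, g.adjacency, model_params)
        np.testing.assert_allclose(Fp2.data, eFp, atol=1e-5)
        np.testing.assert_allclose(Fd2.data, eFd, atol=1e-5)

    def test_association_recomputed_each_round_stays_stochastic(self, model_params, rng):
        Ad = featurize_molecule("CC(O)CN").adjacency
        Fp, Fd = Tensor(rng.normal(size=(4, 64))), Tensor(rng.normal(size=(5, 64)))
        for _ in range(3):
            C = compute_association(Fp, Fd)
            np.testing.assert_allclose(C.data.sum(axis=1), np.ones(4), atol=1e-6)
            Fp, Fd = fusion_round(Fp, Fd, Ad, model_params)


class TestFuse:
    def test_output_width(self, model_params, rng):
        g = featurize_molecule("c1ccccc1")
        fs = fuse(rng.normal(size=(10, 64)), rng.normal(size=(6, 64)), g.adjacency,
                  model_params, n_rounds=2)
        assert fs.shape == (64,)

    def test_single_round_composition(self, model_params, rng):
        Ad = featurize_molecule("CC(O)CN").adjacency
        Fp, Fd = rng.normal(size=(3, 64)), rng.normal(size=(Ad.shape[0], 64))
        fs = fuse(Fp, Fd, Ad, model_params, n_rounds=1).data
        Fp1, Fd1 = fusion_round(Tensor(Fp), Tensor(Fd), Ad, model_params)
        pooled = np.concatenate([Fp1.data.mean(axis=0), Fd1.data.mean(axis=0)])
        expect = pooled @ model_params["fus_Wout"].data + model_params["fus_bout"].data
        np.testing.assert_allclose(fs, expect, atol=1e-10)

    def test_atom_permutation_invariance(self, model_params, rng):
        g = featurize_molecule("CC(=O)Nc1ccc(O)cc1")
        Fp = rng.normal(size=(8, 64))
        Fd = rng.normal(size=(g.num_atoms, 64))
        perm = rng.permutation(g.num_atoms)
        fs1 = fuse(Fp, Fd, g.adjacency, model_params).data
        fs2 = fuse(Fp, Fd[perm], g.adjacency[perm][:, perm], model_params).data
        np.testing.assert_allclose(fs1, fs2, atol=1e-6)

    def test_requires_at_least_one_round(self, model_params, rng):
        with pytest.raises(ValueError):
            fuse(rng.normal(size=(3, 64)), rng.normal(size=(4, 64)),
                 np.zeros((4, 4)), model_params, n_rounds=0)


class TestCatBaseline:
    def test_matches_hand_pooled_concatenation(self, model_params, rng):
        Fp, Fd = rng.normal(size=(5, 64)), rng.normal(size=(3, 64))
        fs = fuse_cat_baseline(Fp, Fd, model_params).data
        pooled = np.concatenate([Fp.mean(axis=0), Fd.mean(axis=0)])
        expect = pooled @ model_params["fus_Wout"].data + model_params["fus_bout"].data
        np.testing.assert_allclose(fs, expect, atol=1e-10)


class TestBatchedPath:
    def _random_batch(self, model_params, rng, B=3):
        lps = [5, 3, 5]
        lds = [4, 6, 2]
        Fps = [rng.normal(size=(lp, 64)) for lp in lps]
        Fds = [rng.normal(size=(ld, 64)) for ld in lds]
        Ads = []
        for ld in lds:
            A = (rng.random((ld, ld)) < 0.4).astype(float)
            A = np.triu(A, 1) + np.triu(A, 1).T
            Ads.append(A)
        lp_max, ld_max = max(lps), max(lds)
        Fp3 = np.zeros((B, lp_max, 64)); Fd3 = np.zeros((B, ld_max, 64))
        Ad3 = np.zeros((B, ld_max, ld_max))
        pm = np.zeros((B, lp_max)); am = np.zeros((B, ld_max))
        for b in range(B):
            Fp3[b, :lps[b]] = Fps[b]; pm[b, :lps[b]] = 1
            Fd3[b, :lds[b]] = Fds[b]; am[b, :lds[b]] = 1
            Ad3[b, :lds[b], :lds[b]] = Ads[b]
        return Fps, Fds, Ads, Fp3, Fd3, Ad3, pm, am

    def test_batched_fuse_equals_per_sample(self, model_params, rng):
        Fps, Fds, Ads, Fp3, Fd3, Ad3, pm, am = self._random_batch(model_params, rng)
        out = fuse_batch(Fp3, Fd3, Ad3, model_params, pm, am, n_rounds=2).data
        for b in range(3):
            single = fuse(Fps[b], Fds[b], Ads[b], model_params, n_rounds=2).data
            np.testing.assert_allclose(out[b], single, atol=1e-5)

    def test_batched_cat_equals_per_sample(self, model_params, rng):
        Fps, Fds, _, Fp3, Fd3, _, pm, am = self._random_batch(model_params, rng)
        out = fuse_cat_batch(Fp3, Fd3, model_params, pm, am).data
        for b in range(3):
            single = fuse_cat_baseline(Fps[b], Fds[b], model_params).data
            np.testing.assert_allclose(out[b], single, atol=1e-5)

    def test_extra_padding_rows_do_not_change_result(self, model_params, rng):
        Fps, Fds, Ads, Fp3, Fd3, Ad3, pm, am = self._random_batch(model_params, rng)
        # widen padding by 3 residues and 2 atoms
        B = 3
        Fp3w = np.concatenate([Fp3, rng.normal(size=(B, 3, 64))], axis=1)
        pmw = np.concatenate([pm, np.zeros((B, 3))], axis=1)
        Fd3w = np.concatenate([Fd3, np.zeros((B, 2, 64))], axis=1)
        amw = np.concatenate([am, np.zeros((B, 2))], axis=1)
        Ad3w = np.zeros((B, Ad3.shape[1] + 2, Ad3.shape[1] + 2))
        Ad3w[:, :Ad3.shape[1], :Ad3.shape[1]] = Ad3
        a = fuse_batch(Fp3, Fd3, Ad3, model_params, pm, am).data
        b = fuse_batch(Fp3w, Fd3w, Ad3w, model_params, pmw, amw).data
        np.testing.assert_allclose(a, b, atol=1e-6)
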