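"""Labeling, deduplication, scaffold splitting and library filtering."""

import numpy as np
import pytest

from mpff.data_pipeline import (
    ActivityRecord,
    FilterCriteria,
    deduplicate,
    filter_library,
    label_by_ic50,
    murcko_scaffold,
    scaffold_split,
    split_records,
)
from mpff.mol_graph import MoleculeRecord, compute_descriptors
from mpff.synthetic import SyntheticSpec, generate_activity_dataset, generate_library


def _rec(smiles, ic50=None, rid="m", target="T1", label=None):
    return ActivityRecord(id=rid, smiles=smiles, ic50_nM=ic50, target_id=target, label=label)


class TestLabeling:
    @pytest.mark.parametrize("ic50,label", [(1.0, 1), (100.0, 0), (6.1, 1), (6.11, 0)])
    def test_threshold_rule(self, ic50, label):
        labeled, rejected = label_by_ic50([_rec("CCO", ic50)])
        assert not rejected
        assert labeled[0].label == label

    def test_missing_ic50_rejected_with_reason(self):
        labeled, rejected = label_by_ic50([_rec("CCO", None)])
        assert not labeled and rejected[0][1] == "missing ic50"

    def test_monotone_in_threshold(self, rng):
        recs = [_rec("CCO", float(v), rid=f"m{i}") for i, v in enumerate(rng.uniform(0.1, 100, 50))]
        loose, _ = label_by_ic50(recs, threshold_nM=10.0)
        tight, _ = label_by_ic50(recs, threshold_nM=2.0)
        for a, b in zip(tight, loose):
            assert a.label <= b.label   # lowering threshold never creates positives


class TestDeduplication:
    def test_identical_records_collapse(self):
        survivors, n = deduplicate([_rec("CCO", 2.0), _rec("CCO", 2.0)])
        assert len(survivors) == 1 and n == 1

    def test_median_ic50_and_relabel(self):
        survivors, _ = deduplicate([_rec("CCO", 2.0), _rec("OCC", 10.0)])
        assert len(survivors) == 1
        assert survivors[0].ic50_nM == pytest.approx(6.0)
        assert survivors[0].label == 1   # 6.0 ≤ 6.1

    def test_distinct_molecules_untouched(self):
        recs = [_rec(s, 1.0, rid=s) for s in ["CCO", "CCC", "CCN"]]
        survivors, n = deduplicate(recs)
        assert len(survivors) == 3 and n == 0

    def test_same_smiles_different_target_kept(self):
        survivors, _ = deduplicate([_rec("CCO", 1.0, target="T1"), _rec("CCO", 1.0, target="T2")])
        assert len(survivors) == 2

    def test_strict_mode_drops_conflicts(self):
        recs = label_by_ic50([_rec("CCO", 2.0), _rec("OCC", 100.0)])[0]
        survivors, _ = deduplicate(recs, strict=True)
        assert survivors == []


class TestMurckoScaffold:
    def test_pure_ring_is_its_own_scaffold(self):
        assert murcko_scaffold("c1ccccc1") == "c1ccccc1"

    def test_toluene_strips_side_chain(self):
        assert murcko_scaffold("Cc1ccccc1") == "c1ccccc1"

    def test_acyclic_molecule_has_empty_scaffold(self):
        assert murcko_scaffold("CCO") == ""


class TestScaffoldSplit:
    def test_ten_singleton_groups_split_8_1_1(self):
        # ten distinct ring systems, one molecule each
        smiles = ["c1ccccc1", "C1CCCCC1", "c1ccncc1", "C1CCNCC1", "c1ccsc1",
                  "c1ccoc1", "C1CCOC1", "C1CCCC1", "C1CCNC1", "c1cncnc1"]
        recs = [_rec(s, rid=f"m{i}", label=i % 2) for i, s in enumerate(smiles)]
        split = scaffold_split(recs)
        sizes = {k: round(v * 10) for k, v in split.size_fractions.items()}
        assert sizes == {"train": 8, "val": 1, "test": 1}

    def test_single_shared_scaffold_all_train_with_warning(self):
        recs = [_rec(f"{'C' * i}c1ccccc1", rid=f"m{i}", label=i % 2) for i in range(1, 6)]
        split = scaffold_split(recs)
        assert split.size_fractions["train"] == 1.0
        assert split.warnings

    def test_no_scaffold_leakage_and_partition(self, small_dataset):
        split = scaffold_split(small_dataset, seed=7)
        subsets = split_records(small_dataset, split)
        assert sum(len(v) for v in subsets.values()) == len(small_dataset)
        seen = {}
        for name, recs in subsets.items():
            for r in recs:
                scaf = murcko_scaffold(r.canonical_smiles)
                assert seen.setdefault(scaf, name) == name

    def test_determinism(self, small_dataset):
        a = scaffold_split(small_dataset, seed=7)
        b = scaffold_split(small_dataset, seed=7)
        assert a.assignment == b.assignment

    def test_seeded_thousand_molecule_library_hits_targets(self):
        spec = SyntheticSpec(n_molecules=1000, seed=7, scaffold_pool_size=100)
        recs = generate_activity_dataset(spec)
        split = scaffold_split(recs, seed=7)
        for subset, target in zip(("train", "val", "test"), (0.8, 0.1, 0.1)):
            assert abs(split.size_fractions[subset] - target) <= 0.05
            assert abs(split.positive_fractions[subset] - split.global_positive_fraction) < 0.05

    def test_bad_fractions_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            scaffold_split(small_dataset, fractions=(0.5, 0.2, 0.2))


class TestFilterLibrary:
    def test_low_mw_rejected_with_reason(self):
        survivors, log = filter_library([MoleculeRecord(id="a", smiles="CCO")])
        assert not survivors
        assert log == [("a", "mw")]

    def test_engineered_in_window_molecule_retained(self):
        # long lipophilic amide: inside all four inclusive windows
        smiles = "CCCCCCc1ccc(OCCOCCOCCOC(=O)c2ccc(NC(=O)CCCC)cc2)cc1C(=O)NCCOC"
        d = compute_descriptors(smiles)
        assert 550 <= d.mw <= 1500 and 4 <= d.logp <= 8
        assert 1 <= d.hbd <= 4 and 7 <= d.hba <= 13
        survivors, log = filter_library([MoleculeRecord(id="big", smiles=smiles)])
        assert [r.id for r in survivors] == ["big"]

    def test_matches_brute_force_bound_check(self, small_dataset):
        crit = FilterCriteria(mw=(150.0, 400.0), logp=(0.0, 5.0), hbd=(0, 3), hba=(0, 6))
        survivors, _ = filter_library(small_dataset, crit)
        expect = []
        seen = set()
        for rec in small_dataset:
            d = compute_descriptors(rec.smiles)
            ok = (150.0 <= d.mw <= 400.0 and 0.0 <= d.logp <= 5.0
                  and 0 <= d.hbd <= 3 and 0 <= d.hba <= 6)
            if ok and rec.canonical_smiles not in seen:
                seen.add(rec.canonical_smiles)
                expect.append(rec.id)
        assert [r.id for r in survivors] == expect

    def test_order_independent_survivor_set(self, small_dataset, rng):
        crit = FilterCriteria(mw=(150.0, 400.0), logp=(0.0, 5.0), hbd=(0, 3), hba=(0, 6))
        a, _ = filter_library(small_dataset, crit)
        shuffled = [small_dataset[i] for i in rng.permutation(len(small_dataset))]
        b, _ = filter_library(shuffled, crit)
        assert {r.id for r in a} == {r.id for r in b}

    def test_unparsable_smiles_logged_not_fatal(self):
        recs = [MoleculeRecord(id="ok", smiles="CCO")]
        bad = MoleculeRecord.__new__(MoleculeRecord)
        bad.id, bad.smiles, bad.canonical_smiles = "bad", "C1CC", "C1CC"
        bad.ic50_nM = bad.label = bad.source = None
        survivors, log = filter_library(recs + [bad])
        assert ("bad", "parse_error") in log

    def test_invalid_criteria_rejected(self):
        with pytest.raises(ValueError):
            FilterCriteria(mw=(1500.0, 550.0))
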