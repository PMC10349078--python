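"""Curation filters, pActivity labelling, and the label-reversal split."""

import dataclasses

import numpy as np
import pytest

from seq2drug.dataset_builder import (
    ActivityRecord,
    CPISample,
    assign_label,
    build_dataset,
    clean_records,
    enforce_bilabel_compounds,
    filter_sizes,
    label_reversal_split,
    read_activity_table,
    read_split_tsv,
    records_to_samples,
    remove_conflicts,
    to_p_activity,
    write_splits,
)


def record(**kw) -> ActivityRecord:
    base = dict(compound_id="c1", smiles="CCO", target_id="t1", sequence="MKVLAW",
                activity_type="IC50", value_nM=100.0, confidence_score=9,
                assay_type="B", target_type="SINGLE PROTEIN",
                molecule_type="Small molecule", units="nM")
    base.update(kw)
    return ActivityRecord(**base)


class TestCleanRecords:
    def test_empty_list(self):
        assert clean_records([]) == []

    def test_synthetic_table_keeps_only_full_passes(self):
        # 10 records, exactly 4 satisfy every filter
        records = [
            record(),                                      # pass
            record(confidence_score=8),                    # fail: confidence
            record(assay_type="F"),                        # fail: assay
            record(activity_type="Kd"),                    # fail: activity type
            record(units="uM"),                            # fail: units
            record(target_type="PROTEIN COMPLEX"),         # fail: target type
            record(molecule_type="Antibody"),              # fail: molecule type
            record(value_nM=-5.0),                         # fail: nonpositive
            record(activity_type="EC50", value_nM=2.0),    # pass
            record(activity_type="Ki"),                    # pass
        ] + [record(value_nM=3.0)]                         # pass
        kept = clean_records(records)
        assert len(kept) == 4
        assert kept == [records[0], records[8], records[9], records[10]]

    def test_confidence_eight_removed(self):
        assert clean_records([record(confidence_score=8)]) == []


class TestPActivity:
    def test_micromolar_boundary(self):
        assert to_p_activity(1000.0) == 6.0

    def test_nanomolar(self):
        assert to_p_activity(1.0) == 9.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            to_p_activity(0.0)

    @pytest.mark.parametrize("p,label", [(6.6, 1), (6.4, 0), (6.5, 1)])
    def test_label_boundary_inclusive(self, p, label):
        assert assign_label(p) == label

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            assign_label(float("nan"))


class TestRemoveConflicts:
    def test_conflicting_pair_fully_removed(self):
        s = [CPISample("CCO", "MKV", 1, 7.0), CPISample("CCO", "MKV", 0, 5.0)]
        assert remove_conflicts(s) == []

    def test_duplicate_collapsed(self):
        s = [CPISample("CCO", "MKV", 1, 7.0), CPISample("CCO", "MKV", 1, 7.2)]
        assert remove_conflicts(s) == [s[0]]

    def test_six_sample_fixture_keeps_three(self):
        s = [
            CPISample("CCO", "MKV", 1, 7.0),   # conflict with next -> removed
            CPISample("CCO", "MKV", 0, 5.0),
            CPISample("CCN", "MKV", 1, 7.0),   # duplicate pair -> one kept
            CPISample("CCN", "MKV", 1, 7.1),
            CPISample("CCN", "ACD", 0, 5.0),   # kept
            CPISample("CCS", "ACD", 1, 8.0),   # kept
        ]
        assert len(remove_conflicts(s)) == 3


class TestFilterSizes:
    def test_boundaries_inclusive(self):
        keep = CPISample("C" * 60, "A" * 4000, 1, 7.0)
        assert filter_sizes([keep]) == [keep]

    def test_oversized_compound_dropped(self):
        assert filter_sizes([CPISample("C" * 61, "MKV", 1, 7.0)]) == []

    def test_oversized_protein_dropped(self):
        assert filter_sizes([CPISample("CCO", "A" * 4001, 1, 7.0)]) == []


class TestBilabel:
    def test_single_class_compound_removed(self):
        s = [CPISample("CCO", "MKV", 1, 7.0), CPISample("CCO", "ACD", 1, 7.5)]
        assert enforce_bilabel_compounds(s) == []

    def test_bilabel_compound_kept_whole(self):
        s = [CPISample("CCO", "MKV", 1, 7.0), CPISample("CCO", "ACD", 1, 7.5),
             CPISample("CCO", "WKD", 0, 5.0)]
        assert enforce_bilabel_compounds(s) == s

    def test_empty(self):
        assert enforce_bilabel_compounds([]) == []


def bilabel_world(n_compounds=20, n_proteins=8):
    """Deterministic fixture: every compound has positives and negatives."""
    samples = []
    for c in range(n_compounds):
        smiles = "C" * (c + 1)
        for p in range(n_proteins):
            seq = "ACDEFGHIKLMNPQRSTVWY"[p] * 5
            label = int((c + p) % 2 == 0)
            samples.append(CPISample(smiles, seq, label, 7.0 if label else 5.0))
    return samples


class TestLabelReversalSplit:
    def test_reversal_invariant_and_conservation(self):
        samples = bilabel_world()
        splits = label_reversal_split(samples, n_neg_ligands=3, n_pos_ligands=3, seed=42)
        assert len(splits.train) + len(splits.validation) + len(splits.test) == len(samples)
        assert splits.neg_reversal_ligands.isdisjoint(splits.pos_reversal_ligands)
        trainval = splits.train + splits.validation
        for s in splits.test:
            if s.compound_key in splits.neg_reversal_ligands:
                assert s.label == 0
            else:
                assert s.compound_key in splits.pos_reversal_ligands and s.label == 1
        for s in trainval:
            if s.compound_key in splits.neg_reversal_ligands:
                assert s.label == 1
            if s.compound_key in splits.pos_reversal_ligands:
                assert s.label == 0

    def test_expected_sizes_from_hand_count(self):
        samples = bilabel_world()
        splits = label_reversal_split(samples, 3, 3, seed=42)
        # independent recount from the returned ligand sets
        n_test = sum(1 for s in samples
                     if (s.compound_key in splits.neg_reversal_ligands and s.label == 0)
                     or (s.compound_key in splits.pos_reversal_ligands and s.label == 1))
        remainder = len(samples) - n_test
        assert len(splits.test) == n_test
        assert len(splits.validation) == remainder // 11
        assert len(splits.train) == remainder - remainder // 11

    def test_zero_reversal_ligands_gives_plain_split(self):
        samples = bilabel_world()
        splits = label_reversal_split(samples, 0, 0, seed=0)
        assert splits.test == []
        assert len(splits.validation) == len(samples) // 11

    def test_deterministic_under_seed(self):
        samples = bilabel_world()
        a = label_reversal_split(samples, 3, 3, seed=7)
        b = label_reversal_split(samples, 3, 3, seed=7)
        assert a == b

    def test_insufficient_compounds_rejected(self):
        with pytest.raises(ValueError, match="distinct compounds"):
            label_reversal_split(bilabel_world(n_compounds=4), 3, 3, seed=0)


def test_records_to_samples_canonicalizes_compound_keys():
    samples = records_to_samples([record(smiles="OCC"), record(smiles="CCO")])
    assert samples[0].compound_key == samples[1].compound_key


def test_pipeline_is_deterministic_and_file_stable(tmp_path):
    rows = []
    for c in range(5):
        for p in range(4):
            rows.append(record(
                compound_id=f"c{c}", smiles="C" * (c + 1),
                sequence="ACDEFGHIKLMNPQRSTVWY"[p] * 6,
                value_nM=10.0 ** (2 if (c + p) % 2 == 0 else 4),
                confidence_score=9 if (c + p) % 7 else 8))
    samples = build_dataset(rows)
    splits = label_reversal_split(samples, 1, 1, seed=3)
    for run in range(2):
        out = tmp_path / f"run{run}"
        write_splits(splits, out)
    for name in ("train.tsv", "validation.tsv", "test.tsv", "provenance.json"):
        assert (tmp_path / "run0" / name).read_bytes() == (tmp_path / "run1" / name).read_bytes()
    back = read_split_tsv(tmp_path / "run0" / "train.tsv")
    assert [s.compound_key for s in back] == [s.compound_key for s in splits.train]


def test_activity_table_roundtrip(tmp_path):
    import pandas as pd

    df = pd.DataFrame([dataclasses.asdict(record()), dataclasses.asdict(record(smiles="CCN"))])
    path = tmp_path / "acts.tsv"
    df.to_csv(path, sep="\t", index=False)
    records = read_activity_table(path)
    assert len(records) == 2 and records[1].smiles == "CCN"
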