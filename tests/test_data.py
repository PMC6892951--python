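"""Measurement-table parsing, labeling, allele filtering and CV splits."""

import numpy as np
import pytest

from pepconv.data import (
    BindingRecord,
    LabeledExample,
    SchemaError,
    SplitError,
    filter_alleles,
    label_record,
    label_records,
    read_measurement_table,
    shuffle_and_split,
    write_labeled_table,
    write_quarantine_report,
)
from pepconv.peptides import normalize_to_15mer

HEADER = (
    "allele\tpeptide\tmeasurement_value\tmeasurement_inequality\t"
    "measurement_type\tmeasurement_source\toriginal_allele\n"
)


def _table(tmp_path, rows, header=HEADER):
    f = tmp_path / "table.tsv"
    f.write_text(header + "".join(rows))
    return f


class TestReadTable:
    def test_clean_parse(self, tmp_path):
        f = _table(tmp_path, [
            "HLA-A*02:01\tSIINFEKL\t50\t=\tquantitative\tiedb\tHLA-A*02:01\n",
            "HLA-A*02:01\tACDEFGHIK\t900\t=\tquantitative\tiedb\tHLA-A*02:01\n",
            "HLA-B*27:05\tACDEFGHIKL\t\t=\teluted ligand\tms\tHLA-B*27:05\n",
        ])
        records = read_measurement_table(f)
        assert len(records) == 3
        assert records[0].measurement_value == 50.0
        assert records[2].measurement_value is None

    def test_csv_dialect(self, tmp_path):
        f = tmp_path / "table.csv"
        f.write_text("allele,peptide,measurement_value\nHLA-A*02:01,SIINFEKL,50\n")
        records = read_measurement_table(f)
        assert records[0].peptide == "SIINFEKL"

    def test_missing_mandatory_columns(self, tmp_path):
        f = tmp_path / "bad.tsv"
        f.write_text("allele\tmeasurement_value\nHLA-A*02:01\t50\n")
        with pytest.raises(SchemaError, match="peptide"):
            read_measurement_table(f)

    def test_header_only_gives_empty_list(self, tmp_path):
        assert read_measurement_table(_table(tmp_path, [])) == []


class TestLabelRecord:
    def _rec(self, **kw):
        base = dict(allele="HLA-A*02:01", peptide="SIINFEKL", measurement_value=50.0,
                    measurement_inequality="=", measurement_type="quantitative")
        base.update(kw)
        return BindingRecord(**base)

    @pytest.mark.parametrize("value,ineq,label", [
        (50.0, "=", 1),
        (500.0, "=", 1),      # boundary: <= threshold is a binder
        (501.0, "=", 0),
        (20000.0, ">", 0),
        (100.0, "<", 1),
    ])
    def test_quantitative_labels(self, value, ineq, label):
        out = label_record(self._rec(measurement_value=value, measurement_inequality=ineq))
        assert isinstance(out, LabeledExample) and out.label == label

    @pytest.mark.parametrize("value,ineq", [(1000.0, "<"), (100.0, ">")])
    def test_indeterminate_bounds_quarantined(self, value, ineq):
        out = label_record(self._rec(measurement_value=value, measurement_inequality=ineq))
        assert isinstance(out, str) and "indeterminate" in out

    def test_eluted_ligand_is_positive(self):
        out = label_record(self._rec(measurement_value=None, measurement_type="eluted ligand"))
        assert out.label == 1 and out.provenance == "EL"

    @pytest.mark.parametrize("term,label", [("Positive", 1), ("Positive-High", 1), ("Negative", 0)])
    def test_qualitative_terms(self, term, label):
        out = label_record(self._rec(measurement_value=None, measurement_type="qualitative",
                                     qualitative_measure=term))
        assert out.label == label

    def test_unmappable_qualitative_term_quarantined(self):
        out = label_record(self._rec(measurement_value=None, measurement_type="qualitative",
                                     qualitative_measure="maybe"))
        assert isinstance(out, str)

    def test_invalid_peptide_quarantined(self):
        out = label_record(self._rec(peptide="ACDEFB"))
        assert isinstance(out, str) and "validation" in out

    def test_custom_threshold(self):
        out = label_record(self._rec(measurement_value=800.0), threshold_nm=1000.0)
        assert out.label == 1


class TestLabelRecords:
    def test_every_row_is_retained_or_quarantined(self):
        records = [
            BindingRecord("HLA-A*02:01", "SIINFEKL", 50.0),
            BindingRecord("HLA-A*02:01", "BADPEP", 50.0),
            BindingRecord("HLA-A*02:01", "ACDEFGHIK", None, "=", "qualitative"),
        ]
        labeled, quarantine = label_records(records)
        assert len(labeled) + len(quarantine) == len(records)
        assert {q.row for q in quarantine} == {1, 2}

    def test_duplicates_prefer_quantitative_over_el(self):
        records = [
            BindingRecord("HLA-A*02:01", "SIINFEKL", None, "=", "eluted ligand"),
            BindingRecord("HLA-A*02:01", "SIINFEKL", 900.0, "=", "quantitative"),
        ]
        labeled, _ = label_records(records)
        assert len(labeled) == 1
        assert labeled[0].label == 0  # the quantitative (non-binder) row wins


def _examples(allele, n, label=1):
    return [
        LabeledExample(allele, normalize_to_15mer("ACDEFGHIK"), label, "BA")
        for _ in range(n)
    ]


class TestFilterAlleles:
    def test_strictly_more_than_min_count_survives(self):
        examples = _examples("KEEP", 21) + _examples("DROP", 20)
        retained, summary = filter_alleles(examples, min_count=20)
        assert {ex.allele for ex in retained} == {"KEEP"}
        assert summary.allele_counts == {"KEEP": 21}
        assert summary.retained == 21 and summary.total == 41

    def test_all_below_threshold_gives_empty(self):
        retained, summary = filter_alleles(_examples("A", 5), min_count=20)
        assert retained == [] and summary.retained == 0 and summary.positives == 0

    def test_label_totals_conserved(self):
        examples = _examples("A", 15, label=1) + _examples("A", 10, label=0)
        retained, summary = filter_alleles(examples, min_count=20)
        negatives = sum(1 for ex in retained if ex.label == 0)
        assert summary.positives + negatives == summary.retained == 25

    def test_length_frequencies_recorded(self):
        examples = _examples("A", 21)
        _, summary = filter_alleles(examples, min_count=20)
        assert summary.allele_length_counts["A"] == {9: 21}


class TestShuffleAndSplit:
    def test_even_split(self):
        folds = shuffle_and_split(10, k=5, seed=0)
        assert sorted(len(f) for f in folds) == [2, 2, 2, 2, 2]

    def test_remainder_goes_to_earliest_folds(self):
        folds = shuffle_and_split(11, k=5, seed=0)
        assert [len(f) for f in folds] == [3, 2, 2, 2, 2]

    def test_partition_property(self):
        folds = shuffle_and_split(53, k=5, seed=3)
        combined = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(combined, np.arange(53))

    def test_same_seed_identical_folds(self):
        a = shuffle_and_split(40, k=5, seed=7)
        b = shuffle_and_split(40, k=5, seed=7)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa, fb)

    def test_too_few_examples_rejected(self):
        with pytest.raises(SplitError):
            shuffle_and_split(3, k=5, seed=0)

    def test_k_below_two_rejected(self):
        with pytest.raises(SplitError):
            shuffle_and_split(10, k=1, seed=0)

    def test_stratified_folds_balance_classes(self):
        labels = [1] * 10 + [0] * 40
        folds = shuffle_and_split(50, k=5, seed=0, labels=labels)
        y = np.array(labels)
        for f in folds:
            assert y[f].sum() == 2


class TestOutputs:
    def test_labeled_and_quarantine_tables(self, tmp_path):
        labeled, quarantine = label_records([
            BindingRecord("HLA-A*02:01", "SIINFEKL", 50.0),
            BindingRecord("HLA-A*02:01", "BADPEP", 50.0),
        ])
        out = tmp_path / "labeled.tsv"
        qout = tmp_path / "quarantine.tsv"
        write_labeled_table(labeled, out)
        write_quarantine_report(quarantine, qout)
        assert "SIINXFEKL" in out.read_text()  # 8mer frame: gap at position 5
        assert "BADPEP" in qout.read_text()
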