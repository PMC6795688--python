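"""Summary-statistic I/O, harmonization and the sample-overlap audit."""
import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from bodymr.exceptions import ConfigurationError, InputError
from bodymr.gwas_io import (CohortOverlapTable, DIALECTS, SummaryDataset,
                            harmonize, read_summary, sample_overlap,
                            write_summary)
from tests.conftest import summary_text


class TestReadSummary:
    def test_alleles_are_uppercased(self):
        ds = read_summary(summary_text([("rs1", 1, 1000, "a", "g", 0.30,
                                         0.05, 0.01, 1e-9, 50000)]))
        rec = ds.get("rs1")
        assert (rec["effect_allele"], rec["other_allele"]) == ("A", "G")

    def test_invalid_rows_dropped_and_counted(self):
        ds = read_summary(summary_text([
            ("rs1", 1, 1000, "A", "G", 0.3, 0.05, 0.01, 1e-9, 50000),
            ("rs2", 1, 2000, "A", "G", 0.3, 0.05, 0.0, 1e-9, 50000),   # se = 0
            ("rs3", 1, 3000, "A", "A", 0.3, 0.05, 0.01, 1e-9, 50000),  # same alleles
            ("rs4", 1, 4000, "A", "G", 1.3, 0.05, 0.01, 1e-9, 50000),  # eaf > 1
            ("rs5", 1, 5000, "A", "G", 0.3, 0.05, 0.01, 0.0, 50000),   # p = 0
        ]))
        assert len(ds) == 1
        assert ds.parse_report.dropped == {
            "invalid_se": 1, "invalid_alleles": 1, "invalid_eaf": 1,
            "invalid_pvalue": 1}

    def test_missing_required_column_is_config_error(self):
        txt = io.StringIO("SNP\tCHR\tPOS\tEA\tOA\tEAF\tBETA\tSE\tN\nrs1\t1\t1\tA\tG\t.3\t.1\t.01\t5\n")
        with pytest.raises(ConfigurationError):
            read_summary(txt)

    def test_zero_valid_rows_is_input_error(self):
        with pytest.raises(InputError):
            read_summary(summary_text([("rs1", 1, 1, "A", "G", 0.3, 0.1, 0.0, 1e-9, 5)]))

    def test_missing_eaf_tolerated(self):
        ds = read_summary(summary_text([("rs1", 1, 1, "A", "G", "NA", 0.1, 0.01, 1e-9, "NA")]))
        assert np.isnan(ds.get("rs1")["eaf"])

    def test_named_dialects_cover_all_required_fields(self):
        for name, mapping in DIALECTS.items():
            missing = {"snp_id", "chrom", "pos", "effect_allele",
                       "other_allele", "beta", "se", "pvalue"} - set(mapping)
            assert not missing, f"{name} lacks {missing}"


class TestRoundTrip:
    def test_write_read_identity(self, tmp_path):
        ds = read_summary(summary_text([
            ("rs1", 1, 1000, "A", "G", 0.30, 0.05, 0.01, 1e-9, 50000),
            ("rs2", 2, 2000, "C", "T", "NA", -0.02, 0.02, 0.5, 40000),
            ("rs3", "X", 3000, "A", "T", 0.10, 0.00, 0.03, 0.9, "NA"),
        ]), trait="bmi", sd_per_unit=4.69)
        path = tmp_path / "out.tsv"
        write_summary(ds, path)
        back = read_summary(path, trait="bmi", sd_per_unit=4.69)
        pd.testing.assert_frame_equal(ds.records, back.records)

    def test_empty_dataset_writes_header_only(self, tmp_path):
        ds = SummaryDataset(trait="t", trait_type="continuous",
                            records=pd.DataFrame(columns=[
                                "snp_id", "chrom", "pos", "effect_allele",
                                "other_allele", "eaf", "beta", "se",
                                "pvalue", "n"]))
        path = tmp_path / "empty.tsv"
        write_summary(ds, path)
        assert path.read_text().count("\n") == 1

    def test_single_record_writes_two_lines(self, tmp_path):
        ds = read_summary(summary_text([("rs1", 1, 1, "A", "G", 0.3, 0.1, 0.01, 1e-9, 5)]))
        path = tmp_path / "one.tsv"
        write_summary(ds, path)
        assert path.read_text().count("\n") == 2


def _dataset(rows):
    return read_summary(summary_text(rows), trait="t")


class TestHarmonize:
    def _pair(self, exp_row, out_row):
        return _dataset([exp_row]), _dataset([out_row])

    def test_matching_alleles_copied(self):
        e, o = self._pair(("rs1", 1, 1, "A", "G", 0.3, 0.10, 0.01, 1e-9, 100),
                          ("rs1", 1, 1, "A", "G", 0.3, 0.05, 0.02, 1e-4, 100))
        table, rep = harmonize(e, o, ["rs1"])
        assert rep.counts()["harmonized"] == 1
        assert table.loc[0, "beta_outcome"] == 0.05

    def test_swapped_alleles_negate_beta_and_flip_eaf(self):
        e, o = self._pair(("rs1", 1, 1, "A", "G", 0.3, 0.10, 0.01, 1e-9, 100),
                          ("rs1", 1, 1, "G", "A", 0.7, 0.05, 0.02, 1e-4, 100))
        table, _ = harmonize(e, o, ["rs1"])
        assert table.loc[0, "beta_outcome"] == -0.05

    @pytest.mark.parametrize("eaf_exp,eaf_out", [(0.50, 0.50), (0.45, 0.30),
                                                 (0.30, 0.44)])
    def test_ambiguous_palindrome_dropped(self, eaf_exp, eaf_out):
        e, o = self._pair(("rs1", 1, 1, "A", "T", eaf_exp, 0.10, 0.01, 1e-9, 100),
                          ("rs1", 1, 1, "A", "T", eaf_out, 0.05, 0.02, 1e-4, 100))
        _, rep = harmonize(e, o, ["rs1"])
        assert rep.ambiguous == ["rs1"]

    def test_palindrome_missing_eaf_is_ambiguous(self):
        e, o = self._pair(("rs1", 1, 1, "C", "G", 0.2, 0.10, 0.01, 1e-9, 100),
                          ("rs1", 1, 1, "C", "G", "NA", 0.05, 0.02, 1e-4, 100))
        _, rep = harmonize(e, o, ["rs1"])
        assert rep.ambiguous == ["rs1"]

    @pytest.mark.parametrize("eaf_out,expected_beta", [
        (0.22, 0.05),    # same side of 0.5: same strand labelling
        (0.80, -0.05),   # opposite sides: strand-flipped labelling
    ])
    def test_unambiguous_palindrome_aligned_by_eaf(self, eaf_out, expected_beta):
        e, o = self._pair(("rs1", 1, 1, "A", "T", 0.20, 0.10, 0.01, 1e-9, 100),
                          ("rs1", 1, 1, "A", "T", eaf_out, 0.05, 0.02, 1e-4, 100))
        table, rep = harmonize(e, o, ["rs1"])
        assert rep.harmonized == ["rs1"]
        assert table.loc[0, "beta_outcome"] == pytest.approx(expected_beta)

    def test_incompatible_alleles_mismatched(self):
        e, o = self._pair(("rs1", 1, 1, "A", "G", 0.3, 0.10, 0.01, 1e-9, 100),
                          ("rs1", 1, 1, "A", "C", 0.3, 0.05, 0.02, 1e-4, 100))
        _, rep = harmonize(e, o, ["rs1"])
        assert rep.mismatched == ["rs1"]

    def test_strand_flipped_outcome_still_aligns(self):
        # outcome reported on the opposite strand: A/G vs T/C
        e, o = self._pair(("rs1", 1, 1, "A", "G", 0.3, 0.10, 0.01, 1e-9, 100),
                          ("rs1", 1, 1, "T", "C", 0.3, 0.05, 0.02, 1e-4, 100))
        table, rep = harmonize(e, o, ["rs1"])
        assert rep.harmonized == ["rs1"]
        assert table.loc[0, "beta_outcome"] == 0.05

    def test_absent_snp_needs_proxy(self):
        e = _dataset([("rs1", 1, 1, "A", "G", 0.3, 0.10, 0.01, 1e-9, 100)])
        o = _dataset([("rs9", 1, 9, "A", "G", 0.3, 0.05, 0.02, 1e-4, 100)])
        _, rep = harmonize(e, o, ["rs1"])
        assert rep.absent == ["rs1"]

    def test_every_snp_lands_in_exactly_one_category(self):
        e = _dataset([
            ("rs1", 1, 1, "A", "G", 0.3, 0.1, 0.01, 1e-9, 100),
            ("rs2", 1, 2, "A", "T", 0.5, 0.1, 0.01, 1e-9, 100),
            ("rs3", 1, 3, "A", "G", 0.3, 0.1, 0.01, 1e-9, 100),
            ("rs4", 1, 4, "C", "T", 0.3, 0.1, 0.01, 1e-9, 100),
        ])
        o = _dataset([
            ("rs1", 1, 1, "G", "A", 0.7, 0.1, 0.01, 1e-9, 100),
            ("rs2", 1, 2, "A", "T", 0.5, 0.1, 0.01, 1e-9, 100),
            ("rs4", 1, 4, "C", "A", 0.3, 0.1, 0.01, 1e-9, 100),
        ])
        _, rep = harmonize(e, o)
        cats = rep.harmonized + rep.ambiguous + rep.mismatched + rep.absent
        assert sorted(cats) == ["rs1", "rs2", "rs3", "rs4"]
        assert len(set(cats)) == 4

    def test_harmonization_is_idempotent(self):
        """Re-harmonizing the already-aligned pair changes nothing."""
        e = _dataset([("rs1", 1, 1, "A", "G", 0.3, 0.10, 0.01, 1e-9, 100)])
        o = _dataset([("rs1", 1, 1, "G", "A", 0.7, 0.05, 0.02, 1e-4, 100)])
        t1, _ = harmonize(e, o, ["rs1"])
        aligned = o.records.copy()
        aligned.loc[0, ["effect_allele", "other_allele"]] = ["A", "G"]
        aligned.loc[0, "beta"] = t1.loc[0, "beta_outcome"]
        aligned.loc[0, "eaf"] = 0.3
        o2 = SummaryDataset(trait="t", trait_type="continuous", records=aligned)
        t2, _ = harmonize(e, o2, ["rs1"])
        pd.testing.assert_frame_equal(t1, t2)

    @given(beta=st.floats(-1, 1, allow_nan=False), eaf=st.floats(0.01, 0.99))
    def test_allele_swap_involution(self, beta, eaf):
        """Swapping outcome allele labels (negate beta, eaf -> 1-eaf) yields
        the same harmonized record; f + f' = 1 by construction."""
        e = _dataset([("rs1", 1, 1, "A", "G", 0.3, 0.10, 0.01, 1e-9, 100)])
        o_fwd = _dataset([("rs1", 1, 1, "A", "G", eaf, beta, 0.02, 0.5, 100)])
        o_swp = _dataset([("rs1", 1, 1, "G", "A", 1 - eaf, -beta, 0.02, 0.5, 100)])
        t1, _ = harmonize(e, o_fwd, ["rs1"])
        t2, _ = harmonize(e, o_swp, ["rs1"])
        assert t1.loc[0, "beta_outcome"] == pytest.approx(t2.loc[0, "beta_outcome"])

    def test_requested_snp_must_be_in_exposure(self):
        e = _dataset([("rs1", 1, 1, "A", "G", 0.3, 0.1, 0.01, 1e-9, 100)])
        with pytest.raises(InputError):
            harmonize(e, e, ["rs_missing"])


class TestSampleOverlap:
    def _table(self, counts, totals):
        return CohortOverlapTable(
            counts=pd.DataFrame(counts),
            totals=pd.Series(totals))

    def test_bmi_overlap_from_published_cohort_counts(self):
        # AGES-RS, CHS, FHS, KORA F4 against the 322,154-person BMI GWAS
        t = self._table({"BMI": [3207, 3228, 8904, 1811]}, {"BMI": 322154})
        assert sample_overlap(t)["BMI"] == 5.32

    def test_zero_overlap_column(self):
        t = self._table({"WHR": [0, 0, 0, 0]}, {"WHR": 210088})
        assert sample_overlap(t)["WHR"] == 0.0

    def test_simple_fraction(self):
        t = self._table({"d": [50]}, {"d": 1000})
        assert sample_overlap(t)["d"] == 5.0

    def test_zero_total_is_input_error(self):
        t = self._table({"d": [5]}, {"d": 0})
        with pytest.raises(InputError):
            sample_overlap(t)

    def test_negative_counts_rejected(self):
        with pytest.raises(InputError):
            self._table({"d": [-1]}, {"d": 10})
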