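"""Summary-statistic table I/O, the built-in instrument fixture, and reports."""

import json

import pytest

from summr import (AnalysisReport, DuplicateSnpError, ExposureAssociation,
                   FormatError, OutcomeAssociation, Pathway, Subtype,
                   VocabularyError, builtin_sunlight_instruments,
                   read_exposure_table, read_outcome_table, read_report,
                   write_exposure_table, write_outcome_table, write_report)
from summr.summary_io import group_outcomes

EXPOSURE_HEADER = "snp_id\tchrom\tposition\teffect_allele\tother_allele\tbeta\tse\tf_stat\tlocus\tpathway\teaf\n"

TABLE1_TSV = EXPOSURE_HEADER + (
    "rs2282679\t4\t72608383\tG\tT\t-0.047\t0.013\t13.38\tGC\tmetabolism\t\n"
    "rs10741657\t11\t14914878\tG\tA\t-0.052\t0.012\t18.78\tCYP2R1\tsynthesis\t\n"
    "rs12785878\t11\t71167449\tG\tT\t-0.056\t0.013\t18.29\tDHCR7\tsynthesis\t\n"
    "rs6013897\t20\t52742479\tA\tT\t-0.027\t0.015\t3.13\tCYP24A1\tmetabolism\t\n"
)


class TestReadExposureTable:
    def test_transcribed_instrument_table(self, tmp_path):
        p = tmp_path / "exp.tsv"
        p.write_text(TABLE1_TSV)
        recs = read_exposure_table(p)
        assert len(recs) == 4
        gc = {r.snp_id: r for r in recs}["rs2282679"]
        assert gc.beta_exposure == pytest.approx(-0.047)
        assert gc.se_exposure == pytest.approx(0.013)
        assert gc.f_stat == pytest.approx(13.38)
        assert gc.pathway is Pathway.METABOLISM

    def test_header_only_gives_empty_list(self, tmp_path):
        p = tmp_path / "exp.tsv"
        p.write_text(EXPOSURE_HEADER)
        assert read_exposure_table(p) == []

    def test_zero_se_row_is_named(self, tmp_path):
        p = tmp_path / "exp.tsv"
        p.write_text(EXPOSURE_HEADER
                     + "rs1\t1\t100\tA\tG\t0.1\t0.01\t\t\t\t\n"
                     + "rs2\t1\t200\tA\tG\t0.1\t0\t\t\t\t\n")
        with pytest.raises(FormatError, match="row 2"):
            read_exposure_table(p)

    def test_missing_mandatory_column_is_named(self, tmp_path):
        p = tmp_path / "exp.tsv"
        p.write_text("snp_id\tchrom\tposition\teffect_allele\tother_allele\tbeta\n"
                     "rs1\t1\t100\tA\tG\t0.1\n")
        with pytest.raises(FormatError, match="'se'"):
            read_exposure_table(p)

    def test_duplicate_snp_rejected(self, tmp_path):
        p = tmp_path / "exp.tsv"
        row = "rs1\t1\t100\tA\tG\t0.1\t0.01\t\t\t\t\n"
        p.write_text(EXPOSURE_HEADER + row + row)
        with pytest.raises(DuplicateSnpError, match="rs1"):
            read_exposure_table(p)

    def test_alleles_uppercased(self, tmp_path):
        p = tmp_path / "exp.tsv"
        p.write_text(EXPOSURE_HEADER + "rs1\t1\t100\ta\tg\t0.1\t0.01\t\t\t\t\n")
        rec = read_exposure_table(p)[0]
        assert (rec.effect_allele, rec.other_allele) == ("A", "G")

    def test_dialect_column_mapping(self, tmp_path):
        p = tmp_path / "exp.tsv"
        p.write_text("SNP\tCHR\tBP\tA1\tA2\tBETA\tSE\n"
                     "rs1\t1\t100\tA\tG\t0.1\t0.01\n")
        recs = read_exposure_table(p, dialect={
            "snp_id": "SNP", "chrom": "CHR", "position": "BP",
            "effect_allele": "A1", "other_allele": "A2",
            "beta_exposure": "BETA", "se_exposure": "SE"})
        assert recs[0].snp_id == "rs1" and recs[0].se_exposure == 0.01


class TestReadOutcomeTable:
    def _write(self, path, rows, header="snp_id\teffect_allele\tother_allele\tbeta\tse\tcohort\tsubtype\teaf\n"):
        path.write_text(header + "".join(rows))

    def test_eight_cohorts_grouped(self, tmp_path):
        p = tmp_path / "out.tsv"
        rows = [f"rs{k}\tA\tG\t0.01\t0.05\tC{c}\tall_glioma\t0.3\n"
                for c in range(8) for k in range(4)]
        self._write(p, rows)
        recs = read_outcome_table(p)
        assert len(recs) == 32
        groups = group_outcomes(recs)
        assert len(groups) == 8
        assert all(len(v) == 4 for v in groups.values())

    def test_subtype_constant_propagates(self, tmp_path):
        p = tmp_path / "out.tsv"
        p.write_text("snp_id\teffect_allele\tother_allele\tbeta\tse\n"
                     "rs1\tA\tG\t0.01\t0.05\n")
        recs = read_outcome_table(p, cohort="UK", subtype="GBM")
        assert recs[0].subtype is Subtype.GBM and recs[0].cohort == "UK"

    def test_out_of_range_eaf_rejected(self, tmp_path):
        p = tmp_path / "out.tsv"
        self._write(p, ["rs1\tA\tG\t0.01\t0.05\tUK\tall_glioma\t1.2\n"])
        with pytest.raises(FormatError, match="eaf"):
            read_outcome_table(p)

    def test_unknown_subtype_is_vocabulary_error(self, tmp_path):
        p = tmp_path / "out.tsv"
        self._write(p, ["rs1\tA\tG\t0.01\t0.05\tUK\tastro\t0.3\n"])
        with pytest.raises(VocabularyError, match="astro"):
            read_outcome_table(p)

    def test_negative_se_rejected(self, tmp_path):
        p = tmp_path / "out.tsv"
        self._write(p, ["rs1\tA\tG\t0.01\t-0.05\tUK\tall_glioma\t0.3\n"])
        with pytest.raises(FormatError, match="se_outcome"):
            read_outcome_table(p)


class TestBuiltinInstruments:
    EXPECTED = {
        "rs2282679": (-0.047, 0.013, 13.38, "GC", Pathway.METABOLISM),
        "rs10741657": (-0.052, 0.012, 18.78, "CYP2R1", Pathway.SYNTHESIS),
        "rs12785878": (-0.056, 0.013, 18.29, "DHCR7", Pathway.SYNTHESIS),
        "rs6013897": (-0.027, 0.015, 3.13, "CYP24A1", Pathway.METABOLISM),
    }

    @pytest.mark.parametrize("snp_id", sorted(EXPECTED))
    def test_values(self, snp_id):
        rec = {r.snp_id: r for r in builtin_sunlight_instruments()}[snp_id]
        beta, se, f, locus, pathway = self.EXPECTED[snp_id]
        assert rec.beta_exposure == beta
        assert rec.se_exposure == se
        assert rec.f_stat == f
        assert locus in rec.locus
        assert rec.pathway is pathway

    def test_all_betas_negative_decreasing_allele_convention(self):
        assert all(r.beta_exposure < 0 for r in builtin_sunlight_instruments())

    def test_stable_across_calls(self):
        assert builtin_sunlight_instruments() == builtin_sunlight_instruments()

    def test_no_frequencies_attached(self):
        assert all(r.eaf is None for r in builtin_sunlight_instruments())


class TestRecordInvariants:
    def test_identical_alleles_rejected(self):
        with pytest.raises(FormatError):
            ExposureAssociation("rs1", "1", 1, "A", "A", 0.1, 0.01)

    def test_non_acgt_allele_rejected(self):
        with pytest.raises(FormatError):
            OutcomeAssociation("rs1", "N", "G", 0.1, 0.01, cohort="UK")

    def test_empty_cohort_rejected(self):
        with pytest.raises(FormatError):
            OutcomeAssociation("rs1", "A", "G", 0.1, 0.01, cohort="")


class TestRoundTrip:
    def test_exposure_write_read_lossless(self, tmp_path, rng):
        recs = [ExposureAssociation(f"rs{i}", "2", 1000 + i, "A", "G",
                                    float(rng.normal(-0.05, 0.01)),
                                    float(rng.uniform(0.005, 0.02)),
                                    f_stat=float(rng.uniform(1, 30)),
                                    eaf=float(rng.uniform(0.1, 0.9)))
                for i in range(6)]
        p = tmp_path / "exp.tsv"
        write_exposure_table(recs, p)
        assert read_exposure_table(p) == recs

    def test_outcome_write_read_lossless(self, tmp_path, rng):
        recs = [OutcomeAssociation(f"rs{i}", "T", "C", float(rng.normal(0, 0.05)),
                                   float(rng.uniform(0.01, 0.1)), cohort="UK",
                                   subtype=Subtype.GBM, eaf=0.25)
                for i in range(5)]
        p = tmp_path / "out.tsv"
        write_outcome_table(recs, p)
        assert read_outcome_table(p) == recs


class TestReport:
    def _report(self):
        return AnalysisReport(
            provenance={"seed": 1, "config_hash": "abc"},
            estimates=[{"subtype": "all_glioma", "method": "IVW", "n_snps": 4,
                        "beta": 0.189, "se": 0.148, "or": 1.208, "ci_low": 0.904,
                        "ci_high": 1.615, "p": 0.201}],
            egger=[{"subtype": "all_glioma",
                    "slope": {"estimate": 0.07, "se": 0.1, "ci_low": -0.12,
                              "ci_high": 0.26, "p": 0.47},
                    "intercept": {"estimate": -0.001, "se": 0.009, "ci_low": -0.019,
                                  "ci_high": 0.017, "p": 0.89}}],
            forest=[{"subtype": "all_glioma", "method": "IVW", "cohort": "UK",
                     "or": 1.2, "ci_low": 0.8, "ci_high": 1.8, "weight": 1.0}],
            harmonization_log=[{"snp_id": "rs1", "cohort": "UK",
                                "subtype": "all_glioma", "action": "kept_as_is",
                                "reason": ""}],
        )

    def test_json_round_trip_is_identity(self, tmp_path):
        rep = self._report()
        p = tmp_path / "report.json"
        write_report(rep, p, "json")
        assert read_report(p) == rep

    def test_tsv_has_one_row_per_method_subtype(self, tmp_path):
        p = tmp_path / "report.tsv"
        write_report(self._report(), p, "tsv")
        text = p.read_text()
        section = text.split("## estimates")[1].split("##")[0].strip().splitlines()
        assert len(section) == 2  # header + one data row
        assert "all_glioma\tIVW\t4\t0.189\t0.148\t1.21" in section[1]

    def test_absent_sections_marked_not_erroring(self, tmp_path):
        p = tmp_path / "report.tsv"
        write_report(self._report(), p, "tsv")  # sensitivity/power left None
        text = p.read_text()
        assert "## sensitivity\n(absent)" in text
        assert "## power\n(absent)" in text

    def test_reported_or_consistent_with_beta(self):
        import math
        rep = self._report()
        for row in rep.estimates:
            assert abs(row["or"] - math.exp(row["beta"])) < 0.01  # display rounding
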