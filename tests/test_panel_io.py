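"""Panel/genotype I/O, allele alignment and weight classification."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from grscore import (PanelError, SnpPanelRecord, align_alleles, classify_weight,
                     default_panel_path, is_palindromic, read_genotypes,
                     read_panel, read_vcf_dosages, write_panel)


def make_record(effect="G", other="A", **kw):
    defaults = dict(gene="FTO", rsid="rs1", effect_allele=effect,
                    other_allele=other, eaf=0.3)
    defaults.update(kw)
    return SnpPanelRecord(**defaults)


class TestPanelReading:
    def test_packaged_panel_composition(self, panel):
        assert len(panel) == 28
        assert sum(r.in_ea_set for r in panel) == 24
        assert sum(r.in_eaa_set for r in panel) == 11
        assert sum(r.in_ea_set and r.in_eaa_set for r in panel) == 7
        fto = {r.rsid: r for r in panel}["rs9939609"]
        assert fto.gene == "FTO"
        assert fto.eaf == pytest.approx(0.11)

    def test_round_trip_byte_identical(self, panel, tmp_path):
        out = tmp_path / "panel.tsv"
        write_panel(panel, out)
        assert out.read_text() == default_panel_path().read_text()

    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text("gene\trsid\teffect_allele\tother_allele\teaf\n")
        assert read_panel(p) == []

    def test_duplicate_rsid_rejected(self, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text("gene\trsid\teffect_allele\tother_allele\teaf\n"
                     "FTO\trs1\tA\tG\t0.2\nMC4R\trs1\tC\tT\t0.3\n")
        with pytest.raises(PanelError, match="rs1"):
            read_panel(p)

    @pytest.mark.parametrize("bad_row", [
        "FTO\trs1\tA\tG\t1.2",   # eaf out of range
        "FTO\trs1\tX\tG\t0.2",   # unknown allele
        "FTO\trs1\tA\tA\t0.2",   # identical alleles
    ])
    def test_invalid_records_rejected(self, tmp_path, bad_row):
        p = tmp_path / "p.tsv"
        p.write_text("gene\trsid\teffect_allele\tother_allele\teaf\n"
                     + bad_row + "\n")
        with pytest.raises(PanelError):
            read_panel(p)


class TestGenotypeReading:
    def _write(self, tmp_path, header, rows):
        p = tmp_path / "g.tsv"
        p.write_text("\t".join(header) + "\n"
                     + "".join("\t".join(r) + "\n" for r in rows))
        return p

    def test_basic_matrix(self, tmp_path):
        panel = [make_record(rsid="rs1"), make_record(rsid="rs2")]
        path = self._write(tmp_path, ["individual_id", "rs1", "rs2"],
                           [["a", "1", "1"], ["b", "1", "1"], ["c", "1", "1"]])
        gm = read_genotypes(path, panel)
        assert gm.dosage.shape == (3, 2)
        assert (gm.dosage == 1).all()

    def test_missing_token_and_bad_dosage(self, tmp_path):
        panel = [make_record(rsid="rs1")]
        path = self._write(tmp_path, ["individual_id", "rs1"],
                           [["a", "NA"], ["b", "2"]])
        gm = read_genotypes(path, panel)
        assert np.isnan(gm.dosage[0, 0]) and gm.dosage[1, 0] == 2
        bad = self._write(tmp_path, ["individual_id", "rs1"], [["a", "3"]])
        with pytest.raises(PanelError, match="rs1"):
            read_genotypes(bad, panel)

    def test_unknown_column_dropped_with_warning(self, tmp_path):
        panel = [make_record(rsid="rs1")]
        path = self._write(tmp_path, ["individual_id", "rs1", "rs999"],
                           [["a", "1", "2"]])
        with pytest.warns(UserWarning, match="rs999"):
            gm = read_genotypes(path, panel)
        assert gm.snp_ids == ["rs1"]
        assert gm.dosage[0, 0] == 1


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=1>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
)


class TestVcfIngestion:
    def _vcf(self, tmp_path, body):
        p = tmp_path / "in.vcf"
        p.write_text(VCF_HEADER + body)
        return p

    def test_orientation_and_missing(self, tmp_path):
        panel = [make_record(rsid="rs1", effect="G", other="A")]
        # ALT is the effect allele: dosage = ALT count; ./. -> missing
        path = self._vcf(tmp_path, "1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/1\t./.\n")
        gm = read_vcf_dosages(path, panel)
        assert gm.dosage[0, 0] == 1
        assert np.isnan(gm.dosage[1, 0])

    def test_flipped_orientation(self, tmp_path):
        # REF is the effect allele: homozygous ALT -> dosage 0
        panel = [make_record(rsid="rs1", effect="G", other="A")]
        path = self._vcf(tmp_path, "1\t100\trs1\tG\tA\t.\t.\t.\tGT\t1/1\t0/1\n")
        gm = read_vcf_dosages(path, panel)
        assert gm.dosage[0, 0] == 0
        assert gm.dosage[1, 0] == 1

    def test_allele_mismatch_is_error(self, tmp_path):
        panel = [make_record(rsid="rs1", effect="G", other="A")]
        path = self._vcf(tmp_path, "1\t100\trs1\tC\tT\t.\t.\t.\tGT\t0/1\t0/0\n")
        with pytest.raises(PanelError, match="rs1"):
            read_vcf_dosages(path, panel)

    def test_palindromic_site_flagged(self, tmp_path):
        panel = [make_record(rsid="rs1", effect="T", other="A")]
        path = self._vcf(tmp_path, "1\t100\trs1\tA\tT\t.\t.\t.\tGT\t0/1\t1/1\n")
        gm = read_vcf_dosages(path, panel)
        assert gm.strand_ambiguous == {"rs1"}
        assert gm.dosage[0, 0] == 1 and gm.dosage[1, 0] == 2


class TestAlignAlleles:
    @pytest.mark.parametrize("ref,alt,alt_count,expected", [
        ("A", "G", 2, 2), ("A", "G", 1, 1), ("A", "G", 0, 0),
        ("G", "A", 2, 0), ("G", "A", 1, 1), ("G", "A", 0, 2),
    ])
    def test_hand_enumerated_orientations(self, ref, alt, alt_count, expected):
        rec = make_record(effect="G", other="A")
        assert align_alleles(rec, ref, alt, alt_count).dosage == expected

    def test_allele_set_mismatch(self):
        rec = make_record(effect="G", other="A")
        with pytest.raises(PanelError):
            align_alleles(rec, "C", "T", 1)

    def test_palindromic_flag(self):
        rec = make_record(effect="T", other="A")
        res = align_alleles(rec, "A", "T", 1)
        assert res.strand_ambiguous
        assert not align_alleles(make_record(), "A", "G", 1).strand_ambiguous
        assert is_palindromic(make_record(effect="C", other="G"))

    @given(st.integers(min_value=0, max_value=2))
    def test_both_orientations_agree(self, k):
        # the same genotype seen as k ALT alleles or 2-k ALT alleles on the
        # swapped orientation must yield one dosage
        rec = make_record(effect="G", other="A")
        assert (align_alleles(rec, "A", "G", k).dosage
                == align_alleles(rec, "G", "A", 2 - k).dosage)


class TestClassifyWeight:
    @pytest.mark.parametrize("bmi,expected", [
        (23.9, "normal"), (24.0, "overweight"), (27.999, "overweight"),
        (28.0, "obese"), (18.0, "normal"), (35.0, "obese"),
    ])
    def test_chinese_cutoffs(self, bmi, expected):
        assert classify_weight(bmi) == expected

    @pytest.mark.parametrize("bad", [0.0, -1.0, float("nan"), float("inf")])
    def test_invalid_bmi(self, bad):
        with pytest.raises(PanelError):
            classify_weight(bad)

    @given(st.floats(min_value=1e-6, max_value=200, allow_nan=False))
    def test_partition(self, bmi):
        # every positive finite BMI maps to exactly one of the three classes
        assert classify_weight(bmi) in ("normal", "overweight", "obese")
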