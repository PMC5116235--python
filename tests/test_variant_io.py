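import pytest

from varburden.variant_io import (
    CONSEQUENCE_VOCABULARY,
    CaseVariant,
    ReferenceSite,
    VariantClass,
    classify_consequence,
    read_case_table,
    read_reference_table,
    write_case_table,
)


class TestClassifyConsequence:
    @pytest.mark.parametrize(
        "term,expected",
        [
            ("frameshift", VariantClass.TRUNCATING),
            ("frameshift_variant", VariantClass.TRUNCATING),
            ("nonsense", VariantClass.TRUNCATING),
            ("stop_gained", VariantClass.TRUNCATING),
            ("stop gained", VariantClass.TRUNCATING),
            ("splice_donor_variant", VariantClass.TRUNCATING),
            ("splice_acceptor_variant", VariantClass.TRUNCATING),
            ("missense", VariantClass.NONTRUNCATING),
            ("missense_variant", VariantClass.NONTRUNCATING),
            ("inframe_insertion", VariantClass.NONTRUNCATING),
            ("inframe_deletion", VariantClass.NONTRUNCATING),
            ("synonymous", VariantClass.EXCLUDED),
            ("synonymous_variant", VariantClass.EXCLUDED),
            ("intron_variant", VariantClass.EXCLUDED),
            ("5_prime_utr_variant", VariantClass.EXCLUDED),
        ],
    )
    def test_known_terms(self, term, expected):
        assert classify_consequence(term) is expected

    @pytest.mark.parametrize(
        "term,expected",
        [
            # essential splice region: first and last two intronic bases
            ("intron_variant+1", VariantClass.TRUNCATING),
            ("intron_variant-2", VariantClass.TRUNCATING),
            ("intron_variant+3", VariantClass.EXCLUDED),
            ("intron_variant-8", VariantClass.EXCLUDED),
        ],
    )
    def test_intron_offset_rule(self, term, expected):
        assert classify_consequence(term) is expected

    def test_unknown_and_empty_terms_excluded_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert classify_consequence("made_up_term") is VariantClass.EXCLUDED
            assert classify_consequence("") is VariantClass.EXCLUDED
        assert "made_up_term" in caplog.text

    def test_classification_partitions_vocabulary(self):
        preimages = {cls: set() for cls in VariantClass}
        for term in CONSEQUENCE_VOCABULARY:
            preimages[classify_consequence(term)].add(term)
        assert set().union(*preimages.values()) == set(CONSEQUENCE_VOCABULARY)
        assert preimages[VariantClass.TRUNCATING] & preimages[VariantClass.NONTRUNCATING] == set()
        assert preimages[VariantClass.EXCLUDED] & preimages[VariantClass.TRUNCATING] == set()


class TestCaseTable:
    def test_row_count_preserved(self, case_tsv):
        records = read_case_table(case_tsv)
        assert len(records) == 3
        assert records[0].gene == "MYBPC3"
        assert records[0].carrier_count == 104
        assert records[0].protein_pos == 502

    def test_missing_column_names_it(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("disease\tvariant_id\tconsequence\tcarrier_count\nHCM\tv\tmissense\t1\n")
        with pytest.raises(ValueError, match="gene"):
            read_case_table(path)

    def test_negative_carrier_count_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "disease\tgene\tvariant_id\tconsequence\tcarrier_count\n"
            "HCM\tMYH7\tv\tmissense\t-1\n"
        )
        with pytest.raises(ValueError, match="carrier_count"):
            read_case_table(path)

    def test_non_integer_carrier_count_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "disease\tgene\tvariant_id\tconsequence\tcarrier_count\n"
            "HCM\tMYH7\tv\tmissense\tlots\n"
        )
        with pytest.raises(ValueError, match="integer"):
            read_case_table(path)

    def test_round_trip_preserves_all_fields(self, case_tsv, tmp_path):
        records = read_case_table(case_tsv)
        out = tmp_path / "out.tsv"
        write_case_table(records, out)
        assert read_case_table(out) == records


class TestReferenceTable:
    def test_tsv_reader(self, reference_tsv):
        sites = read_reference_table(reference_tsv)
        assert len(sites) == 4
        assert sites[0].ac == 3 and sites[0].an == 121412

    def test_ac_above_an_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "gene\tvariant_id\tconsequence\tac\tan\nG\tv\tmissense\t10\t4\n"
        )
        with pytest.raises(ValueError, match="ac"):
            read_reference_table(path)


VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=AC,Number=A,Type=Integer,Description="Allele count">
##INFO=<ID=AN,Number=1,Type=Integer,Description="Allele number">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


class TestSitesVcf:
    def test_pass_filter_and_multiallelic_decomposition(self, tmp_path):
        path = tmp_path / "sites.vcf"
        path.write_text(
            VCF_HEADER
            + "11\t47364249\t.\tG\tA\t100\tPASS\tAC=3;AN=121412;GENE=MYBPC3;CSQ=missense_variant\n"
            + "11\t47364300\t.\tC\tT,G\t100\tPASS\tAC=5,2;AN=120000;GENE=MYBPC3;CSQ=missense_variant\n"
            + "11\t47364400\t.\tA\tG\t100\tVQSRTrancheSNP\tAC=9;AN=120000;GENE=MYBPC3;CSQ=missense_variant\n"
        )
        sites = read_reference_table(path, format="vcf_sites")
        # non-PASS dropped; multiallelic record splits into two sites
        assert len(sites) == 3
        assert sites[0].ac == 3 and sites[0].an == 121412
        assert {s.variant_id for s in sites[1:]} == {
            "11:47364300:C:T",
            "11:47364300:C:G",
        }
        assert [s.ac for s in sites[1:]] == [5, 2]

    def test_missing_an_is_hard_failure(self, tmp_path):
        path = tmp_path / "sites.vcf"
        header = VCF_HEADER.replace(
            '##INFO=<ID=AN,Number=1,Type=Integer,Description="Allele number">\n', ""
        )
        path.write_text(
            header + "11\t47364249\t.\tG\tA\t100\tPASS\tAC=3;GENE=MYBPC3;CSQ=missense_variant\n"
        )
        with pytest.raises(ValueError, match="AN"):
            read_reference_table(path, format="vcf_sites")


class TestInvariants:
    def test_case_variant_rejects_zero_carriers(self):
        with pytest.raises(ValueError):
            CaseVariant("HCM", "MYH7", "v", "missense", 0)

    def test_case_variant_rejects_nonpositive_protein_pos(self):
        with pytest.raises(ValueError):
            CaseVariant("HCM", "MYH7", "v", "missense", 1, protein_pos=0)

    def test_reference_site_bounds(self):
        with pytest.raises(ValueError):
            ReferenceSite("G", "v", "missense", ac=-1, an=100)
        with pytest.raises(ValueError):
            ReferenceSite("G", "v", "missense", ac=1, an=0)
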