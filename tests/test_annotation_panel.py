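"""Panel loading, HGVS consequence classification, and annotation lookups."""

import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from couplescreen import (
    ClassificationTable,
    CoupleScreenError,
    FrequencyTable,
    Variant,
    attach_frequency,
    classify_consequence,
    load_panel,
    parse_significance,
)
from couplescreen.annotation_panel import (
    ABSENT,
    BENIGN,
    CANONICAL_SPLICE,
    CONFLICTING,
    CONSEQUENCE_CATEGORIES,
    FRAMESHIFT,
    INFRAME_INDEL,
    MISSENSE,
    NONSENSE,
    OTHER,
    PATHOGENIC,
    PLP_COMBINED,
    PLP_SIGNIFICANCES,
    SEVERITY_ORDER,
    VUS,
)

PANEL_HEADER = "GENE\tCONDITION\tOMIM\tINHERITANCE\tLOF_MECHANISM\n"


class TestLoadPanel:
    def test_ar_rows_retained_ad_only_dropped(self):
        tsv = PANEL_HEADER + (
            "GJB2\tDeafness, autosomal recessive 1A\t220290\tAR\tyes\n"
            "MUTYH\tPolyposis\t608456\tAD,AR\tyes\n"
            "FBN1\tMarfan syndrome\t154700\tAD\tno\n"
        )
        panel = load_panel(io.StringIO(tsv))
        assert set(panel) == {"GJB2", "MUTYH"}
        assert panel["GJB2"].lof_mechanism == "yes"
        assert panel["MUTYH"].inheritance == frozenset({"AD", "AR"})

    def test_empty_panel_warns(self, caplog):
        with caplog.at_level("WARNING"):
            panel = load_panel(io.StringIO(PANEL_HEADER))
        assert panel == {} and "empty" in caplog.text

    def test_missing_column_is_fatal(self):
        with pytest.raises(CoupleScreenError, match="LOF_MECHANISM"):
            load_panel(io.StringIO("GENE\tCONDITION\tOMIM\tINHERITANCE\nX\tc\t1\tAR\n"))

    def test_duplicate_gene_keeps_first(self, caplog):
        tsv = PANEL_HEADER + "GJB2\tfirst\t1\tAR\tyes\nGJB2\tsecond\t2\tAR\tno\n"
        with caplog.at_level("WARNING"):
            panel = load_panel(io.StringIO(tsv))
        assert panel["GJB2"].condition == "first" and "duplicate" in caplog.text

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.tuples(
        st.text(alphabet="ABCDEFG", min_size=1, max_size=4),
        st.sets(st.sampled_from(["AR", "AD", "XL", "MT", "YL"]), min_size=1),
    ), max_size=12))
    def test_never_retains_entry_lacking_ar(self, rows):
        tsv = PANEL_HEADER + "".join(
            f"{gene}\tcond\t123456\t{','.join(sorted(modes))}\tunknown\n"
            for gene, modes in rows
        )
        panel = load_panel(io.StringIO(tsv))
        assert all("AR" in entry.inheritance for entry in panel.values())
        ar_genes = {gene for gene, modes in rows if "AR" in modes}
        assert set(panel) == ar_genes


class TestClassifyConsequence:
    @pytest.mark.parametrize("hgvs_c,hgvs_p,category", [
        # published cohort examples
        ("c.1456C>T", "p.(Arg486Trp)", MISSENSE),
        ("c.955C>T", "p.(Gln319*)", NONSENSE),
        ("c.975+1G>C", "", CANONICAL_SPLICE),
        ("c.1357-2A>C", "", CANONICAL_SPLICE),
        ("c.1564dup", "p.(Ala522Glyfs*8)", FRAMESHIFT),
        ("c.20A>T", "p.(Glu7Val)", MISSENSE),
        ("c.2145G>A", "p.(Trp715*)", NONSENSE),
        ("c.945dup", "p.(Glu316*)", NONSENSE),  # protein-level call wins
        ("c.935_936del", "p.(Thr312Serfs*13)", FRAMESHIFT),
        # constructed edge cases
        ("c.100+2T>C", "", CANONICAL_SPLICE),
        ("c.100+3A>G", "", OTHER),            # beyond the canonical site
        ("c.100-5C>G", "", OTHER),
        ("c.100_102del", "", INFRAME_INDEL),  # 3 nt, frame preserved
        ("c.100del", "", FRAMESHIFT),         # 1 nt, frame decided from c.
        ("c.100_101insACT", "", INFRAME_INDEL),
        ("c.100_105delinsGGG", "", INFRAME_INDEL),  # net -3
        ("c.1775_1778del", "p.(Val592_593delins30)", OTHER),  # conflicting row
        ("c.303C>T", "p.(Trp101Ter)", NONSENSE),
        ("garbage", "nonsense-string", OTHER),
    ])
    def test_classification_rules(self, hgvs_c, hgvs_p, category):
        consequence = classify_consequence(hgvs_c, hgvs_p)
        assert consequence.category == category
        assert consequence.truncating == (
            category in (NONSENSE, FRAMESHIFT, CANONICAL_SPLICE)
        )

    def test_both_empty_rejected(self):
        with pytest.raises(CoupleScreenError):
            classify_consequence("", "")

    @settings(max_examples=300, derandomize=True)
    @given(st.text(max_size=25), st.text(max_size=25))
    def test_total_and_never_crashes(self, hgvs_c, hgvs_p):
        if not hgvs_c and not hgvs_p:
            return
        assert classify_consequence(hgvs_c, hgvs_p).category in CONSEQUENCE_CATEGORIES


class TestSignificance:
    @pytest.mark.parametrize("text,expected", [
        ("Pathogenic", PATHOGENIC),
        ("Likely_pathogenic", "likely_pathogenic"),
        ("Pathogenic/Likely_pathogenic", PLP_COMBINED),
        ("Conflicting_interpretations_of_pathogenicity", CONFLICTING),
        ("Uncertain_significance", VUS),
        ("benign", BENIGN),
        ("", ABSENT),
    ])
    def test_vocabulary_mapping(self, text, expected):
        assert parse_significance(text) == expected

    def test_combined_counts_as_plp_conflicting_does_not(self):
        assert PLP_COMBINED in PLP_SIGNIFICANCES
        assert CONFLICTING not in PLP_SIGNIFICANCES

    def test_unrecognized_maps_to_vus_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert parse_significance("drug_response") == VUS
        assert "unrecognized" in caplog.text


def _variant(**kwargs):
    defaults = dict(chrom="1", pos=100, ref="A", alt="G")
    defaults.update(kwargs)
    return Variant(**defaults)


class TestClassificationTable:
    def test_genomic_key_lookup_and_absent_default(self):
        table = ClassificationTable.from_records([
            dict(chrom="1", pos=100, ref="A", alt="G", clnsig="Pathogenic"),
        ])
        assert table.lookup(_variant()).significance == PATHOGENIC
        assert table.lookup(_variant(pos=101)).significance == ABSENT

    def test_hgvs_fallback_key(self):
        table = ClassificationTable.from_records([
            dict(gene="GJB2", hgvs_c="c.109G>A", clnsig="Pathogenic"),
        ])
        v = _variant(gene="GJB2", hgvs_c="c.109G>A")
        assert table.lookup(v).significance == PATHOGENIC

    def test_duplicate_keys_keep_most_pathogenic(self, caplog):
        """Resolution order must match the severity ranking exactly."""
        for first, second in [("VUS", "Pathogenic"), ("Pathogenic", "VUS"),
                              ("Benign", "Likely_pathogenic")]:
            table = ClassificationTable()
            with caplog.at_level("WARNING"):
                table.add_record(chrom="1", pos=100, ref="A", alt="G", clnsig=first)
                table.add_record(chrom="1", pos=100, ref="A", alt="G", clnsig=second)
            expected = min(
                (parse_significance(first), parse_significance(second)),
                key=SEVERITY_ORDER.index,
            )
            assert table.lookup(_variant()).significance == expected
        assert "duplicate" in caplog.text

    def test_row_without_any_key_rejected(self):
        with pytest.raises(CoupleScreenError):
            ClassificationTable.from_records([dict(clnsig="Pathogenic")])

    def test_tsv_round_trip(self, tmp_path):
        path = tmp_path / "clf.tsv"
        path.write_text(
            "CHROM\tPOS\tREF\tALT\tGENE\tHGVS_C\tCLNSIG\tREVIEW_STATUS\n"
            "# a comment line\n"
            "1\t100\tA\tG\tGJB2\tc.109G>A\tPathogenic\ttwo stars\n"
        )
        table = ClassificationTable.from_tsv(path)
        record = table.lookup(_variant(gene="GJB2", hgvs_c="c.109G>A"))
        assert record.significance == PATHOGENIC
        assert record.review_status == "two stars"


class TestAttachFrequency:
    def test_max_over_populations(self):
        freq = FrequencyTable.from_records([("1", 100, "A", "G", 0.004, 0.0001)])
        assert attach_frequency(_variant(), freq).max_af == 0.004

    def test_absent_everywhere_stays_missing(self):
        assert attach_frequency(_variant(), FrequencyTable()).max_af is None

    def test_info_af_combined_with_table(self):
        freq = FrequencyTable.from_records([("1", 100, "A", "G", 0.002)])
        assert attach_frequency(_variant(max_af=0.01), freq).max_af == 0.01

    def test_out_of_range_frequency_is_fatal(self):
        with pytest.raises(CoupleScreenError):
            FrequencyTable.from_records([("1", 100, "A", "G", 1.2)])
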