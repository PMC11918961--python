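"""Transcript model invariants, HGVS c. parsing and variant localization."""

import pytest
from hypothesis import given, settings, strategies as st

from splicedx.gene_model import (
    GeneModelError,
    HgvsParseError,
    Region,
    SpliceVariantDescriptor,
    TranscriptModel,
    cds_to_exon_offset,
    exon_offset_to_cds,
    format_hgvs_c,
    locate_variant,
    parse_hgvs_c,
    read_gff3_exons,
    read_model,
    write_model,
)


class TestParseHgvsC:
    @pytest.mark.parametrize(
        "text,anchor,offset,ref,alt,kind",
        [
            ("c.613-11G>A", 613, -11, "G", "A", "substitution"),
            ("c.2349A>G", 2349, 0, "A", "G", "substitution"),
            ("c.2349A>G/p.(=)", 2349, 0, "A", "G", "substitution"),
            ("c.2090+3A>T", 2090, 3, "A", "T", "substitution"),
            ("c.1669-2_1669-1delinsTT", 1669, -2, "", "TT", "delins"),
            ("c.2996_2998del", 2996, 0, "", "", "deletion"),
        ],
    )
    def test_examples(self, text, anchor, offset, ref, alt, kind):
        v = parse_hgvs_c(text)
        assert (v.anchor_position, v.intron_offset) == (anchor, offset)
        assert (v.ref_allele, v.alt_allele, v.edit_kind) == (ref, alt, kind)

    def test_delins_span(self):
        v = parse_hgvs_c("c.1669-2_1669-1delinsTT")
        assert (v.end_anchor, v.end_offset) == (1669, -1)
        assert not v.is_exonic and v.is_canonical_site

    @pytest.mark.parametrize(
        "bad",
        ["c.613-11G>", "g.123A>T", "c.0A>G", "c.-12A>G", "c.*45A>G", "c.12dup",
         "c.", "nonsense", "c.12_15invAT"],
    )
    def test_rejects_unsupported_grammar(self, bad):
        with pytest.raises(HgvsParseError):
            parse_hgvs_c(bad)

    def test_round_trip_example(self):
        assert format_hgvs_c(parse_hgvs_c("c.2090+3A>T")) == "c.2090+3A>T"

    @given(
        anchor=st.integers(1, 9999),
        offset=st.integers(-50, 50),
        ref=st.sampled_from("ACGT"),
        alt=st.sampled_from("ACGT"),
    )
    @settings(max_examples=200, derandomize=True)
    def test_substitution_round_trip_property(self, anchor, offset, ref, alt):
        text = f"c.{anchor}{offset:+d}{ref}>{alt}" if offset else f"c.{anchor}{ref}>{alt}"
        assert format_hgvs_c(parse_hgvs_c(text)) == text

    @given(
        anchor=st.integers(1, 9999),
        offset=st.integers(-20, -1),
        width=st.integers(0, 5),
        alt=st.text(alphabet="ACGT", min_size=1, max_size=6),
    )
    @settings(max_examples=100, derandomize=True)
    def test_delins_round_trip_property(self, anchor, offset, width, alt):
        end = offset + width
        if end >= 0:  # keep both ends intronic on the same side
            return
        text = f"c.{anchor}{offset:+d}_{anchor}{end:+d}delins{alt}"
        assert format_hgvs_c(parse_hgvs_c(text)) == text


class TestModelInvariants:
    def test_intron_count_enforced(self):
        with pytest.raises(GeneModelError, match="introns"):
            TranscriptModel("x", (Region(1, 9), Region(2, 9)), (), cds_start=1, cds_end=18)

    def test_cds_multiple_of_three(self):
        with pytest.raises(GeneModelError, match="multiple of 3"):
            TranscriptModel("x", (Region(1, 10),), (), cds_start=1, cds_end=10)

    def test_internal_stop_rejected(self):
        with pytest.raises(GeneModelError, match="internal stop"):
            TranscriptModel(
                "x", (Region(1, 12, "ATGTAAGAATAA"),), (), cds_start=1, cds_end=12
            )

    def test_sequence_length_must_match(self):
        with pytest.raises(GeneModelError, match="length"):
            Region(1, 5, "ACGT")

    def test_tiny_gene_translates(self, tiny_gene):
        assert tiny_gene.protein() == "MEEEEEEEWWWWHHHHPPP"


class TestCoordinateMapping:
    def test_first_base_and_boundary(self, packaged_model):
        assert cds_to_exon_offset(packaged_model, 1) == (1, 1)
        e1 = packaged_model.exons[0].length
        assert cds_to_exon_offset(packaged_model, e1) == (1, e1)
        assert cds_to_exon_offset(packaged_model, e1 + 1) == (2, 1)

    def test_exhaustive_round_trip(self, tiny_gene):
        for pos in range(1, tiny_gene.exonic_length + 1):
            exon, offset = cds_to_exon_offset(tiny_gene, pos)
            assert exon_offset_to_cds(tiny_gene, exon, offset) == pos

    def test_out_of_range(self, tiny_gene):
        for pos in (0, tiny_gene.exonic_length + 1):
            with pytest.raises(GeneModelError):
                cds_to_exon_offset(tiny_gene, pos)


class TestLocateVariant:
    @pytest.mark.parametrize(
        "hgvs,kind,index,canonical",
        [
            ("c.613-11G>A", "intron", 5, False),
            ("c.4221G>A", "exon", 31, False),
            ("c.839-1G>A", "intron", 6, True),
            ("c.3538-1G>A", "intron", 25, True),
            ("c.455+8T>C", "intron", 4, False),
            ("c.1669-2_1669-1delinsTT", "intron", 13, True),
            ("c.2349A>G/p.(=)", "exon", 19, False),
        ],
    )
    def test_study_variants(self, packaged_model, hgvs, kind, index, canonical):
        locus = locate_variant(packaged_model, parse_hgvs_c(hgvs))
        assert (locus.region_kind, locus.region_index) == (kind, index)
        assert locus.is_canonical_site is canonical

    def test_acceptor_distance(self, packaged_model):
        locus = locate_variant(packaged_model, parse_hgvs_c("c.613-11G>A"))
        assert locus.distance_to_acceptor == 11

    def test_canonical_iff_offset_one_or_two(self, tiny_gene):
        for intron in tiny_gene.introns:
            donor_anchor = tiny_gene.exon_end(intron.index)
            acceptor_anchor = donor_anchor + 1
            for offset in range(1, intron.length + 1):
                v = SpliceVariantDescriptor(
                    hgvs_c="", anchor_position=donor_anchor, intron_offset=offset,
                    ref_allele="A", alt_allele="C", edit_kind="substitution",
                )
                locus = locate_variant(tiny_gene, v)
                expected = min(offset, intron.length - offset + 1) in (1, 2)
                assert locus.is_canonical_site is expected
                w = SpliceVariantDescriptor(
                    hgvs_c="", anchor_position=acceptor_anchor, intron_offset=-offset,
                    ref_allele="A", alt_allele="C", edit_kind="substitution",
                )
                assert locate_variant(tiny_gene, w).region_index == intron.index

    def test_anchor_beyond_transcript(self, tiny_gene):
        with pytest.raises(GeneModelError, match="beyond"):
            locate_variant(tiny_gene, parse_hgvs_c("c.9999A>G"))

    def test_non_boundary_intronic_anchor_rejected(self, tiny_gene):
        with pytest.raises(GeneModelError, match="boundary"):
            locate_variant(tiny_gene, parse_hgvs_c("c.5+3A>G"))


class TestModelIO:
    def test_write_read_round_trip(self, tiny_gene, tmp_path):
        path = tmp_path / "tiny.txt"
        write_model(tiny_gene, path, header_notes=["test gene"])
        back = read_model(path)
        assert back == tiny_gene

    def test_length_only_round_trip(self, packaged_model, tmp_path):
        path = tmp_path / "model.txt"
        write_model(packaged_model, path)
        back = read_model(path)
        assert back.exonic_length == packaged_model.exonic_length
        assert not back.has_intron_sequences

    def test_missing_format_tag(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("transcript_id\tx\n")
        with pytest.raises(GeneModelError, match="format tag"):
            read_model(path)

    def test_gff3_reader(self, tmp_path):
        gff = tmp_path / "m.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\t.\texon\t101\t130\t.\t+\t.\tID=e1\n"
            "chr1\t.\texon\t201\t230\t.\t+\t.\tID=e2\n"
        )
        model = read_gff3_exons(gff, "t1", cds_end=60)
        assert [e.length for e in model.exons] == [30, 30]
        assert [i.length for i in model.introns] == [70]
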