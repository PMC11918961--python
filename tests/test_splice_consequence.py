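"""Splice-event application, protein consequences and species summaries."""

import numpy as np
import pytest

from splicedx.gene_model import GeneModelError, Region, TranscriptModel
from splicedx.simulate import SimulationConfig, make_toy_transcript, oracle_consequence, random_event
from splicedx.splice_consequence import (
    AlteredTranscript,
    SpliceEvent,
    SpliceEventError,
    apply_splice_event,
    classify_frame,
    describe_event_set,
    read_event_table,
    translate_consequence,
    write_event_table,
)


class TestClassifyFrame:
    @pytest.mark.parametrize(
        "size,expected",
        [(9, True), (185, False), (0, True), (96, True), (134, False), (27, True), (71, False)],
    )
    def test_modular_arithmetic(self, size, expected):
        assert classify_frame(size, "intron_retention") is expected

    def test_negative_size_rejected(self):
        with pytest.raises(SpliceEventError):
            classify_frame(-3, "intron_retention")


class TestApplySpliceEvent:
    def test_exon_skip_length_bookkeeping(self, tiny_gene):
        event = SpliceEvent("exon_skipping", 3, tiny_gene.exons[2].length)
        altered = apply_splice_event(tiny_gene, event)
        assert len(altered.sequence) == tiny_gene.exonic_length - tiny_gene.exons[2].length
        assert altered.deleted == tiny_gene.exons[2].sequence

    def test_acceptor_retention_appears_verbatim(self, tiny_gene):
        event = SpliceEvent("intron_retention", 2, 9, anchor_side="acceptor")
        altered = apply_splice_event(tiny_gene, event)
        # manual concatenation oracle: exon1+exon2 + last 9 intronic nt + exon3..5
        exons = [e.sequence for e in tiny_gene.exons]
        expected = "".join(exons[:2]) + tiny_gene.introns[1].sequence[-9:] + "".join(exons[2:])
        assert altered.sequence == expected
        assert altered.inserted == "TCTGTGCAG"

    def test_donor_retention_takes_intron_head(self, tiny_gene):
        event = SpliceEvent("intron_retention", 2, 6, anchor_side="donor")
        altered = apply_splice_event(tiny_gene, event)
        assert altered.inserted == tiny_gene.introns[1].sequence[:6]

    @pytest.mark.parametrize("size", [1, 5, 11])
    def test_donor_side_exon_truncation_brute_force(self, tiny_gene, size):
        event = SpliceEvent("exon_internal_deletion", 2, size, anchor_side="donor")
        altered = apply_splice_event(tiny_gene, event)
        exons = [e.sequence for e in tiny_gene.exons]
        expected = exons[0] + exons[1][:-size] + "".join(exons[2:])
        assert altered.sequence == expected

    def test_retention_without_intron_sequence_fails_loudly(self, packaged_model):
        event = SpliceEvent("intron_retention", 5, 9, anchor_side="acceptor")
        with pytest.raises(GeneModelError, match="sequence"):
            apply_splice_event(packaged_model, event)

    def test_oversized_events_rejected(self, tiny_gene):
        with pytest.raises(SpliceEventError):
            apply_splice_event(tiny_gene, SpliceEvent("intron_retention", 1, 99))
        with pytest.raises(SpliceEventError):
            apply_splice_event(tiny_gene, SpliceEvent("exon_internal_deletion", 2, 12))
        with pytest.raises(SpliceEventError):
            apply_splice_event(tiny_gene, SpliceEvent("exon_skipping", 2, 5))


class TestTranslateConsequence:
    def test_nine_nt_acceptor_retention_is_three_residue_insertion(self, tiny_gene):
        event = SpliceEvent("intron_retention", 2, 9, anchor_side="acceptor")
        cons = translate_consequence(apply_splice_event(tiny_gene, event), tiny_gene)
        assert cons.category == "in_frame_insertion"
        assert cons.frame_preserved
        assert "insSerValGln" in cons.hgvs_p

    def test_two_nt_deletion_frameshift_matches_codon_scan(self):
        # exon 3 starts "TA", so losing the last 2 nt of exon 2 shifts codon 8
        # to GTA (Val) and codon 9 to TAA: p.(Glu8Valfs*2)
        exons = (
            Region(1, 12, "ATG" + "GAA" * 3),
            Region(2, 12, "GAG" * 4),
            Region(3, 12, "TATAAGGGTTTT"),
            Region(4, 12, "CAT" * 4),
            Region(5, 12, "CCC" * 3 + "TAA"),
        )
        introns = tuple(Region(i, 10, "GT" + "A" * 6 + "AG") for i in range(1, 5))
        model = TranscriptModel("fs", exons, introns, cds_start=1, cds_end=60)
        event = SpliceEvent("exon_internal_deletion", 2, 2, anchor_side="donor")
        altered = apply_splice_event(model, event)
        cons = translate_consequence(altered, model)
        assert cons.category == "frameshift" and not cons.frame_preserved
        assert cons.stop_offset == 2
        assert cons.hgvs_p == "p.(Glu8Valfs*2)"
        oracle = oracle_consequence(model, event)
        assert (cons.category, cons.stop_offset) == (oracle.category, oracle.stop_offset)

    def test_frameshift_without_downstream_stop_is_extension(self, tiny_gene):
        # tiny_gene's repeat-built sequence has no stop codon in shifted frames
        event = SpliceEvent("exon_internal_deletion", 2, 2, anchor_side="donor")
        cons = translate_consequence(apply_splice_event(tiny_gene, event), tiny_gene)
        assert cons.category == "stop_loss_extension"
        assert cons.stop_offset is None
        assert oracle_consequence(tiny_gene, event).category == "stop_loss_extension"

    def test_empty_edit_is_no_change(self, tiny_gene):
        altered = AlteredTranscript("tiny", tiny_gene.spliced_sequence(), 0, "", "")
        assert translate_consequence(altered, tiny_gene).category == "no_change"

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_inframe_retention_of_3k_inserts_k_residues(self, k):
        exons = (
            Region(1, 12, "ATG" + "GAA" * 3),
            Region(2, 12, "CAT" * 3 + "TAA"),
        )
        introns = (Region(1, 20, "GT" + "A" * 6 + "GCT" * 4),)
        model = TranscriptModel("g", exons, introns, cds_start=1, cds_end=24)
        event = SpliceEvent("intron_retention", 1, 3 * k, anchor_side="acceptor")
        cons = translate_consequence(apply_splice_event(model, event), model)
        assert cons.category == "in_frame_insertion"
        assert cons.hgvs_p.count("Ala") == k

    def test_inframe_deletion_of_3k_removes_k_residues(self, tiny_gene):
        event = SpliceEvent("exon_internal_deletion", 3, 6, anchor_side="donor")
        cons = translate_consequence(apply_splice_event(tiny_gene, event), tiny_gene)
        assert cons.category == "in_frame_deletion"
        # deleting 2 of 4 Trp codons; 3'-normalized window ends at Trp12
        assert cons.hgvs_p == "p.(Trp11_Trp12del)"

    def test_category_invariant_under_equivalent_descriptions(self, tiny_gene):
        """Full-intron retention named from either side is the same edit."""
        n = tiny_gene.introns[1].length
        donor = SpliceEvent("intron_retention", 2, n, anchor_side="donor")
        acceptor = SpliceEvent("intron_retention", 2, n, anchor_side="acceptor")
        c1 = translate_consequence(apply_splice_event(tiny_gene, donor), tiny_gene)
        c2 = translate_consequence(apply_splice_event(tiny_gene, acceptor), tiny_gene)
        assert c1 == c2

    def test_agrees_with_oracle_on_random_events(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            cfg = SimulationConfig(
                seed=int(rng.integers(0, 2**31)), n_exons=int(rng.integers(3, 8))
            )
            model = make_toy_transcript(cfg)
            event, oracle = random_event(model, rng)
            cons = translate_consequence(apply_splice_event(model, event), model)
            assert cons.category == oracle.category, (event, cons, oracle)
            if cons.category == "frameshift":
                assert cons.stop_offset == oracle.stop_offset

    def test_frame_flag_equals_mod3_for_random_events(self):
        rng = np.random.default_rng(5)
        model = make_toy_transcript(SimulationConfig(seed=42, n_exons=6))
        for _ in range(200):
            event, _ = random_event(model, rng)
            altered = apply_splice_event(model, event)
            cons = translate_consequence(altered, model)
            assert cons.frame_preserved == (altered.delta_nt % 3 == 0)
            assert classify_frame(event.size_nt, event.event_kind) == (event.size_nt % 3 == 0)


class TestDescribeEventSet:
    def test_two_aberrant_species_no_normal(self, tiny_gene):
        events = [
            SpliceEvent("exon_internal_deletion", 2, 5, "donor", fraction=0.6),
            SpliceEvent("exon_internal_deletion", 2, 3, "donor", fraction=0.4),
        ]
        rows = describe_event_set(tiny_gene, events, fraction_normal=0.0)
        assert len(rows) == 2
        assert all(r.species != "normal" for r in rows)
        assert rows[0].fraction >= rows[1].fraction

    def test_partial_aberration_reports_normal_species(self, tiny_gene):
        events = [SpliceEvent("exon_internal_deletion", 2, 5, "donor", fraction_normal=0.35)]
        rows = describe_event_set(tiny_gene, events)
        assert len(rows) == 2
        species = {r.species for r in rows}
        assert "normal" in species

    def test_empty_event_list_is_single_normal_species(self, tiny_gene):
        rows = describe_event_set(tiny_gene, [], fraction_normal=1.0)
        assert len(rows) == 1 and rows[0].species == "normal" and rows[0].category == "no_change"

    def test_fraction_overflow_rejected(self, tiny_gene):
        events = [SpliceEvent("exon_internal_deletion", 2, 5, "donor", fraction=0.8)]
        with pytest.raises(SpliceEventError, match="> 1"):
            describe_event_set(tiny_gene, events, fraction_normal=0.5)

    def test_ordering_deterministic(self, tiny_gene):
        events = [
            SpliceEvent("exon_internal_deletion", 2, 3, "donor", fraction=0.3),
            SpliceEvent("exon_internal_deletion", 3, 6, "donor", fraction=0.3),
        ]
        a = describe_event_set(tiny_gene, events, fraction_normal=0.4)
        b = describe_event_set(tiny_gene, list(reversed(events)), fraction_normal=0.4)
        assert [r.species for r in a] == [r.species for r in b]


class TestEventTableIO:
    def test_round_trip(self, tmp_path):
        rows = [
            ("c.1G>A", SpliceEvent("intron_retention", 1, 9, "acceptor", None, 0.0)),
            ("c.2G>A", SpliceEvent("exon_skipping", 2, 12, "donor", 0.7, 0.3)),
        ]
        path = tmp_path / "events.tsv"
        write_event_table(path, rows)
        assert read_event_table(path) == rows

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("variant\tevent_kind\nx\ty\n")
        with pytest.raises(SpliceEventError, match="missing columns"):
            read_event_table(path)
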